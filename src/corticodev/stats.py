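"""Per-instance and cross-instance statistics on simulated connectomes.

The analysis battery mirrors how empirical connectomes are treated:
relative connection frequency across bins of a structural measure,
Spearman rank correlations (with an exact permutation p-value where the
number of bins is small enough that the discrete null matters), left-tailed
sign tests aggregating per-instance p-values, and binary logistic
regression quantified by McFadden's pseudo-R^2.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from itertools import permutations

import numpy as np
import pandas as pd
from scipy import stats as sps

from .connectome import (
    AreaConnectome,
    PairMeasures,
    area_degree,
    fraction_connected,
    n_connections,
    offdiag_mask,
)

EXACT_PERM_MAX_N = 9


@dataclass(frozen=True)
class AnalysisConfig:
    """Thresholds and sizes of the analysis battery."""

    alpha_spearman: float = 0.05
    alpha_sign: float = 0.05
    n_bins_max: int = 10
    n_instances: int = 100

    def __post_init__(self) -> None:
        if not (0 < self.alpha_spearman < 1 and 0 < self.alpha_sign < 1):
            raise ValueError("significance levels must lie in (0, 1)")


# ----------------------------------------------------------------------
# binned relative frequency

@dataclass
class BinnedFrequency:
    """Fraction of present connections per bin of a structural measure."""

    bin_values: np.ndarray  # bin centres (continuous) or distinct values
    n_present: np.ndarray
    n_absent: np.ndarray

    @property
    def relative_frequency(self) -> np.ndarray:
        total = self.n_present + self.n_absent
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(total > 0, self.n_present / total, np.nan)

    @property
    def n_bins(self) -> int:
        return len(self.bin_values)


def bin_relative_frequency(
    values: np.ndarray,
    exists: np.ndarray,
    n_bins: int = 10,
    tiered: bool = False,
) -> BinnedFrequency:
    """Bin ordered-pair measures and compute per-bin connection frequency.

    Continuous measures get ``n_bins`` (<= 10) equal-width bins over the
    observed range; tiered measures (e.g. absolute density difference with
    few distinct levels) get one bin per distinct value, which may be fewer
    than ``n_bins``.
    """
    values = np.asarray(values, dtype=float)
    exists = np.asarray(exists, dtype=bool)
    if values.shape != exists.shape:
        raise ValueError("values and exists must align")
    if not 1 <= n_bins <= 10:
        raise ValueError("n_bins must lie in [1, 10]")
    if tiered:
        levels = np.unique(np.round(values, 6))
        pres = np.array([exists[np.isclose(values, v, atol=1e-6)].sum() for v in levels])
        tot = np.array([(np.isclose(values, v, atol=1e-6)).sum() for v in levels])
        return BinnedFrequency(levels, pres, tot - pres)
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return BinnedFrequency(
            np.array([lo]), np.array([exists.sum()]), np.array([(~exists).sum()])
        )
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(values, edges[1:-1]), 0, n_bins - 1)
    pres = np.bincount(idx, weights=exists, minlength=n_bins)
    tot = np.bincount(idx, minlength=n_bins)
    centres = (edges[:-1] + edges[1:]) / 2
    return BinnedFrequency(centres, pres.astype(int), (tot - pres).astype(int))


# ----------------------------------------------------------------------
# Spearman correlation with exact small-n permutation p

@dataclass(frozen=True)
class CorrelationResult:
    rho: float
    p_value: float

    @property
    def defined(self) -> bool:
        return math.isfinite(self.rho)


UNDEFINED_CORRELATION = CorrelationResult(float("nan"), float("nan"))


@lru_cache(maxsize=None)
def _perm_matrix(n: int) -> np.ndarray:
    return np.array(list(permutations(range(n))), dtype=np.int64)


def _rank(x: np.ndarray) -> np.ndarray:
    return sps.rankdata(x, method="average")


def spearman_correlation(x, y) -> CorrelationResult:
    """Spearman rank correlation with a two-sided p-value.

    Non-finite pairs are dropped. For n <= 9 observations the p-value is
    the exact permutation probability P(|rho_perm| >= |rho_obs|), whose
    discreteness matters when correlating across a handful of bins (the
    best attainable p across 4 bins is 2/4! = 0.083, across 5 bins
    2/5! = 0.0167). Larger n uses the t approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    n = len(x)
    if n < 3:
        return UNDEFINED_CORRELATION
    rx, ry = _rank(x), _rank(y)
    if np.std(rx) == 0 or np.std(ry) == 0:
        return UNDEFINED_CORRELATION
    rho = float(np.corrcoef(rx, ry)[0, 1])
    if n <= EXACT_PERM_MAX_N:
        perms = _perm_matrix(n)
        permuted = ry[perms]  # (n!, n)
        rxc = rx - rx.mean()
        pc = permuted - permuted.mean(axis=1, keepdims=True)
        denom = np.sqrt((rxc**2).sum() * (pc**2).sum(axis=1))
        rhos = pc @ rxc / denom
        p = float(np.mean(np.abs(rhos) >= abs(rho) - 1e-12))
    else:
        p = float(sps.spearmanr(x, y).pvalue)
    return CorrelationResult(rho, p)


# ----------------------------------------------------------------------
# sign test

def sign_test_left(p_values, alpha_ref: float = 0.05) -> dict:
    """Left-tailed sign test of H1: median of ``p_values`` < ``alpha_ref``.

    Normal approximation with continuity correction on the number of values
    above the reference (ties at the reference dropped); 100 values all
    below 0.05 give z = -9.9 and p = 2.08e-23.
    """
    p_values = np.asarray([p for p in np.atleast_1d(p_values) if math.isfinite(p)])
    if p_values.size == 0:
        raise ValueError("sign test requires at least one finite p-value")
    above = int((p_values > alpha_ref).sum())
    below = int((p_values < alpha_ref).sum())
    n = above + below
    if n == 0:
        return {"z": 0.0, "p": 0.5, "n": 0}
    diff = above - n / 2
    correction = -0.5 if diff > 0 else (0.5 if diff < 0 else 0.0)
    z = (diff + correction) / (math.sqrt(n) / 2)
    return {"z": z, "p": float(sps.norm.cdf(z)), "n": n}


# ----------------------------------------------------------------------
# logistic regression and McFadden's pseudo-R^2

PREDICTOR_SETS = ("null", "distance", "abs_density_diff", "both")


@dataclass
class LogisticModelFit:
    predictor_set: str
    coefficients: np.ndarray
    log_likelihood: float
    converged: bool = True
    separated: bool = False


def zscore(values: np.ndarray) -> np.ndarray:
    """Standardize to mean 0, sample standard deviation 1 ({1,2,3} -> {-1,0,1})."""
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least two values to z-score")
    sd = values.std(ddof=1)
    if sd == 0:
        raise ValueError("zero variance: z-scores undefined")
    return (values - values.mean()) / sd


def fit_logistic(exists: np.ndarray, predictors: np.ndarray | None, predictor_set: str = "both") -> LogisticModelFit:
    """Maximum-likelihood logistic fit (unregularized) with an intercept.

    ``predictors`` holds z-scored columns; pass ``None`` (or an empty
    matrix) for the constant-only null model, whose log-likelihood has the
    closed form n*(q*ln(q) + (1-q)*ln(1-q)) at the base rate q.
    """
    import statsmodels.api as sm

    y = np.asarray(exists, dtype=float)
    if predictors is None or (hasattr(predictors, "size") and predictors.size == 0):
        q = y.mean()
        if q in (0.0, 1.0):
            raise ValueError("outcomes contain a single class")
        n = len(y)
        ll = n * (q * math.log(q) + (1 - q) * math.log(1 - q))
        return LogisticModelFit("null", np.array([math.log(q / (1 - q))]), ll)
    X = sm.add_constant(np.asarray(predictors, dtype=float), has_constant="add")
    if y.min() == y.max():
        raise ValueError("outcomes contain a single class")
    model = sm.Logit(y, X)
    separated = False
    try:
        fit = model.fit(disp=0, maxiter=200, method="lbfgs")
        converged = bool(fit.mle_retvals.get("converged", True))
    except Exception:
        fit = model.fit(disp=0, maxiter=50, method="bfgs", skip_hessian=True)
        converged = False
        separated = True
    return LogisticModelFit(
        predictor_set, np.asarray(fit.params), float(fit.llf), converged, separated
    )


def mcfadden_r2(ll_model: float, ll_null: float, printed_formula: bool = False) -> float:
    """McFadden's pseudo-R^2 = 1 - LL_model / LL_null.

    ``printed_formula=True`` returns the bare likelihood ratio
    LL_model/LL_null instead, for auditing against sources that print the
    statistic without the "1 -".
    """
    if ll_null == 0:
        raise ValueError("null log-likelihood must be negative")
    ratio = ll_model / ll_null
    return ratio if printed_formula else 1.0 - ratio


# ----------------------------------------------------------------------
# per-instance analysis and cross-instance aggregation

@dataclass
class InstanceReport:
    """One per-instance row of the analysis battery."""

    fraction_connected: float
    n_connections: int
    freq_distance: CorrelationResult
    freq_abs_density: CorrelationResult
    degree_density: CorrelationResult
    mcfadden: dict[str, float]  # distance / abs_density_diff / both
    log_likelihoods: dict[str, float]
    n_density_bins: int

    def to_row(self) -> dict:
        return {
            "fraction_connected": self.fraction_connected,
            "n_connections": self.n_connections,
            "rho_freq_distance": self.freq_distance.rho,
            "p_freq_distance": self.freq_distance.p_value,
            "rho_freq_absdens": self.freq_abs_density.rho,
            "p_freq_absdens": self.freq_abs_density.p_value,
            "rho_degree_density": self.degree_density.rho,
            "p_degree_density": self.degree_density.p_value,
            "r2_distance": self.mcfadden["distance"],
            "r2_abs_density_diff": self.mcfadden["abs_density_diff"],
            "r2_both": self.mcfadden["both"],
            "n_density_bins": self.n_density_bins,
        }


def analyze_instance(
    connectome: AreaConnectome,
    measures: PairMeasures,
    config: AnalysisConfig = AnalysisConfig(),
) -> InstanceReport:
    """Run the full per-instance battery on one simulated connectome."""
    n = connectome.n_areas
    mask = offdiag_mask(n)
    exists = connectome.exists[mask]
    dist = measures.distance[mask]
    absdd = measures.abs_density_difference[mask]

    bf_dist = bin_relative_frequency(dist, exists, n_bins=config.n_bins_max)
    bf_dens = bin_relative_frequency(absdd, exists, tiered=True)
    cor_dist = spearman_correlation(
        bf_dist.bin_values, bf_dist.relative_frequency
    )
    cor_dens = spearman_correlation(
        bf_dens.bin_values, bf_dens.relative_frequency
    )
    cor_deg = spearman_correlation(measures.densities, area_degree(connectome))

    ll_null = fit_logistic(exists, None).log_likelihood
    preds = {
        "distance": zscore(dist)[:, None],
        "abs_density_diff": zscore(absdd)[:, None],
        "both": np.column_stack([zscore(absdd), zscore(dist)]),
    }
    lls = {"null": ll_null}
    r2 = {}
    for name, X in preds.items():
        fit = fit_logistic(exists, X, name)
        lls[name] = fit.log_likelihood
        r2[name] = float(mcfadden_r2(fit.log_likelihood, ll_null))
    return InstanceReport(
        fraction_connected=fraction_connected(connectome),
        n_connections=n_connections(connectome),
        freq_distance=cor_dist,
        freq_abs_density=cor_dens,
        degree_density=cor_deg,
        mcfadden=r2,
        log_likelihoods=lls,
        n_density_bins=bf_dens.n_bins,
    )


def aggregate_instances(
    reports: list[InstanceReport], config: AnalysisConfig = AnalysisConfig()
) -> dict:
    """Cross-instance medians plus sign tests on the correlation p-values."""
    if not reports:
        raise ValueError("no instance reports to aggregate")
    frame = pd.DataFrame([r.to_row() for r in reports])
    out: dict = {
        "n_instances": len(reports),
        "median_fraction_connected": float(frame["fraction_connected"].median()),
        "median_n_connections": float(frame["n_connections"].median()),
    }
    for key in ("freq_distance", "freq_absdens", "degree_density"):
        rho = frame[f"rho_{key}"]
        p = frame[f"p_{key}"].dropna()
        out[f"median_rho_{key}"] = float(rho.median())
        out[f"median_p_{key}"] = float(p.median()) if len(p) else float("nan")
        if len(p):
            st = sign_test_left(p.to_numpy(), config.alpha_spearman)
            out[f"sign_z_{key}"] = st["z"]
            out[f"sign_p_{key}"] = st["p"]
        else:
            out[f"sign_z_{key}"] = float("nan")
            out[f"sign_p_{key}"] = float("nan")
    for key in ("r2_distance", "r2_abs_density_diff", "r2_both"):
        out[f"median_{key}"] = float(frame[key].median())
    return out
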