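"""Prediction of (empirical-format) connectivity from simulated networks.

A linear-kernel support vector machine is trained on a simulated
connectome's z-scored structural measures (absolute density difference and
distance) to predict connection existence, with class-balanced weights
standing in for uniform class priors and Platt sigmoid calibration
providing posterior probabilities. The classifier is then applied to an
empirical-format dataset with dual posterior thresholds: pairs whose
posterior exceeds the threshold are labelled present, pairs below
1 - threshold are labelled absent, and the band in between stays
unclassified. Accuracy and Youden's J over classified pairs are validated
against permutation nulls, aggregated over ten thresholds per instance and
over instances per layout, and finally compared across layouts with a
three-way analysis of variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps
from sklearn.svm import SVC

from .stats import sign_test_left, zscore

DEFAULT_THRESHOLDS = tuple(np.round(np.arange(0.750, 0.9751, 0.025), 3))


@dataclass(frozen=True)
class ClassifierConfig:
    thresholds: tuple[float, ...] = DEFAULT_THRESHOLDS
    n_permutations: int = 100
    alpha_z: float = 0.05
    alpha_sign: float = 0.05

    def __post_init__(self) -> None:
        t = np.asarray(self.thresholds)
        if len(t) == 0 or (np.diff(t) <= 0).any() or t.min() <= 0.5 or t.max() >= 1:
            raise ValueError("thresholds must increase strictly within (0.5, 1)")


@dataclass
class EmpiricalDataset:
    """Directed area pairs with existence and two structural measures.

    ``differentiation`` is the architectonic-difference measure (absolute
    log-density-ratio for macaque-style data, absolute cortical-type
    difference for cat-style data); ``distance`` the spatial measure.
    """

    species_label: str
    frame: pd.DataFrame  # columns: source, target, exists, differentiation, distance

    REQUIRED = ("source", "target", "exists", "differentiation", "distance")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise ValueError(f"empirical dataset missing column(s): {missing}")
        if not set(np.unique(self.frame["exists"])) <= {0, 1}:
            raise ValueError("exists must be binary")
        meas = self.frame[["differentiation", "distance"]].to_numpy(dtype=float)
        if not np.isfinite(meas).all():
            raise ValueError("measures must be finite")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def exists(self) -> np.ndarray:
        return self.frame["exists"].to_numpy(dtype=int)

    def features_z(self) -> np.ndarray:
        """Z-scored (differentiation, distance), standardized per dataset."""
        return np.column_stack(
            [zscore(self.frame["differentiation"]), zscore(self.frame["distance"])]
        )


# ----------------------------------------------------------------------
class TrainedClassifier:
    """Linear SVM with sigmoid-calibrated posterior probabilities."""

    def __init__(self, svc: SVC):
        self._svc = svc

    def p_present(self, features_z: np.ndarray) -> np.ndarray:
        proba = self._svc.predict_proba(np.asarray(features_z, dtype=float))
        return proba[:, list(self._svc.classes_).index(1)]


def train_classifier(
    sim_features_z: np.ndarray,
    sim_exists: np.ndarray,
    config: ClassifierConfig = ClassifierConfig(),
    random_state: int = 0,
) -> TrainedClassifier:
    """Train the linear-kernel SVM on simulated pairs.

    Class weights inversely proportional to class frequencies implement the
    uniform-prior assumption; Platt scaling on the decision scores yields
    the posterior probability of the "present" class.
    """
    y = np.asarray(sim_exists, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training data must contain both classes")
    svc = SVC(
        kernel="linear",
        probability=True,  # Platt sigmoid calibration of the decision score
        class_weight="balanced",
        random_state=random_state,
    )
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        svc.fit(np.asarray(sim_features_z, dtype=float), y)
    return TrainedClassifier(svc)


def classify_with_threshold(p_present: np.ndarray, threshold: float) -> np.ndarray:
    """Dual-threshold labelling: 1 present, -1 absent, 0 unclassified."""
    if not 0.5 < threshold < 1:
        raise ValueError("threshold must lie in (0.5, 1)")
    p = np.asarray(p_present, dtype=float)
    out = np.zeros(len(p), dtype=np.int8)
    out[p > threshold] = 1
    out[p < 1 - threshold] = -1
    return out


@dataclass
class ThresholdEvaluation:
    threshold: float
    accuracy: float  # nan when nothing classified
    youden_j: float  # nan when a truth class is absent among classified
    fraction_classified: float
    null_mean: dict[str, float] = field(default_factory=dict)
    null_sd: dict[str, float] = field(default_factory=dict)
    z_p_value: dict[str, float] = field(default_factory=dict)


def evaluate_threshold(predictions: np.ndarray, truth: np.ndarray, threshold: float = 0.75) -> ThresholdEvaluation:
    """Accuracy, Youden's J and coverage over the classified pairs."""
    truth = np.asarray(truth, dtype=int)
    pred = np.asarray(predictions)
    classified = pred != 0
    frac = float(classified.mean()) if len(pred) else 0.0
    if not classified.any():
        return ThresholdEvaluation(threshold, float("nan"), float("nan"), frac)
    t = truth[classified]
    p = (pred[classified] == 1).astype(int)
    accuracy = float((p == t).mean())
    pos, neg = t == 1, t == 0
    if pos.any() and neg.any():
        sens = float(p[pos].mean())
        spec = float(1 - p[neg].mean())
        j = sens + spec - 1.0
    else:
        j = float("nan")
    return ThresholdEvaluation(threshold, accuracy, j, frac)


def permutation_null(
    truth: np.ndarray,
    p_present: np.ndarray,
    threshold: float,
    n_permutations: int = 100,
    rng: np.random.Generator | None = None,
) -> ThresholdEvaluation:
    """Evaluate a threshold and test it against a permutation null.

    Truth labels are permuted ``n_permutations`` times, the metrics are
    recomputed, the chance distribution is fit to a normal, and a two-sided
    z-test p-value is attached per metric.
    """
    if n_permutations < 2:
        raise ValueError("need at least two permutations")
    rng = rng if rng is not None else np.random.default_rng(0)
    truth = np.asarray(truth, dtype=int)
    pred = classify_with_threshold(p_present, threshold)
    ev = evaluate_threshold(pred, truth, threshold)
    null_acc, null_j = [], []
    for _ in range(n_permutations):
        perm = rng.permutation(truth)
        pe = evaluate_threshold(pred, perm, threshold)
        null_acc.append(pe.accuracy)
        null_j.append(pe.youden_j)
    for name, observed, null in (
        ("accuracy", ev.accuracy, null_acc),
        ("youden_j", ev.youden_j, null_j),
    ):
        null = np.asarray([v for v in null if math.isfinite(v)])
        if len(null) < 2 or not math.isfinite(observed):
            ev.z_p_value[name] = float("nan")
            continue
        mean, sd = float(null.mean()), float(null.std(ddof=1))
        ev.null_mean[name], ev.null_sd[name] = mean, sd
        if sd == 0:
            ev.z_p_value[name] = 1.0 if observed == mean else 0.0
        else:
            z = (observed - mean) / sd
            ev.z_p_value[name] = float(2 * sps.norm.sf(abs(z)))
    return ev


# ----------------------------------------------------------------------
@dataclass
class InstanceEvaluation:
    """Per-instance aggregate over the ten thresholds."""

    mean_accuracy: float
    mean_youden: float
    mean_fraction_classified: float
    median_z_p: dict[str, float]
    thresholds: list[ThresholdEvaluation]

    @property
    def missing(self) -> bool:
        return not math.isfinite(self.mean_accuracy)


def evaluate_instance(
    classifier: TrainedClassifier,
    dataset: EmpiricalDataset,
    config: ClassifierConfig = ClassifierConfig(),
    rng: np.random.Generator | None = None,
) -> InstanceEvaluation:
    """Apply a simulation-trained classifier to one empirical dataset.

    Undefined metrics at a threshold (nothing classified, or only one truth
    class among classified pairs) drop that threshold from the means.
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    p = classifier.p_present(dataset.features_z())
    evaluations = [
        permutation_null(dataset.exists, p, thr, config.n_permutations, rng)
        for thr in config.thresholds
    ]
    return aggregate_instance(evaluations)


def aggregate_instance(evaluations: list[ThresholdEvaluation]) -> InstanceEvaluation:
    acc = [e.accuracy for e in evaluations if math.isfinite(e.accuracy)]
    j = [e.youden_j for e in evaluations if math.isfinite(e.youden_j)]
    frac = [e.fraction_classified for e in evaluations]
    med_p = {}
    for name in ("accuracy", "youden_j"):
        ps = [
            e.z_p_value[name]
            for e in evaluations
            if math.isfinite(e.z_p_value.get(name, float("nan")))
        ]
        med_p[name] = float(np.median(ps)) if ps else float("nan")
    return InstanceEvaluation(
        mean_accuracy=float(np.mean(acc)) if acc else float("nan"),
        mean_youden=float(np.mean(j)) if j else float("nan"),
        mean_fraction_classified=float(np.mean(frac)) if frac else float("nan"),
        median_z_p=med_p,
        thresholds=evaluations,
    )


def aggregate_layout(
    instances: list[InstanceEvaluation],
    config: ClassifierConfig = ClassifierConfig(),
) -> dict:
    """Layout-level medians and the sign test on the median z-test p-values."""
    if not instances:
        raise ValueError("no instances")
    usable = [i for i in instances if not i.missing]
    out = {
        "n_instances": len(instances),
        "n_missing": len(instances) - len(usable),
        "median_fraction_classified": float(
            np.median([i.mean_fraction_classified for i in instances])
        ),
    }
    for key, metric in (("accuracy", "mean_accuracy"), ("youden_j", "mean_youden")):
        vals = [getattr(i, metric) for i in usable if math.isfinite(getattr(i, metric))]
        ps = [i.median_z_p[key] for i in usable if math.isfinite(i.median_z_p[key])]
        out[f"median_{key}"] = float(np.median(vals)) if vals else float("nan")
        out[f"median_p_{key}"] = float(np.median(ps)) if ps else float("nan")
        if ps:
            st = sign_test_left(ps, config.alpha_z)
            out[f"sign_z_{key}"], out[f"sign_p_{key}"] = st["z"], st["p"]
        else:
            out[f"sign_z_{key}"] = float("nan")
            out[f"sign_p_{key}"] = 1.0
    return out


# ----------------------------------------------------------------------
def anova_origins(performance: pd.DataFrame, metric: str = "value") -> dict:
    """Three-way main-effects ANOVA over the realistic-gradient layouts.

    ``performance`` must be a balanced table with columns ``species``
    (2 levels), ``growth_mode`` (3), ``origins`` (3) and the metric; on the
    full design (100 instances x 2 species x 9 layouts = 1800 rows) the
    main-effects model leaves 1794 error degrees of freedom. Returns the
    ANOVA table, estimated marginal means per origin level and
    Bonferroni-corrected pairwise comparisons.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf
    from statsmodels.stats.anova import anova_lm

    required = {"species", "growth_mode", "origins", metric}
    if not required <= set(performance.columns):
        raise ValueError(f"performance table needs columns {sorted(required)}")
    counts = performance.groupby(["species", "growth_mode", "origins"]).size()
    if counts.nunique() != 1:
        raise ValueError("design must be balanced across factor combinations")

    df = performance.copy()
    df["origins"] = df["origins"].astype(str)
    model = smf.ols(
        f"{metric} ~ C(species) + C(origins) + C(growth_mode)", data=df
    ).fit()
    table = anova_lm(model, typ=2)

    levels = sorted(df["origins"].unique())
    others = df[["species", "growth_mode"]].drop_duplicates()
    emmeans = {}
    for lvl in levels:
        grid = others.assign(origins=lvl)
        emmeans[lvl] = float(model.predict(grid).mean())
    # SE of an EMM / of a difference, from the OLS covariance of the
    # averaged design rows
    import patsy

    def design_row(lvl):
        grid = others.assign(origins=lvl)
        X = patsy.dmatrix(model.model.data.design_info, grid)
        return np.asarray(X).mean(axis=0)

    cov = model.cov_params().to_numpy()
    rows = {lvl: design_row(lvl) for lvl in levels}
    se_emm = {
        lvl: float(np.sqrt(rows[lvl] @ cov @ rows[lvl])) for lvl in levels
    }
    n_pairs = len(levels) * (len(levels) - 1) // 2
    posthoc = []
    for i, a in enumerate(levels):
        for b in levels[i + 1 :]:
            c = rows[a] - rows[b]
            diff = emmeans[a] - emmeans[b]
            se = float(np.sqrt(c @ cov @ c))
            z = diff / se if se > 0 else np.inf * np.sign(diff)
            p = float(2 * sps.norm.sf(abs(z)))
            posthoc.append(
                {
                    "pair": f"{a} vs {b}",
                    "difference": diff,
                    "se": se,
                    "p": p,
                    "p_bonferroni": min(1.0, p * n_pairs),
                }
            )
    return {
        "anova": table,
        "error_df": int(model.df_resid),
        "emmeans": emmeans,
        "se_emmeans": se_emm,
        "posthoc": pd.DataFrame(posthoc),
    }
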