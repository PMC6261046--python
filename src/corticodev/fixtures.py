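"""Synthetic empirical-format connectivity fixtures.

Real tract-tracing datasets (1128 directed macaque pairs with absolute
log-density-ratio and Euclidean distance; 954 cat pairs with absolute
cortical-type difference and border distance) cannot be shipped, so this
module generates datasets of the same shape with a controllable
architectonic-type-principle signature: connection existence is drawn from
a logistic model in which the log-odds fall with the architectonic
difference between areas and with their spatial separation. With both
coefficients at zero the existence rate equals the configured base rate;
with positive coefficients the binned existence frequency decreases in
both measures, giving the classification pipeline a truthful testbed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .classify import EmpiricalDataset
from .stats import zscore


@dataclass(frozen=True)
class FixtureSpec:
    """Generative recipe for one synthetic empirical-format dataset.

    atp_strength / distance_decay are log-odds decreases of connection
    existence per standard deviation of the respective measure; base_rate
    is the target overall connectivity (empirically 50-77%).
    """

    n_rows: int = 1128
    measure_kind: str = "continuous"  # or "ordinal" (<= 8 cortical types)
    atp_strength: float = 1.0
    distance_decay: float = 1.0
    base_rate: float = 0.55
    n_type_levels: int = 8
    seed: int = 0

    def __post_init__(self) -> None:
        if self.measure_kind not in ("continuous", "ordinal"):
            raise ValueError("measure_kind must be continuous or ordinal")
        if self.atp_strength < 0 or self.distance_decay < 0:
            raise ValueError("coefficients must be non-negative")
        if not 0 < self.base_rate < 1:
            raise ValueError("base_rate must lie in (0, 1)")
        if self.n_rows < 10:
            raise ValueError("n_rows too small to be useful")


#: Study-condition presets mirroring the two empirical dataset shapes.
MACAQUE_LIKE = FixtureSpec(n_rows=1128, measure_kind="continuous", base_rate=0.55)
CAT_LIKE = FixtureSpec(n_rows=954, measure_kind="ordinal", base_rate=0.6)


def _n_areas_for(n_rows: int) -> int:
    n = 2
    while n * (n - 1) < n_rows:
        n += 1
    return n


def generate_fixture(
    spec: FixtureSpec, rng: np.random.Generator | None = None
) -> EmpiricalDataset:
    """Draw one synthetic dataset from the spec's generative model.

    Areas receive architectonic differentiation levels (log-densities for
    the continuous kind, <= ``n_type_levels`` ordinal cortical types for the
    ordinal kind) and planar positions; ordered pairs inherit the absolute
    differentiation difference and the Euclidean distance, and existence is
    Bernoulli with logit b0 - atp_strength*z(diff) - distance_decay*z(dist),
    b0 solved so the expected existence rate equals ``base_rate``.
    """
    rng = rng if rng is not None else np.random.default_rng(spec.seed)
    n_areas = _n_areas_for(spec.n_rows)
    if spec.measure_kind == "continuous":
        level = rng.uniform(0.0, math.log(5.0), n_areas)  # ~five-fold density span
    else:
        level = rng.integers(1, spec.n_type_levels + 1, n_areas).astype(float)
    pos = rng.uniform(0.0, 10.0, (n_areas, 2))

    src, tgt = np.nonzero(~np.eye(n_areas, dtype=bool))
    order = rng.permutation(len(src))[: spec.n_rows]
    src, tgt = src[order], tgt[order]
    diff = np.abs(level[src] - level[tgt])
    dist = np.sqrt(((pos[src] - pos[tgt]) ** 2).sum(axis=1))

    score = -spec.atp_strength * zscore(diff) - spec.distance_decay * zscore(dist)

    def rate(b0: float) -> float:
        return float(1.0 / (1.0 + np.exp(-(b0 + score))).mean())

    b0 = brentq(lambda b: rate(b) - spec.base_rate, -30.0, 30.0)
    p = 1.0 / (1.0 + np.exp(-(b0 + score)))
    exists = (rng.random(spec.n_rows) < p).astype(int)

    frame = pd.DataFrame(
        {
            "source": src,
            "target": tgt,
            "exists": exists,
            "differentiation": diff,
            "distance": dist,
        }
    )
    label = "macaque-like" if spec.measure_kind == "continuous" else "cat-like"
    return EmpiricalDataset(species_label=f"synthetic-{label}", frame=frame)
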