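"""Growth layouts of the developing cortical sheet.

A growth layout fixes the spatiotemporal trajectory along which a
two-dimensional cortical sheet is populated by neurons: the *set* (how the
neuron-density gradient is oriented relative to neurogenetic timing), the
*growth mode* (one row of areas, two rows, or full two-dimensional growth),
and the number of neurogenetic origins around which new areas appear. The
registry enumerates the 21 canonical layouts used throughout the package.

Conventions
-----------
* In 1D growth modes the origin areas pre-exist at the start of the
  simulation and are not counted as a growth event; each growth event adds
  one new area per side per origin per row.
* In 2D growth mode the first growth event places the origin area(s); each
  later event adds a complete square ring of areas around each origin block.
* All growth events fire within the first third of the simulated duration,
  leaving the remaining time for connection formation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Literal

import numpy as np

SetName = Literal["realistic", "inverse", "radial", "static", "random"]
GrowthMode = Literal["1D_1row", "1D_2rows", "2D"]

#: Sets whose sheet expands in the plane as areas are added at the fringes.
PLANAR_SETS = ("realistic", "inverse", "random")

DEFAULT_DENSITY_MIN = 100.0
DEFAULT_DENSITY_FOLD = 5.0
DEFAULT_TOTAL_STEPS = 360


class ConfigurationError(ValueError):
    """Raised for invalid layout configurations."""


@dataclass(frozen=True)
class GrowthLayoutConfig:
    """One spatiotemporal growth trajectory of the cortical sheet.

    Parameters
    ----------
    set_name:
        Orientation of the density gradient relative to neurogenetic time:
        ``realistic`` (later areas denser), ``inverse`` (later areas
        sparser), ``radial`` (in-place neuron accumulation on a static
        arrangement), ``static`` (fully formed at onset) or ``random``
        (densities permuted over locations).
    growth_mode:
        ``1D_1row``, ``1D_2rows`` or ``2D``.
    n_origins:
        Number of neurogenetic origins (1-3 for 1D modes, 1, 2 or 4 for 2D).
    n_growth_events:
        Number of growth events that build the sheet.
    total_steps:
        Simulated duration T in time steps; all growth happens in [1, T/3].
    density_min, density_fold:
        Neuron density (somata per unit area) of the sparsest tier and the
        max/min density ratio (about five-fold empirically).
    area_side:
        Side length of the identical square areas, in sheet length units.
    """

    set_name: SetName
    growth_mode: GrowthMode
    n_origins: int
    n_growth_events: int
    abbreviation: str
    total_steps: int = DEFAULT_TOTAL_STEPS
    density_min: float = DEFAULT_DENSITY_MIN
    density_fold: float = DEFAULT_DENSITY_FOLD
    area_side: float = 1.0

    def __post_init__(self) -> None:
        if self.growth_mode not in ("1D_1row", "1D_2rows", "2D"):
            raise ConfigurationError(f"unknown growth mode {self.growth_mode!r}")
        if self.set_name not in ("realistic", "inverse", "radial", "static", "random"):
            raise ConfigurationError(f"unknown set {self.set_name!r}")
        allowed = {1, 2, 3} if self.growth_mode != "2D" else {1, 2, 4}
        if self.n_origins not in allowed:
            raise ConfigurationError(
                f"{self.n_origins} origins invalid for mode {self.growth_mode}"
            )
        if self.n_growth_events < 1 or self.total_steps < 3 * self.n_growth_events:
            raise ConfigurationError(
                "total_steps must allow all growth events within the first third "
                f"(got T={self.total_steps}, {self.n_growth_events} events)"
            )
        if self.density_fold <= 1 or self.density_min <= 0 or self.area_side <= 0:
            raise ConfigurationError("density_fold > 1 and positive sizes required")

    # ------------------------------------------------------------------
    @property
    def n_rows(self) -> int:
        return 2 if self.growth_mode == "1D_2rows" else 1

    @property
    def n_geometry_events(self) -> int:
        """Growth events of the planar layout defining the final geometry.

        For planar sets this equals ``n_growth_events``. Radial and static
        sheets reuse the final arrangement of the corresponding planar
        realistic layout (6 events in 1D modes, 5 in 2D).
        """
        if self.set_name == "static":
            return 5 if self.growth_mode == "2D" else 6
        return self.n_growth_events

    @property
    def n_tiers(self) -> int:
        """Number of distinct neuron-density levels on the final sheet."""
        if self.growth_mode == "2D":
            return self.n_geometry_events
        return self.n_geometry_events + 1

    @property
    def n_areas(self) -> int:
        """Final number of areas implied by mode, origins and events."""
        g = self.n_geometry_events
        if self.growth_mode == "2D":
            side = 2 * (g - 1) + 1
            return self.n_origins * side * side
        return self.n_rows * self.n_origins * (1 + 2 * g)

    def with_steps(self, total_steps: int) -> "GrowthLayoutConfig":
        return replace(self, total_steps=total_steps)


# ----------------------------------------------------------------------
# Registry: the 21 canonical layouts.
# (set, mode, origins, growth events, abbreviation)
_TABLE = [
    ("realistic", "1D_1row", 1, 12, "1D-1row-1or"),
    ("realistic", "1D_2rows", 1, 12, "1D-2row-1or"),
    ("realistic", "2D", 1, 5, "2D-1or"),
    ("realistic", "1D_1row", 2, 6, "1D-1row-2or"),
    ("realistic", "1D_2rows", 2, 6, "1D-2row-2or"),
    ("realistic", "2D", 2, 5, "2D-2or"),
    ("realistic", "1D_1row", 3, 4, "1D-1row-3or"),
    ("realistic", "1D_2rows", 3, 4, "1D-2row-3or"),
    ("realistic", "2D", 4, 4, "2D-4or"),
    ("inverse", "1D_1row", 2, 6, "inverse-1D-1row-2or"),
    ("inverse", "1D_2rows", 2, 6, "inverse-1D-2row-2or"),
    ("inverse", "2D", 2, 5, "inverse-2D-2or"),
    ("radial", "1D_1row", 2, 6, "radial-1D-1row-2or"),
    ("radial", "1D_2rows", 2, 6, "radial-1D-2row-2or"),
    ("radial", "2D", 2, 5, "radial-2D-2or"),
    ("static", "1D_1row", 2, 1, "static-1D-1row-2or"),
    ("static", "1D_2rows", 2, 1, "static-1D-2row-2or"),
    ("static", "2D", 2, 1, "static-2D-2or"),
    ("random", "1D_1row", 2, 6, "random-1D-1row-2or"),
    ("random", "1D_2rows", 2, 6, "random-1D-2row-2or"),
    ("random", "2D", 2, 5, "random-2D-2or"),
]


def make_layout_registry(
    total_steps: int = DEFAULT_TOTAL_STEPS,
    density_min: float = DEFAULT_DENSITY_MIN,
) -> list[GrowthLayoutConfig]:
    """Build the registry of the 21 canonical growth layouts.

    ``total_steps`` must accommodate the layout with the most growth events
    (12) within the first third of the simulation.
    """
    max_events = max(row[3] for row in _TABLE)
    if total_steps < 3 * max_events:
        raise ConfigurationError(
            f"total_steps must be >= {3 * max_events} to fit {max_events} growth events"
        )
    return [
        GrowthLayoutConfig(
            set_name=s,
            growth_mode=m,
            n_origins=o,
            n_growth_events=e,
            abbreviation=abbr,
            total_steps=total_steps,
            density_min=density_min,
        )
        for s, m, o, e, abbr in _TABLE
    ]


def get_layout(
    abbreviation: str,
    total_steps: int = DEFAULT_TOTAL_STEPS,
    density_min: float = DEFAULT_DENSITY_MIN,
) -> GrowthLayoutConfig:
    """Look up a layout by its abbreviation (e.g. ``"1D-1row-2or"``)."""
    for cfg in make_layout_registry(total_steps, density_min):
        if cfg.abbreviation == abbreviation:
            return cfg
    raise KeyError(f"unknown layout abbreviation {abbreviation!r}")


# ----------------------------------------------------------------------
def density_for_tier(tier: int, n_tiers: int, config: GrowthLayoutConfig) -> float:
    """Neuron density of a density tier.

    The underlying gradient ramps linearly from ``density_min`` to
    ``density_min * density_fold`` across ``n_tiers`` levels. For the
    realistic orientation (and the radial/static sheets sharing its final
    gradient, as well as the source multiset of the random set) tier indices
    follow creation order ascending; the inverse orientation maps creation
    order onto the gradient descending.
    """
    if not 0 <= tier < n_tiers:
        raise ValueError(f"tier {tier} out of range [0, {n_tiers})")
    if n_tiers == 1:
        frac = 0.0
    else:
        idx = n_tiers - 1 - tier if config.set_name == "inverse" else tier
        frac = idx / (n_tiers - 1)
    return config.density_min * (1.0 + (config.density_fold - 1.0) * frac)


def tier_densities(config: GrowthLayoutConfig) -> np.ndarray:
    """Densities of all tiers of a layout, indexed by tier."""
    return np.array(
        [density_for_tier(t, config.n_tiers, config) for t in range(config.n_tiers)]
    )


@dataclass(frozen=True)
class GrowthSchedule:
    """Time steps at which growth events fire."""

    event_times: tuple[int, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.event_times)


def schedule_growth_events(config: GrowthLayoutConfig) -> GrowthSchedule:
    """Evenly space the growth events over the first third of the run.

    The last event lands exactly at ``floor(total_steps / 3)`` so that all
    neurons are in place with two thirds of the simulation remaining. A
    static sheet is complete at onset, so its single event fires at t=1.
    """
    k = config.n_growth_events
    window = config.total_steps // 3
    if config.set_name == "static":
        return GrowthSchedule((1,))
    if k > window:
        raise ConfigurationError(
            f"cannot fit {k} growth events into the first {window} steps"
        )
    times = tuple(int(round(i * window / k)) for i in range(1, k + 1))
    if len(set(times)) != k or any(t < 1 for t in times):
        raise ConfigurationError("growth event times are not strictly increasing")
    return GrowthSchedule(times)
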