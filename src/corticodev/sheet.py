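"""Construction and growth of the cortical sheet.

The sheet is a rectangle tiled by identical square areas. Planar layouts
expand it over time: new areas emerge at the fringes of each neurogenetic
origin's block and push previously generated areas apart. Radial layouts
keep the final arrangement fixed from the start and fill every area with
somata at a constant rate; static layouts are complete at onset.

All coordinates are continuous, with the sheet's lower-left corner pinned
at the origin after every re-layout. Area positions are tracked on an
integer cell grid (one cell per area) from which global coordinates,
per-event displacement vectors and point-to-area lookups are derived.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .layouts import (
    PLANAR_SETS,
    ConfigurationError,
    GrowthLayoutConfig,
    tier_densities,
)


def place_somata(n: int, area_side: float = 1.0) -> np.ndarray:
    """Equidistant soma grid for an area holding ``n`` somata.

    Returns local offsets in ``[0, area_side]^2`` on a cell-centred r x c
    grid where (r, c) is the factor pair of ``n`` closest to square with
    r <= c (ties broken toward more rows). A prime ``n`` degenerates to a
    single row.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    best = (1, n)
    for r in range(1, int(math.isqrt(n)) + 1):
        if n % r == 0:
            best = (r, n // r)  # increasing r: last hit is closest to square
    r, c = best
    xs = (np.arange(c) + 0.5) / c * area_side
    ys = (np.arange(r) + 0.5) / r * area_side
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


@dataclass
class Area:
    """One square cortical area on the sheet."""

    area_id: int
    origin_id: int
    creation_event: int
    tier: int
    density: float
    cx: int  # integer cell coordinates; lower-left = (cx, cy) * area_side
    cy: int
    soma_local: np.ndarray  # (n_somata, 2) local offsets, fill order for radial
    n_active: int  # somata already generated (== n_somata except radial)

    @property
    def n_somata(self) -> int:
        return len(self.soma_local)

    def lower_left(self, area_side: float) -> tuple[float, float]:
        return self.cx * area_side, self.cy * area_side

    def soma_positions(self, area_side: float) -> np.ndarray:
        """Global positions of the currently active somata."""
        x0, y0 = self.lower_left(area_side)
        return self.soma_local[: self.n_active] + np.array([x0, y0])

    def centroid(self, area_side: float) -> np.ndarray:
        x0, y0 = self.lower_left(area_side)
        return np.array([x0 + area_side / 2, y0 + area_side / 2])


@dataclass
class GrowthEventResult:
    """What one growth event changed."""

    event_index: int
    #: (n_pre_existing, 2) displacement applied to area i (indexed by id)
    displacements: np.ndarray
    #: (area_id, soma_index) of every soma that appeared, in creation order
    new_somata: list[tuple[int, int]] = field(default_factory=list)


@dataclass
class CorticalSheet:
    """Time-stamped collection of areas plus growth bookkeeping."""

    layout: GrowthLayoutConfig
    areas: list[Area] = field(default_factory=list)
    current_event: int = 0
    displacement_log: dict[int, np.ndarray] = field(default_factory=dict)
    # 1D planar: ordered columns, one entry = (origin_id, [area_id per row])
    _columns: list[tuple[int, list[int]]] = field(default_factory=list)
    # 2D planar: per area (block, dx, dy)
    _ring_coords: dict[int, tuple[int, int, int]] = field(default_factory=dict)
    # random set: pre-shuffled density assignment by creation order
    _density_pool: np.ndarray | None = None

    # ------------------------------------------------------------------
    @property
    def n_areas(self) -> int:
        return len(self.areas)

    @property
    def area_side(self) -> float:
        return self.layout.area_side

    def grid_shape(self) -> tuple[int, int]:
        if not self.areas:
            return (0, 0)
        nx = max(a.cx for a in self.areas) + 1
        ny = max(a.cy for a in self.areas) + 1
        return nx, ny

    def bounds(self) -> tuple[float, float]:
        """(width, height) of the current sheet rectangle."""
        nx, ny = self.grid_shape()
        return nx * self.area_side, ny * self.area_side

    def cell_map(self) -> np.ndarray:
        """(nx, ny) array mapping each unit cell to its area id."""
        nx, ny = self.grid_shape()
        grid = np.full((nx, ny), -1, dtype=np.int64)
        for a in self.areas:
            grid[a.cx, a.cy] = a.area_id
        return grid

    def area_of_points(self, points: np.ndarray) -> np.ndarray:
        """Area id containing each point (nearest cell for boundary floats)."""
        nx, ny = self.grid_shape()
        ix = np.clip((points[:, 0] // self.area_side).astype(np.int64), 0, nx - 1)
        iy = np.clip((points[:, 1] // self.area_side).astype(np.int64), 0, ny - 1)
        return self.cell_map()[ix, iy]

    def centroids(self) -> np.ndarray:
        return np.array([a.centroid(self.area_side) for a in self.areas])

    def densities(self) -> np.ndarray:
        return np.array([a.density for a in self.areas])

    def total_neurons(self) -> int:
        return sum(a.n_active for a in self.areas)

    def area_lower_lefts(self) -> np.ndarray:
        return np.array([[a.cx, a.cy] for a in self.areas], dtype=float) * self.area_side


# ----------------------------------------------------------------------
# construction helpers

def _n_somata(density: float, area_side: float) -> int:
    return int(np.rint(density * area_side * area_side))


def _block_offsets(n_origins: int) -> list[tuple[int, int]]:
    # origin blocks on a line (1-2 origins) or a 2x2 grid (4 origins)
    if n_origins == 1:
        return [(0, 0)]
    if n_origins == 2:
        return [(0, 0), (1, 0)]
    if n_origins == 4:
        return [(0, 0), (1, 0), (0, 1), (1, 1)]
    raise ConfigurationError(f"2D growth supports 1, 2 or 4 origins, not {n_origins}")


def _realistic_density_sequence(layout: GrowthLayoutConfig) -> np.ndarray:
    """Final per-area densities of the realistic counterpart, creation order."""
    dens = tier_densities(layout)
    seq: list[float] = []
    if layout.growth_mode == "2D":
        for event in range(1, layout.n_geometry_events + 1):
            ring = event - 1
            per_block = 1 if ring == 0 else 8 * ring
            seq.extend([dens[ring]] * (per_block * layout.n_origins))
    else:
        seq.extend([dens[0]] * (layout.n_origins * layout.n_rows))
        for event in range(1, layout.n_geometry_events + 1):
            n_new = 2 * layout.n_origins * layout.n_rows
            seq.extend([dens[event]] * n_new)
    return np.asarray(seq)


def _tier_of_density(density: float, layout: GrowthLayoutConfig) -> int:
    ramp = np.array(
        [
            layout.density_min
            + (layout.density_fold - 1.0)
            * layout.density_min
            * (t / max(layout.n_tiers - 1, 1))
            for t in range(layout.n_tiers)
        ]
    )
    return int(np.argmin(np.abs(ramp - density)))


def _new_area(
    sheet: CorticalSheet,
    origin_id: int,
    creation_event: int,
    tier: int,
    active: bool,
    rng: np.random.Generator | None = None,
) -> Area:
    """Create an area; density comes from the tier or the random pool."""
    layout = sheet.layout
    if layout.set_name == "random":
        assert sheet._density_pool is not None
        density = float(sheet._density_pool[sheet.n_areas])
        tier = _tier_of_density(density, layout)
    else:
        dens = tier_densities(layout)
        density = float(dens[tier])
    n = _n_somata(density, layout.area_side)
    soma = place_somata(n, layout.area_side)
    if layout.set_name == "radial" and rng is not None:
        soma = soma[rng.permutation(n)]  # activation order, spatially uniform
    area = Area(
        area_id=sheet.n_areas,
        origin_id=origin_id,
        creation_event=creation_event,
        tier=tier,
        density=density,
        cx=0,
        cy=0,
        soma_local=soma,
        n_active=n if active else 0,
    )
    sheet.areas.append(area)
    return area


def _relayout_1d(sheet: CorticalSheet) -> None:
    for col_idx, (_, ids) in enumerate(sheet._columns):
        for row, area_id in enumerate(ids):
            sheet.areas[area_id].cx = col_idx
            sheet.areas[area_id].cy = row


def _relayout_2d(sheet: CorticalSheet) -> None:
    rings = max(
        (max(abs(dx), abs(dy)) for _, dx, dy in sheet._ring_coords.values()),
        default=0,
    )
    side = 2 * rings + 1
    offsets = _block_offsets(sheet.layout.n_origins)
    for area_id, (block, dx, dy) in sheet._ring_coords.items():
        bx, by = offsets[block]
        sheet.areas[area_id].cx = bx * side + dx + rings
        sheet.areas[area_id].cy = by * side + dy + rings


def _grow_1d_columns(sheet: CorticalSheet, event: int, rng: np.random.Generator) -> list[Area]:
    """Insert one column per side per origin; returns new areas."""
    layout = sheet.layout
    new_areas: list[Area] = []

    def make_column(origin: int) -> tuple[int, list[int]]:
        ids = []
        for _ in range(layout.n_rows):
            area = _new_area(sheet, origin, event, tier=event, active=True, rng=rng)
            ids.append(area.area_id)
            new_areas.append(area)
        return (origin, ids)

    for origin in range(layout.n_origins):
        positions = [i for i, (o, _) in enumerate(sheet._columns) if o == origin]
        left, right = positions[0], positions[-1]
        sheet._columns.insert(left, make_column(origin))
        sheet._columns.insert(right + 2, make_column(origin))
    return new_areas


def _grow_2d_ring(sheet: CorticalSheet, event: int, rng: np.random.Generator) -> list[Area]:
    layout = sheet.layout
    new_areas: list[Area] = []
    if event == 1:
        for block in range(layout.n_origins):
            area = _new_area(sheet, block, event, tier=0, active=True, rng=rng)
            sheet._ring_coords[area.area_id] = (block, 0, 0)
            new_areas.append(area)
        return new_areas
    ring = event - 1
    coords = [
        (dx, dy)
        for dx in range(-ring, ring + 1)
        for dy in range(-ring, ring + 1)
        if max(abs(dx), abs(dy)) == ring
    ]
    for block in range(layout.n_origins):
        for dx, dy in coords:
            area = _new_area(sheet, block, event, tier=ring, active=True, rng=rng)
            sheet._ring_coords[area.area_id] = (block, dx, dy)
            new_areas.append(area)
    return new_areas


def _build_final_geometry(sheet: CorticalSheet, rng: np.random.Generator, active: bool) -> None:
    """Lay out the full final arrangement (radial/static sheets)."""
    layout = sheet.layout
    if layout.growth_mode == "2D":
        for event in range(1, layout.n_geometry_events + 1):
            _grow_2d_ring(sheet, event, rng)
        _relayout_2d(sheet)
    else:
        sheet._columns = []
        for origin in range(layout.n_origins):
            ids = []
            for _ in range(layout.n_rows):
                area = _new_area(sheet, origin, 0, tier=0, active=True, rng=rng)
                ids.append(area.area_id)
            sheet._columns.append((origin, ids))
        for event in range(1, layout.n_geometry_events + 1):
            _grow_1d_columns(sheet, event, rng)
        _relayout_1d(sheet)
    if not active:
        for a in sheet.areas:
            a.n_active = 0
    # creation_event of radial/static areas is 0: they all exist at onset
    for a in sheet.areas:
        a.creation_event = 0


# ----------------------------------------------------------------------
def init_sheet(config: GrowthLayoutConfig, seed_or_rng) -> CorticalSheet:
    """Create the sheet state at t=0 for a layout.

    Planar 1D sets start with one area per origin per row; planar 2D sets
    start empty (the first growth event places the origin areas). Radial
    sheets have their final arrangement with zero somata; static sheets are
    complete.
    """
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    sheet = CorticalSheet(layout=config)
    if config.set_name == "random":
        pool = _realistic_density_sequence(config)
        sheet._density_pool = pool[rng.permutation(len(pool))]

    if config.set_name in PLANAR_SETS:
        if config.growth_mode == "2D":
            return sheet  # empty; event 1 places the origin areas
        for origin in range(config.n_origins):
            ids = []
            for _ in range(config.n_rows):
                area = _new_area(sheet, origin, 0, tier=0, active=True, rng=rng)
                ids.append(area.area_id)
            sheet._columns.append((origin, ids))
        _relayout_1d(sheet)
        return sheet

    if config.set_name == "radial":
        _build_final_geometry(sheet, rng, active=False)
        return sheet
    if config.set_name == "static":
        _build_final_geometry(sheet, rng, active=True)
        return sheet
    raise ConfigurationError(config.set_name)


def apply_growth_event(
    sheet: CorticalSheet, event_index: int, rng: np.random.Generator
) -> GrowthEventResult:
    """Fire growth event ``event_index`` (1-based) and re-lay-out the sheet.

    Returns the displacement applied to every pre-existing area and the
    somata that appeared, in deterministic creation order.
    """
    layout = sheet.layout
    if event_index != sheet.current_event + 1 or event_index > layout.n_growth_events:
        raise ValueError(
            f"event {event_index} out of order (current {sheet.current_event}, "
            f"schedule has {layout.n_growth_events})"
        )
    n_old = sheet.n_areas
    old_pos = np.array([[a.cx, a.cy] for a in sheet.areas], dtype=float)
    new_somata: list[tuple[int, int]] = []

    if layout.set_name == "static":
        pass  # sheet complete at onset
    elif layout.set_name == "radial":
        max_n = max(a.n_somata for a in sheet.areas)
        k = math.ceil(max_n / layout.n_growth_events)
        for a in sheet.areas:
            add = min(k, a.n_somata - a.n_active)
            for j in range(a.n_active, a.n_active + add):
                new_somata.append((a.area_id, j))
            a.n_active += add
    else:  # planar growth
        if layout.growth_mode == "2D":
            new_areas = _grow_2d_ring(sheet, event_index, rng)
            _relayout_2d(sheet)
        else:
            new_areas = _grow_1d_columns(sheet, event_index, rng)
            _relayout_1d(sheet)
        for a in new_areas:
            for j in range(a.n_somata):
                new_somata.append((a.area_id, j))

    new_pos = np.array([[a.cx, a.cy] for a in sheet.areas[:n_old]], dtype=float)
    disp = (new_pos - old_pos) * layout.area_side if n_old else np.zeros((0, 2))
    sheet.displacement_log[event_index] = disp
    sheet.current_event = event_index
    return GrowthEventResult(event_index, disp, new_somata)


def build_final_sheet(config: GrowthLayoutConfig, seed_or_rng=0) -> CorticalSheet:
    """Convenience: run all growth events and return the finished sheet."""
    rng = (
        seed_or_rng
        if isinstance(seed_or_rng, np.random.Generator)
        else np.random.default_rng(seed_or_rng)
    )
    sheet = init_sheet(config, rng)
    for e in range(1, config.n_growth_events + 1):
        apply_growth_event(sheet, e, rng)
    return sheet
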