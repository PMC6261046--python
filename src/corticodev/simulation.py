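"""Stochastic axon outgrowth and synapse formation.

Every neuron owns a single axon terminal that starts at its soma. Each time
step, unoccupied terminals extend by a fixed length at a uniformly random
angle (reflecting at the sheet boundary). Once a terminal has left its
parent area at least once it becomes eligible to form a synapse: whenever
it comes closer than the contact radius to a candidate soma (any soma but
its own; the nearest one, ties broken at random) a synapse forms with
probability ``accept_prob``. An occupied terminal stops growing and stays
coincident with the contacted soma; synapses persist. When a growth event
re-lays-out the sheet, every terminal is shifted with the area it currently
finds itself in, so contacts are retained.

The dynamics are identical across all growth layouts; only the layout's
spatiotemporal trajectory differs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .layouts import GrowthLayoutConfig, schedule_growth_events
from .sheet import CorticalSheet, apply_growth_event, build_final_sheet, init_sheet

_TIE_EPS = 1e-12


@dataclass(frozen=True)
class SimulationParams:
    """Axon growth parameters (identical within a growth mode).

    step_length
        Fixed axon extension per time step, in sheet length units.
    contact_radius
        Maximal terminal-to-soma distance for synapse formation.
    accept_prob
        Probability that an in-range contact actually forms a synapse.
    total_steps
        Simulated duration T; must match the layout's ``total_steps``.
    """

    step_length: float
    contact_radius: float
    total_steps: int
    accept_prob: float = 0.9

    def __post_init__(self) -> None:
        if self.step_length <= 0 or self.contact_radius <= 0:
            raise ValueError("step_length and contact_radius must be positive")
        if not 0.0 <= self.accept_prob <= 1.0:
            raise ValueError("accept_prob must lie in [0, 1]")


@dataclass
class SimulationState:
    """Mutable per-neuron terminal state plus the synapse table."""

    sheet: CorticalSheet
    params: SimulationParams
    pos: np.ndarray  # (N, 2) terminal positions
    soma: np.ndarray  # (N, 2) soma positions (shifted with the sheet)
    parent_area: np.ndarray  # (N,) int
    occupied: np.ndarray  # (N,) bool
    eligible: np.ndarray  # (N,) bool, monotone
    target: np.ndarray  # (N,) int, -1 while unoccupied
    n_alive: int = 0
    synapses: list[tuple[int, int, int]] = field(default_factory=list)
    _tree: cKDTree | None = None

    @classmethod
    def allocate(cls, sheet: CorticalSheet, params: SimulationParams, capacity: int):
        return cls(
            sheet=sheet,
            params=params,
            pos=np.zeros((capacity, 2)),
            soma=np.zeros((capacity, 2)),
            parent_area=np.zeros(capacity, dtype=np.int64),
            occupied=np.zeros(capacity, dtype=bool),
            eligible=np.zeros(capacity, dtype=bool),
            target=np.full(capacity, -1, dtype=np.int64),
        )

    # ------------------------------------------------------------------
    def add_neurons(self, entries: list[tuple[int, int]]) -> None:
        """Instantiate somata + terminals for (area_id, soma_index) entries."""
        a = self.sheet.area_side
        for area_id, j in entries:
            area = self.sheet.areas[area_id]
            x0, y0 = area.lower_left(a)
            p = area.soma_local[j] + np.array([x0, y0])
            i = self.n_alive
            self.pos[i] = p
            self.soma[i] = p
            self.parent_area[i] = area_id
            self.n_alive += 1
        self._tree = None

    def rebuild_tree(self) -> None:
        self._tree = cKDTree(self.soma[: self.n_alive])

    @property
    def tree(self) -> cKDTree:
        if self._tree is None:
            self.rebuild_tree()
        return self._tree

    def occupancy_fraction(self) -> float:
        return float(self.occupied[: self.n_alive].mean()) if self.n_alive else 0.0


# ----------------------------------------------------------------------
def _reflect(x: np.ndarray, width: float) -> np.ndarray:
    """Mirror coordinates back into [0, width] (exact multiple reflection)."""
    if width <= 0:
        return x
    x = np.mod(x, 2.0 * width)
    return np.where(x > width, 2.0 * width - x, x)


def extend_unoccupied_terminals(
    state: SimulationState, params: SimulationParams, rng: np.random.Generator
) -> None:
    """Extend every unoccupied terminal by one fixed-length random step."""
    n = state.n_alive
    if n == 0:
        return
    active = ~state.occupied[:n]
    idx = np.nonzero(active)[0]
    if idx.size == 0:
        return
    theta = rng.uniform(0.0, 2.0 * np.pi, idx.size)
    step = params.step_length * np.column_stack([np.cos(theta), np.sin(theta)])
    newpos = state.pos[idx] + step
    w, h = state.sheet.bounds()
    newpos[:, 0] = _reflect(newpos[:, 0], w)
    newpos[:, 1] = _reflect(newpos[:, 1], h)
    state.pos[idx] = newpos
    _update_eligibility(state, idx)


def _update_eligibility(state: SimulationState, idx: np.ndarray) -> None:
    """Flip eligibility for terminals that are outside their parent area."""
    pend = idx[~state.eligible[idx]]
    if pend.size == 0:
        return
    a = state.sheet.area_side
    lls = state.sheet.area_lower_lefts()
    ll = lls[state.parent_area[pend]]
    p = state.pos[pend]
    inside = (
        (p[:, 0] >= ll[:, 0])
        & (p[:, 0] <= ll[:, 0] + a)
        & (p[:, 1] >= ll[:, 1])
        & (p[:, 1] <= ll[:, 1] + a)
    )
    state.eligible[pend[~inside]] = True


def attempt_synapses(
    state: SimulationState,
    params: SimulationParams,
    rng: np.random.Generator,
    time_step: int,
) -> int:
    """Let eligible unoccupied terminals contact the nearest in-range soma.

    Returns the number of synapses formed this step.
    """
    n = state.n_alive
    cand = np.nonzero(~state.occupied[:n] & state.eligible[:n])[0]
    if cand.size == 0:
        return 0
    r = params.contact_radius
    k = min(3, n)
    dist, nbr = state.tree.query(state.pos[cand], k=k, distance_upper_bound=r)
    if k == 1:
        dist = dist[:, None]
        nbr = nbr[:, None]
    invalid = (nbr == cand[:, None]) | ~np.isfinite(dist)
    dist = np.where(invalid, np.inf, dist)
    best = np.argmin(dist, axis=1)
    rows = np.arange(cand.size)
    best_dist = dist[rows, best]
    has_target = np.isfinite(best_dist)
    if not has_target.any():
        return 0
    targets = nbr[rows, best]
    # random tie-break among equally-near candidates
    with np.errstate(invalid="ignore"):
        ties = (np.abs(dist - best_dist[:, None]) < _TIE_EPS).sum(axis=1) > 1
    for i in np.nonzero(ties & has_target)[0]:
        opts = nbr[i][np.abs(dist[i] - best_dist[i]) < _TIE_EPS]
        targets[i] = rng.choice(opts)
    accept = rng.random(cand.size) < params.accept_prob
    hit = has_target & accept
    src = cand[hit]
    tgt = targets[hit]
    state.occupied[src] = True
    state.target[src] = tgt
    state.pos[src] = state.soma[tgt]
    for s, t in zip(src, tgt):
        state.synapses.append((int(s), int(t), time_step))
    return int(hit.sum())


def shift_terminals_on_growth(
    state: SimulationState,
    old_cell_map: np.ndarray,
    old_area_side: float,
    displacements: np.ndarray,
) -> None:
    """Translate terminals and somata by the shift of their containing area.

    Containment is evaluated against the sheet layout *before* the event
    (``old_cell_map``); occupied terminals stay coincident with their target
    soma because soma and terminal live in the same cell.
    """
    n = state.n_alive
    if n == 0 or displacements.size == 0:
        return
    nx, ny = old_cell_map.shape

    def area_of(points: np.ndarray) -> np.ndarray:
        ix = np.clip((points[:, 0] // old_area_side).astype(np.int64), 0, nx - 1)
        iy = np.clip((points[:, 1] // old_area_side).astype(np.int64), 0, ny - 1)
        return old_cell_map[ix, iy]

    state.soma[:n] += displacements[area_of(state.soma[:n])]
    state.pos[:n] += displacements[area_of(state.pos[:n])]
    # keep occupied terminals exactly on their target soma
    occ = np.nonzero(state.occupied[:n])[0]
    state.pos[occ] = state.soma[state.target[occ]]
    state._tree = None


# ----------------------------------------------------------------------
@dataclass
class SimulationResult:
    """Final state of one simulation instance."""

    layout: GrowthLayoutConfig
    params: SimulationParams
    seed: int
    sheet: CorticalSheet
    neuron_area: np.ndarray  # (N,) area id per neuron
    synapses: pd.DataFrame  # source_neuron_id, target_neuron_id, time_step
    occupancy: float

    @property
    def n_neurons(self) -> int:
        return len(self.neuron_area)


def run_instance(
    layout: GrowthLayoutConfig, params: SimulationParams, seed: int
) -> SimulationResult:
    """Run one seeded instance of sheet growth plus axon dynamics.

    Per time step: fire the growth event if scheduled (grow the sheet,
    shift terminals, instantiate terminals for new somata), then extend
    unoccupied terminals, then attempt synapse formation.
    """
    if params.total_steps != layout.total_steps:
        raise ValueError("params.total_steps must equal layout.total_steps")
    rng = np.random.default_rng(seed)
    sheet = init_sheet(layout, rng)
    schedule = set(schedule_growth_events(layout).event_times)

    # final neuron capacity is known from the layout
    capacity = sum(
        a.n_somata for a in build_final_sheet(layout, np.random.default_rng(0)).areas
    )
    state = SimulationState.allocate(sheet, params, capacity)

    # neurons present at onset (1D planar origin areas, static sheets)
    initial = [
        (a.area_id, j) for a in sheet.areas for j in range(a.n_active)
    ]
    if initial:
        state.add_neurons(initial)

    event = 0
    for t in range(1, params.total_steps + 1):
        if t in schedule:
            event += 1
            old_map = sheet.cell_map()
            result = apply_growth_event(sheet, event, rng)
            shift_terminals_on_growth(
                state, old_map, layout.area_side, result.displacements
            )
            state.add_neurons(result.new_somata)
            state.rebuild_tree()
            # area shifts can move a terminal relative to its (moved) parent
            _update_eligibility(state, np.arange(state.n_alive))
        extend_unoccupied_terminals(state, params, rng)
        attempt_synapses(state, params, rng, t)

    syn = pd.DataFrame(
        state.synapses,
        columns=["source_neuron_id", "target_neuron_id", "time_step"],
    )
    return SimulationResult(
        layout=layout,
        params=params,
        seed=seed,
        sheet=sheet,
        neuron_area=state.parent_area[: state.n_alive].copy(),
        synapses=syn,
        occupancy=state.occupancy_fraction(),
    )
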