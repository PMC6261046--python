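import numpy as np
import pytest

from corticodev.layouts import GrowthLayoutConfig, get_layout
from corticodev.sheet import Area, CorticalSheet, place_somata
from corticodev.simulation import (
    SimulationParams,
    SimulationState,
    _reflect,
    attempt_synapses,
    extend_unoccupied_terminals,
    run_instance,
    shift_terminals_on_growth,
)


def toy_sheet(n_areas=2, n_per_area=4, density=4.0) -> CorticalSheet:
    """Hand-built 1D strip of equal-density areas (no growth machinery)."""
    layout = GrowthLayoutConfig(
        set_name="static",
        growth_mode="1D_1row",
        n_origins=2,
        n_growth_events=1,
        abbreviation="toy",
        total_steps=60,
    )
    sheet = CorticalSheet(layout=layout)
    for i in range(n_areas):
        sheet.areas.append(
            Area(
                area_id=i,
                origin_id=0,
                creation_event=0,
                tier=0,
                density=density,
                cx=i,
                cy=0,
                soma_local=place_somata(n_per_area),
                n_active=n_per_area,
            )
        )
    return sheet


def toy_state(sheet, params) -> SimulationState:
    state = SimulationState.allocate(sheet, params, capacity=sheet.total_neurons())
    state.add_neurons(
        [(a.area_id, j) for a in sheet.areas for j in range(a.n_active)]
    )
    return state


class TestExtension:
    def test_step_has_fixed_length(self, rng):
        sheet = toy_sheet()
        params = SimulationParams(0.1, 0.01, 60)
        state = toy_state(sheet, params)
        before = state.pos[: state.n_alive].copy()
        extend_unoccupied_terminals(state, params, rng)
        moved = np.linalg.norm(state.pos[: state.n_alive] - before, axis=1)
        # interior moves are exactly step_length; boundary reflections shorten
        # the apparent displacement but never lengthen it
        assert (moved <= 0.1 + 1e-12).all()
        assert (moved[moved > 0.0999] == pytest.approx(0.1, abs=1e-9))

    def test_occupied_terminal_never_moves(self, rng):
        sheet = toy_sheet()
        params = SimulationParams(0.1, 0.01, 60)
        state = toy_state(sheet, params)
        state.occupied[0] = True
        p0 = state.pos[0].copy()
        for _ in range(5):
            extend_unoccupied_terminals(state, params, rng)
        assert np.array_equal(state.pos[0], p0)

    def test_boundary_reflection_mirrors_position(self):
        # stepping to x = -0.09 on a sheet with x >= 0 reflects to +0.09
        assert _reflect(np.array([-0.09]), 2.0)[0] == pytest.approx(0.09)
        assert _reflect(np.array([2.05]), 2.0)[0] == pytest.approx(1.95)
        inside = np.array([0.3, 1.7])
        assert np.allclose(_reflect(inside, 2.0), inside)

    def test_eligibility_flips_only_after_leaving_parent_area(self, rng):
        sheet = toy_sheet()
        params = SimulationParams(0.05, 0.01, 60)
        state = toy_state(sheet, params)
        assert not state.eligible[: state.n_alive].any()
        for _ in range(200):
            extend_unoccupied_terminals(state, params, rng)
        assert state.eligible[: state.n_alive].any()
        # monotone: once set, stays set
        snap = state.eligible.copy()
        extend_unoccupied_terminals(state, params, rng)
        assert (state.eligible[snap] == True).all()  # noqa: E712


class TestSynapseFormation:
    def test_eligible_terminal_contacts_nearest_soma(self, rng):
        sheet = toy_sheet()
        params = SimulationParams(0.1, 0.2, 60, accept_prob=1.0)
        state = toy_state(sheet, params)
        # put terminal 0 just outside its parent, near a soma of area 1
        target = state.soma[4]
        state.pos[0] = target + np.array([0.15, 0.0])
        state.eligible[0] = True
        attempt_synapses(state, params, rng, time_step=1)
        assert state.occupied[0]
        assert state.target[0] != 0
        assert np.array_equal(state.pos[0], state.soma[state.target[0]])
        assert state.synapses[0][0] == 0

    def test_ineligible_terminal_cannot_synapse(self, rng):
        sheet = toy_sheet()
        params = SimulationParams(0.1, 10.0, 60, accept_prob=1.0)
        state = toy_state(sheet, params)
        attempt_synapses(state, params, rng, time_step=1)
        assert not state.occupied[: state.n_alive].any()

    def test_own_soma_is_excluded(self, rng):
        sheet = toy_sheet(n_areas=2, n_per_area=1)
        params = SimulationParams(0.1, 0.05, 60, accept_prob=1.0)
        state = toy_state(sheet, params)
        state.eligible[:2] = True  # terminals still sit on their own somata
        attempt_synapses(state, params, rng, time_step=1)
        assert not state.occupied[:2].any()

    def test_acceptance_rate_matches_connection_probability(self):
        # many eligible terminals, each in range of exactly one foreign soma
        n = 30000
        sheet = toy_sheet(n_areas=2, n_per_area=1)
        params = SimulationParams(0.1, 0.3, 60, accept_prob=0.9)
        state = SimulationState.allocate(sheet, params, capacity=n + 1)
        state.add_neurons([(0, 0)])  # the shared target soma
        state.pos[1 : n + 1] = state.soma[0] + np.array([0.2, 0.0])
        state.soma[1 : n + 1] = np.array([50.0, 50.0])  # own somata far away
        state.parent_area[1 : n + 1] = 1
        state.eligible[1 : n + 1] = True
        state.n_alive = n + 1
        state.eligible[0] = False
        attempt_synapses(state, params, np.random.default_rng(0), time_step=1)
        frac = state.occupied[1 : n + 1].mean()
        sigma = np.sqrt(0.9 * 0.1 / n)
        assert abs(frac - 0.9) < 3 * sigma

    def test_failed_draw_leaves_terminal_free_to_retry(self):
        sheet = toy_sheet(n_areas=2, n_per_area=1)
        params = SimulationParams(0.1, 0.3, 60, accept_prob=0.0)
        state = toy_state(sheet, params)
        state.pos[0] = state.soma[1] + np.array([0.05, 0.0])
        state.eligible[0] = True
        attempt_synapses(state, params, np.random.default_rng(0), time_step=1)
        assert not state.occupied[0]
        # retry with accept_prob 1 succeeds
        params2 = SimulationParams(0.1, 0.3, 60, accept_prob=1.0)
        attempt_synapses(state, params2, np.random.default_rng(0), time_step=2)
        assert state.occupied[0]


class TestTerminalShifting:
    def test_terminals_translate_with_their_area(self):
        sheet = toy_sheet(n_areas=3)
        params = SimulationParams(0.1, 0.01, 60)
        state = toy_state(sheet, params)
        old_map = sheet.cell_map()
        disp = np.array([[0.0, 0.0], [2.0, 0.0], [2.0, 0.0]])
        before = state.pos[: state.n_alive].copy()
        inside_area1 = state.parent_area[: state.n_alive] == 1
        shift_terminals_on_growth(state, old_map, 1.0, disp)
        after = state.pos[: state.n_alive]
        assert np.allclose(after[inside_area1], before[inside_area1] + [2, 0])
        assert np.allclose(
            after[state.parent_area[: state.n_alive] == 0],
            before[state.parent_area[: state.n_alive] == 0],
        )

    def test_occupied_terminal_stays_on_its_shifted_soma(self):
        sheet = toy_sheet(n_areas=2)
        params = SimulationParams(0.1, 0.01, 60)
        state = toy_state(sheet, params)
        state.occupied[0] = True
        state.target[0] = 5  # soma in area 1
        state.pos[0] = state.soma[5]
        disp = np.array([[0.0, 0.0], [3.0, 0.0]])
        shift_terminals_on_growth(state, sheet.cell_map(), 1.0, disp)
        assert np.array_equal(state.pos[0], state.soma[5])

    def test_static_layout_never_displaces_terminals(self):
        cfg = get_layout("static-1D-1row-2or", total_steps=60, density_min=4.0)
        res = run_instance(cfg, SimulationParams(0.8, 0.012, 60), 0)
        assert all(
            np.allclose(d, 0) for d in res.sheet.displacement_log.values()
        )


class TestRunInstance:
    def test_same_seed_gives_identical_synapse_tables(self):
        cfg = get_layout("1D-1row-2or", total_steps=60, density_min=6.0)
        params = SimulationParams(0.8, 0.05, 60)
        a = run_instance(cfg, params, 7)
        b = run_instance(cfg, params, 7)
        assert a.synapses.equals(b.synapses)
        assert a.occupancy == b.occupancy

    def test_axons_are_one_shot(self):
        cfg = get_layout("1D-1row-2or", total_steps=60, density_min=6.0)
        res = run_instance(cfg, SimulationParams(0.8, 0.05, 60), 3)
        src = res.synapses["source_neuron_id"]
        assert src.is_unique
        assert len(res.synapses) <= res.n_neurons
        assert (
            res.synapses["source_neuron_id"] != res.synapses["target_neuron_id"]
        ).all()

    def test_huge_contact_radius_occupies_every_terminal(self):
        cfg = get_layout("static-1D-1row-2or", total_steps=60, density_min=2.0)
        params = SimulationParams(0.8, 100.0, 60, accept_prob=1.0)
        res = run_instance(cfg, params, 0)
        assert res.occupancy == 1.0
        # everyone connects shortly after first leaving their parent area
        assert res.synapses["time_step"].max() <= 30

    def test_neuron_to_neuron_connection_probability_decays_with_distance(self):
        # uniform-density strip; bin synapse probability by soma distance
        sheet = toy_sheet(n_areas=10, n_per_area=9)
        params = SimulationParams(0.5, 0.05, 200, accept_prob=0.9)
        state = toy_state(sheet, params)
        rng = np.random.default_rng(5)
        for t in range(1, 201):
            extend_unoccupied_terminals(state, params, rng)
            attempt_synapses(state, params, rng, t)
        n = state.n_alive
        soma = state.soma[:n]
        syn = np.array([(s, t) for s, t, _ in state.synapses])
        d_all = np.linalg.norm(soma[:, None] - soma[None, :], axis=2)
        d_syn = np.linalg.norm(soma[syn[:, 0]] - soma[syn[:, 1]], axis=1)
        bins = np.linspace(0, d_all.max() + 1e-9, 6)
        p = []
        for lo, hi in zip(bins[:-1], bins[1:]):
            pairs = ((d_all >= lo) & (d_all < hi)).sum()
            hits = ((d_syn >= lo) & (d_syn < hi)).sum()
            if pairs:
                p.append(hits / pairs)
        from scipy.stats import spearmanr

        rho = spearmanr(np.arange(len(p)), p).statistic
        assert rho < -0.8  # strong monotone decay

    def test_occupancy_is_monotone_in_contact_radius_toward_zero(self):
        cfg = get_layout("static-1D-1row-2or", total_steps=60, density_min=4.0)
        tiny = run_instance(cfg, SimulationParams(0.8, 1e-6, 60), 0)
        assert tiny.occupancy == pytest.approx(0.0)
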