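"""Spatial tube model: configuration, the seven sub-steps, conservation and
determinism properties."""

import numpy as np
import pytest

from gutflux.network import (CrowdingSampler, MetabolicNetwork, Metabolite,
                             Reaction, build_toy_network, split_reversible)
from gutflux.spatial import (Cell, ConfigError, GridState, SpatialConfig,
                             advection_step, death_step, diffusion_step,
                             division_mutation_step, init_grid, max_neighbours,
                             meal_input, metabolism_step, movement_step,
                             run_spatial, take_snapshot)


class QueuedRng:
    """Deterministic stand-in for a Generator: .random() pops queued values
    (then returns 1.0, i.e. 'event does not happen')."""

    def __init__(self, values=()):
        self.queue = list(values)

    def random(self, size=None):
        if size is not None:
            return np.array([self.random() for _ in range(size)])
        return self.queue.pop(0) if self.queue else 1.0

    def normal(self, loc=0.0, scale=1.0, size=None):
        if size is not None:
            return np.full(size, loc)
        return loc

    def integers(self, n):
        return 0

    def permutation(self, n):
        return np.arange(n)


def small_cfg(**kw):
    kw.setdefault("grid_length", 6)
    kw.setdefault("grid_height", 3)
    kw.setdefault("t_end_h", 1.0)
    return SpatialConfig(**kw)


@pytest.fixture(scope="module")
def base_net():
    return split_reversible(build_toy_network())


def put_cell(state, r, c, s, net, volume=1.0):
    n_ext = len(state.ext_ids)
    cell = Cell(net.copy(), volume, np.zeros(n_ext), np.zeros(n_ext))
    state.cells[r, c, s] = cell
    return cell


class TestConfig:
    def test_default_diffusion_number(self):
        assert SpatialConfig().diffusion_number == pytest.approx(0.0252)

    def test_stability_guard(self):
        with pytest.raises(ConfigError, match="unstable"):
            SpatialConfig(diffusion_um2_s=14000.0 * 11)

    def test_transit_time_and_step_count(self):
        cfg = SpatialConfig()
        assert cfg.transit_time_h == pytest.approx(37.5)
        assert cfg.n_steps == 80000
        assert cfg.steps_per_drift == 5
        assert cfg.steps_per_food == 160

    def test_from_mapping_table_names(self):
        cfg = SpatialConfig.from_mapping({
            "DENS_MAX": 2.0, "TIME_FOOD": 4.0, "FOOD_IN": 10.0,
            "P_MOVECELL": 0.1, "DEATH_BASAL": 0.05, "DEATH_DENS": 1.0,
            "TIME_DRIFT": 30.0, "P_CELL_FLOW": 0.5, "μ_DEL": 0.01,
            "mu_BIRTH": 0.001, "grid_length": 10, "Grid_Height": 4,
        })
        assert cfg.dens_max == 2.0
        assert cfg.time_food_h == 4.0
        assert cfg.mu_del == 0.01
        assert cfg.p_cell_flow == 0.5
        assert cfg.time_drift_min == 30.0

    def test_from_mapping_unknown_keys_listed(self):
        with pytest.raises(ConfigError, match="FOOD_OUT"):
            SpatialConfig.from_mapping({"FOOD_OUT": 1})

    def test_probability_validation(self):
        with pytest.raises(ConfigError, match="probability"):
            SpatialConfig(p_movecell=1.5)


class TestInitGrid:
    def test_occupancy_extremes(self, base_net):
        rng = np.random.default_rng(0)
        sampler = CrowdingSampler(seed=0)
        empty = init_grid(small_cfg(initial_occupancy=0.0), base_net, sampler, rng)
        assert empty.n_cells == 0
        full = init_grid(small_cfg(initial_occupancy=1.0), base_net, sampler, rng)
        assert full.n_cells == 6 * 3 * 2

    def test_occupancy_binomial(self, base_net):
        """Pooled occupied-slot count over seeds stays inside the binomial
        99% interval."""
        from scipy.stats import binom

        cfg = small_cfg(grid_length=10, grid_height=4)  # 80 slots
        counts = []
        for seed in range(10):
            state = init_grid(cfg, base_net, CrowdingSampler(seed=seed),
                              np.random.default_rng(seed))
            counts.append(state.n_cells)
        n, p = 80 * 10, 0.5
        lo, hi = binom.ppf(0.005, n, p), binom.ppf(0.995, n, p)
        assert lo <= sum(counts) <= hi

    def test_initial_cells_full_genome_unit_volume(self, base_net):
        state = init_grid(small_cfg(initial_occupancy=1.0), base_net,
                          CrowdingSampler(seed=1), np.random.default_rng(1))
        for _, cell in state.iter_cells():
            assert cell.volume == 1.0
            assert cell.genome_size() == base_net.genome_size()
        assert np.all(state.conc == 0.0)


class TestMealInput:
    def test_uniform_entry_column(self, base_net):
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        rng = np.random.default_rng(0)
        meal_input(state, cfg, rng)
        j = state.ext_index["glc"]
        entry = state.conc[j, :, 0]
        assert np.allclose(entry, entry[0])
        assert np.all(state.conc[j, :, 1:] == 0.0)
        # amount / (height * patch_volume)
        assert entry[0] == pytest.approx(state.food_in_total[j]
                                         / (cfg.grid_height * cfg.patch_volume_l))

    def test_draw_statistics(self, base_net):
        cfg = SpatialConfig()
        state = GridState(cfg, base_net)
        rng = np.random.default_rng(42)
        for _ in range(1000):
            meal_input(state, cfg, rng)
        j = state.ext_index["glc"]
        mean = state.food_in_total[j] / 1000
        se = 0.2 * 42.0 / np.sqrt(1000)
        assert abs(mean - 42.0) < 3 * se

    def test_truncation_redraws_negatives(self, base_net):
        cfg = small_cfg(food_in_mmol=0.1, food_rel_sd=50.0)  # mostly negative draws
        state = GridState(cfg, base_net)
        meal_input(state, cfg, np.random.default_rng(0))
        assert np.all(state.conc >= 0.0)


class TestMetabolismStep:
    def test_empty_patch_unchanged(self, base_net):
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        state.conc[state.ext_index["glc"], :, :] = 3.0
        before = state.conc.copy()
        metabolism_step(state, cfg)
        assert np.array_equal(state.conc, before)

    def test_excretion_update_matches_hand_formula(self, base_net):
        """A known-flux cell: with no crowding and glucose available at cap,
        dc = dt * F * V * DENS_MAX / 4 for each exchanged metabolite."""
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        j_glc = state.ext_index["glc"]
        state.conc[j_glc, 0, 0] = 1.0
        cell = put_cell(state, 0, 0, 0, base_net, volume=1.0)
        cell.net.crowding[:] = 0.0  # uptake-cap limited
        c_before = state.conc[:, 0, 0].copy()
        metabolism_step(state, cfg)
        # glucose uptake hits the Eq-14 cap exactly: all of it is consumed
        assert state.conc[j_glc, 0, 0] == pytest.approx(0.0, abs=1e-9)
        # every concentration change equals the ledger entry for this cell
        delta = state.conc[:, 0, 0] - c_before
        ledger_net = cell.ledger_excretion - cell.ledger_uptake
        free = state.free_mask
        assert np.allclose(delta[~free], ledger_net[~free], atol=1e-9)

    def test_uptake_never_exceeds_available(self, base_net):
        """Eq-14 caps bind: high biomass on low concentrations never drives
        a concentration negative."""
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        rng = np.random.default_rng(3)
        state.conc[...] = rng.uniform(0, 1e-3, size=state.conc.shape)
        sampler = CrowdingSampler(seed=3)
        for r in range(cfg.grid_height):
            for c in range(cfg.grid_length):
                for s in range(2):
                    from gutflux.network import sample_crowding
                    put_cell(state, r, c, s,
                             sample_crowding(base_net, sampler, rng), volume=2.0)
        metabolism_step(state, cfg)
        assert np.all(state.conc >= 0.0)

    def test_volume_growth(self, base_net):
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        state.conc[state.ext_index["glc"], 0, 0] = 50.0
        cell = put_cell(state, 0, 0, 0, base_net)
        from gutflux.network import sample_crowding
        cell.net.crowding = sample_crowding(base_net, CrowdingSampler(seed=2)).crowding
        v0 = cell.volume
        metabolism_step(state, cfg)
        assert cell.volume > v0


class TestDeathStep:
    def test_max_neighbours_interior_and_edges(self):
        cfg = SpatialConfig()
        assert max_neighbours(cfg, 5, 75) == 17      # interior: 8*2+1
        assert max_neighbours(cfg, 0, 0) == 7        # corner: 3*2+1
        assert max_neighbours(cfg, 0, 75) == 11      # edge: 5*2+1

    def test_isolated_cell_basal_probability(self, base_net):
        """Isolated interior cell: rate 0.025 h^-1, p = 0.00125 per 0.05 h
        step — dies iff the uniform draw is below p."""
        cfg = small_cfg()
        p = cfg.death_basal * cfg.dt_h
        for draw, survives in ((p * 1.01, True), (p * 0.99, False)):
            state = GridState(cfg, base_net)
            put_cell(state, 1, 3, 0, base_net)
            death_step(state, cfg, QueuedRng([draw]))
            assert (state.cells[1, 3, 0] is not None) is survives

    def test_crowded_cell_rate(self, base_net):
        """Interior cell with all 17 neighbour slots occupied: rate
        0.025 + 2.0 = 2.025 h^-1."""
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        for r in (0, 1, 2):
            for c in (2, 3, 4):
                for s in (0, 1):
                    put_cell(state, r, c, s, base_net)
        p = 2.025 * cfg.dt_h
        rng = QueuedRng()
        # all cells survive except the focal one, probed just under its rate
        draws = []
        for (r, c, s), _ in state.iter_cells():
            draws.append(p * 0.99 if (r, c, s) == (1, 3, 0) else 0.999999)
        rng.queue = draws
        death_step(state, cfg, rng)
        assert state.cells[1, 3, 0] is None

    def test_density_independent_when_dens_zero(self, base_net):
        cfg = small_cfg(death_dens=0.0)
        state = GridState(cfg, base_net)
        for s in (0, 1):
            for c in range(6):
                put_cell(state, 1, c, s, base_net)
        p = cfg.death_basal * cfg.dt_h
        n = state.n_cells
        death_step(state, cfg, QueuedRng([p * 0.5] * n))
        assert state.n_cells == 0  # uniform basal rate killed everyone


class TestDivisionMutation:
    def test_equal_split_above_threshold(self, base_net):
        cfg = small_cfg(mu_del=0.0, mu_birth=0.0, mu_point=0.0)
        state = GridState(cfg, base_net)
        cell = put_cell(state, 0, 0, 0, base_net, volume=2.1)
        cell.ledger_uptake[:] = 4.0
        division_mutation_step(state, cfg, np.random.default_rng(0))
        daughter = state.cells[0, 0, 1]
        assert daughter is not None
        assert cell.volume == pytest.approx(1.05)
        assert daughter.volume == pytest.approx(1.05)
        assert np.allclose(cell.ledger_uptake, 2.0)
        assert np.allclose(daughter.ledger_uptake, 2.0)
        # zero mutation probabilities: genomes identical
        assert np.array_equal(cell.net.ub, daughter.net.ub)
        assert np.array_equal(cell.net.crowding, daughter.net.crowding)

    def test_full_patch_clamps_volume(self, base_net):
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        cell = put_cell(state, 0, 0, 0, base_net, volume=2.5)
        put_cell(state, 0, 0, 1, base_net, volume=1.0)
        division_mutation_step(state, cfg, np.random.default_rng(0))
        assert cell.volume == 2.0

    def test_certain_deletion_zeroes_mutable_bounds(self, base_net):
        cfg = small_cfg(mu_del=1.0, mu_birth=0.0, mu_point=0.0)
        state = GridState(cfg, base_net)
        cell = put_cell(state, 0, 0, 0, base_net, volume=2.0)
        division_mutation_step(state, cfg, np.random.default_rng(0))
        net = cell.net
        mutable = ~net.structure.exchange_mask
        mutable[net.objective_index] = False
        assert np.all(net.ub[mutable] == 0.0)
        # exchange reactions and the objective never mutate
        assert np.all(net.ub[net.structure.exchange_mask] > 0.0)
        assert net.ub[net.objective_index] > 0.0

    def test_zero_step_point_mutation_is_identity(self, base_net):
        cfg = small_cfg(mu_del=0.0, mu_birth=0.0, mu_point=1.0,
                        mu_point_step=0.0)
        state = GridState(cfg, base_net)
        cell = put_cell(state, 0, 0, 0, base_net, volume=2.0)
        a_before = cell.net.crowding.copy()
        division_mutation_step(state, cfg, np.random.default_rng(0))
        assert np.allclose(cell.net.crowding, a_before)  # a * 10^0 = a

    def test_reintroduction_restores_bound(self, base_net):
        cfg = small_cfg(mu_del=0.0, mu_birth=1.0, mu_point=0.0)
        state = GridState(cfg, base_net)
        cell = put_cell(state, 0, 0, 0, base_net, volume=2.0)
        mutable = ~cell.net.structure.exchange_mask
        mutable[cell.net.objective_index] = False
        cell.net.ub[mutable] = 0.0
        division_mutation_step(state, cfg, np.random.default_rng(0))
        assert np.all(cell.net.ub[mutable] == 999999.0)


class TestMovement:
    def test_no_movement_at_zero_probability(self, base_net):
        cfg = small_cfg(p_movecell=0.0)
        state = GridState(cfg, base_net)
        put_cell(state, 1, 1, 0, base_net)
        movement_step(state, cfg, np.random.default_rng(0))
        assert state.cells[1, 1, 0] is not None

    def test_count_conserved_and_positions_spread(self, base_net):
        cfg = small_cfg(p_movecell=1.0)
        state = GridState(cfg, base_net)
        put_cell(state, 1, 2, 0, base_net)
        rng = np.random.default_rng(7)
        positions = set()
        for _ in range(30):
            movement_step(state, cfg, rng)
            locs = [(r, c, s) for (r, c, s), _ in state.iter_cells()]
            assert len(locs) == 1
            positions.add(locs[0])
        assert len(positions) > 3  # the cell actually wanders


class TestAdvection:
    def test_column_shift_and_outflow(self, base_net):
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        j = state.ext_index["glc"]
        state.conc[j, :, 2] = 5.0
        state.conc[j, :, -1] = 7.0
        advection_step(state, cfg, np.random.default_rng(0))
        assert np.all(state.conc[j, :, 3] == 5.0)
        assert np.all(state.conc[j, :, 2] == 0.0)
        assert np.all(state.conc[j, :, 0] == 0.0)
        assert state.advected_out_total[j] == pytest.approx(
            7.0 * cfg.grid_height * cfg.patch_volume_l)

    def test_cells_stay_without_flow(self, base_net):
        cfg = small_cfg(p_cell_flow=0.0)
        state = GridState(cfg, base_net)
        put_cell(state, 0, 4, 0, base_net)
        advection_step(state, cfg, np.random.default_rng(0))
        assert state.cells[0, 4, 0] is not None

    def test_cells_shift_periodically_with_flow(self, base_net):
        cfg = small_cfg(p_cell_flow=1.0)
        state = GridState(cfg, base_net)
        put_cell(state, 0, cfg.grid_length - 1, 0, base_net)  # distal end
        advection_step(state, cfg, np.random.default_rng(0))
        assert state.cells[0, 0, 0] is not None  # re-entered proximally
        assert state.n_cells == 1


class TestDiffusion:
    def test_uniform_field_unchanged(self, base_net):
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        state.conc[...] = 2.5
        diffusion_step(state, cfg)
        assert np.allclose(state.conc, 2.5)

    def test_interior_delta_one_step(self, base_net):
        cfg = SpatialConfig(grid_length=10, grid_height=5, t_end_h=1.0)
        state = GridState(cfg, base_net)
        j = state.ext_index["glc"]
        state.conc[j, 2, 5] = 1.0
        diffusion_step(state, cfg)
        assert state.conc[j, 2, 5] == pytest.approx(1 - 4 * 0.0252)

    def test_closed_grid_mole_conservation(self, base_net):
        cfg = small_cfg()
        state = GridState(cfg, base_net)
        rng = np.random.default_rng(5)
        state.conc[...] = rng.uniform(0, 10, size=state.conc.shape)
        before = state.conc.sum(axis=(1, 2))
        for _ in range(20):
            diffusion_step(state, cfg)
        after = state.conc.sum(axis=(1, 2))
        assert np.allclose(after, before, rtol=1e-12, atol=1e-12)


class TestRunSpatial:
    def test_zero_occupancy_pure_transport(self, base_net):
        cfg = SpatialConfig.scaled_down(seed=2, t_end_h=4.0,
                                        initial_occupancy=0.0)
        res = run_spatial(cfg, base_net=base_net, snapshot_every_h=1.0)
        assert res.final.n_cells == 0
        j = res.final.ext_index["glc"]
        # glucose entered and only left via advection; none consumed
        assert res.final.food_in_total[j] > 0
        total_in = res.final.food_in_total[j]
        in_tube = res.final.total_moles()[j]
        out = res.final.advected_out_total[j]
        assert in_tube + out == pytest.approx(total_in, rel=1e-9)

    def test_mole_audit_with_cells(self, base_net):
        """Global audit: meals in = in tube + advected out (cells exchange
        zero net carbon per solve but do exchange individual metabolites, so
        the audit is on total carbon)."""
        cfg = SpatialConfig.scaled_down(seed=3, t_end_h=6.0)
        res = run_spatial(cfg, base_net=base_net, snapshot_every_h=2.0)
        st = res.final
        cc = np.array([base_net.metabolites[base_net.met_index[m]].carbon_count
                       for m in st.ext_ids], dtype=float)
        free = st.free_mask
        carbon_in = float((st.food_in_total * cc)[~free].sum())
        carbon_tube = float((st.total_moles() * cc)[~free].sum())
        carbon_out = float((st.advected_out_total * cc)[~free].sum())
        assert carbon_tube + carbon_out == pytest.approx(carbon_in, rel=1e-6)

    def test_seeded_bit_reproducibility(self, base_net):
        cfg1 = SpatialConfig.scaled_down(seed=4, t_end_h=5.0)
        cfg2 = SpatialConfig.scaled_down(seed=4, t_end_h=5.0)
        r1 = run_spatial(cfg1, base_net=base_net, snapshot_every_h=1.0)
        r2 = run_spatial(cfg2, base_net=base_net, snapshot_every_h=1.0)
        assert r1.final.digest() == r2.final.digest()

    def test_different_seed_different_trajectory(self, base_net):
        r1 = run_spatial(SpatialConfig.scaled_down(seed=5, t_end_h=3.0),
                         base_net=base_net, snapshot_every_h=1.0)
        r2 = run_spatial(SpatialConfig.scaled_down(seed=6, t_end_h=3.0),
                         base_net=base_net, snapshot_every_h=1.0)
        assert r1.final.digest() != r2.final.digest()

    def test_genome_size_monotone_without_reintroduction(self, base_net):
        """With mu_BIRTH = 0 the population's maximum genome size can never
        increase (deletions only)."""
        cfg = SpatialConfig.scaled_down(seed=7, t_end_h=30.0, mu_birth=0.0,
                                        mu_del=0.05)
        res = run_spatial(cfg, base_net=base_net, snapshot_every_h=2.0)
        maxima = [max(s.cell_genome_sizes) for s in res.snapshots
                  if s.cell_genome_sizes]
        assert all(b <= a for a, b in zip(maxima, maxima[1:]))
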