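"""Stand life cycle and scenario engine."""

import numpy as np
import pytest

from mangrove_growth.io import RasterLayer
from mangrove_growth.simulator import (
    ScenarioConfig,
    initialize,
    run_scenario,
    step_year,
)
from mangrove_growth.synthetic import RasterGeneratorConfig, generate_rasters


def small_layers(seed=0, shape=(8, 8)):
    return generate_rasters(RasterGeneratorConfig(shape=shape, seed=seed))


def uniform_layers(shape=(2, 2), salinity=10.0, elevation=0.2, root_cr=60.0):
    """Spatially constant layers for controlled comparisons."""
    mk = lambda v, kind: RasterLayer(values=np.full(shape, v), kind=kind)
    return {
        "salinity": mk(salinity, "salinity"),
        "elevation": mk(elevation, "elevation"),
        "root_cr": mk(root_cr, "root_cr"),
        "forest_mask": mk(1.0, "forest_mask"),
    }


class TestInitialize:
    def test_deterministic_under_seed(self):
        mask = RasterLayer(values=np.ones((1, 1)), kind="forest_mask")
        cfg = ScenarioConfig(seed=7)
        a = initialize(mask, cfg)
        b = initialize(mask, cfg)
        assert np.array_equal(a.count, b.count)
        assert a.count[0] == a.density_per_plot()[0] * a.plots_per_cell

    def test_density_distribution_mean(self):
        """1000 cells: mean per-plot density within U{10..115} mean +/- 3 SE."""
        mask = RasterLayer(values=np.ones((25, 40)), kind="forest_mask")
        state = initialize(mask, ScenarioConfig(seed=1))
        dens = state.density_per_plot()
        mu = (10 + 115) / 2
        se = np.sqrt(((115 - 10 + 1) ** 2 - 1) / 12 / dens.size)
        assert abs(dens.mean() - mu) < 3 * se

    def test_empty_mask_rejected(self):
        mask = RasterLayer(values=np.zeros((3, 3)), kind="forest_mask")
        with pytest.raises(ValueError):
            initialize(mask, ScenarioConfig(seed=0))

    def test_seedlings_start_at_dbh0(self):
        mask = RasterLayer(values=np.ones((2, 2)), kind="forest_mask")
        cfg = ScenarioConfig(seed=0, dbh0=0.5)
        state = initialize(mask, cfg)
        assert np.all(state.dbh == 0.5) and np.all(state.age == 0)


class TestStepYear:
    def test_favourable_cell_outgrows_stressed_cell(self, sp, mp):
        """Identical stands, same seed: low salinity + plateau elevation beats
        high salinity + marginal elevation after 10 years."""
        good = uniform_layers(shape=(1, 1), salinity=8.0, elevation=0.2)
        poor = uniform_layers(shape=(1, 1), salinity=18.0, elevation=-0.6)
        cfg = ScenarioConfig(name="SC0", seed=4)
        sg = initialize(good["forest_mask"], cfg, np.random.default_rng(4))
        sp_state = initialize(poor["forest_mask"], cfg, np.random.default_rng(4))
        rng_a, rng_b = np.random.default_rng(9), np.random.default_rng(9)
        for _ in range(10):
            sg = step_year(sg, good, cfg, mp, sp, rng_a)
            sp_state = step_year(sp_state, poor, cfg, mp, sp, rng_b)
        mean_g = np.average(sg.dbh, weights=sg.count)
        mean_p = np.average(sp_state.dbh, weights=sp_state.count)
        assert mean_g > mean_p

    def test_pollution_reduces_biomass_in_expectation(self, sp, mp):
        """Unpolluted vs doubled load on identical maps, paired seeds."""
        layers = uniform_layers(shape=(2, 2), root_cr=60.0)
        diffs = []
        for s in range(8):
            tot = {}
            for name in ("SC0", "SC0P2"):
                cfg = ScenarioConfig(name=name, seed=50 + s, end_year=1978 + 15)
                state = initialize(layers["forest_mask"], cfg,
                                   np.random.default_rng(cfg.seed))
                rng = np.random.default_rng(cfg.seed + 1)
                for _ in range(15):
                    state = step_year(state, layers, cfg, mp, sp, rng)
                tot[name] = state.biomass_per_cell(sp).sum()
            diffs.append(tot["SC0"] - tot["SC0P2"])
        assert np.mean(diffs) > 0

    def test_empty_cell_stays_empty_without_recruitment(self, sp, mp):
        layers = uniform_layers(shape=(1, 1))
        cfg = ScenarioConfig(seed=0, m0=1.0)  # kill everything in year 1
        state = initialize(layers["forest_mask"], cfg, np.random.default_rng(0))
        rng = np.random.default_rng(1)
        state = step_year(state, layers, cfg, mp, sp, rng, recruitment=False)
        assert state.count.sum() == 0
        state = step_year(state, layers, cfg, mp, sp, rng, recruitment=False)
        assert state.count.sum() == 0

    def test_dbh_never_exceeds_dmax(self, sp, mp):
        layers = uniform_layers(shape=(1, 1), salinity=0.0, elevation=0.15)
        cfg = ScenarioConfig(seed=0, end_year=1978 + 60)
        state = initialize(layers["forest_mask"], cfg, np.random.default_rng(0))
        rng = np.random.default_rng(2)
        for _ in range(60):
            state = step_year(state, layers, cfg, mp, sp, rng)
            assert np.all(state.dbh <= sp.Dmax + 1e-9)
            assert np.all(state.count >= 0)


class TestRunScenario:
    def test_zero_year_run_config_rejected(self):
        with pytest.raises(ValueError):
            ScenarioConfig(start_year=2020, end_year=2020)

    def test_requires_forest_mask(self, sp, mp):
        layers = small_layers()
        del layers["forest_mask"]
        with pytest.raises(ValueError, match="forest_mask"):
            run_scenario(layers, ScenarioConfig(seed=0), mp, sp)

    def test_mismatched_layer_shapes_rejected(self, sp, mp):
        layers = small_layers()
        layers["salinity"] = RasterLayer(values=np.ones((3, 3)), kind="salinity")
        with pytest.raises(ValueError, match="shape"):
            run_scenario(layers, ScenarioConfig(seed=0), mp, sp)

    def test_bit_identical_under_seed(self, sp, mp):
        layers = small_layers(seed=2)
        cfg = ScenarioConfig(name="SC0P1", seed=42, end_year=1978 + 12)
        a = run_scenario(layers, cfg, mp, sp)
        b = run_scenario(layers, cfg, mp, sp)
        assert np.array_equal(a.final_biomass_per_cell, b.final_biomass_per_cell)
        assert np.array_equal(a.total_biomass_tons, b.total_biomass_tons)

    def test_area_weight_scales_totals_linearly(self, sp, mp):
        layers = small_layers(seed=2)
        cfg = ScenarioConfig(seed=3, end_year=1978 + 8)
        t1 = run_scenario(layers, cfg, mp, sp, area_weight=1.0).final_total_tons
        t2 = run_scenario(layers, cfg, mp, sp, area_weight=2.0).final_total_tons
        assert t2 == pytest.approx(2 * t1, rel=1e-12)

    def test_scenario_ordering_short_run(self, sp, mp):
        """Totals ordered SC0 >= SC0P1 >= SC0P2 on average over seeds."""
        layers = small_layers(seed=5)
        tots = {n: [] for n in ("SC0", "SC0P1", "SC0P2")}
        for s in range(5):
            for n in tots:
                cfg = ScenarioConfig(name=n, seed=200 + s, end_year=1978 + 20)
                tots[n].append(run_scenario(layers, cfg, mp, sp).final_total_tons)
        m = {n: np.mean(v) for n, v in tots.items()}
        assert m["SC0"] > m["SC0P1"] > m["SC0P2"]

    def test_snapshots_and_histogram_shapes(self, sp, mp):
        layers = small_layers(seed=6)
        cfg = ScenarioConfig(seed=1, end_year=1978 + 8, snapshot_count=4)
        res = run_scenario(layers, cfg, mp, sp, hist_bins=10)
        assert len(res.snapshots) == 4
        counts, edges = res.histogram
        assert len(counts) == 10 and len(edges) == 11
        for grid in res.snapshots.values():
            assert grid.shape == layers["forest_mask"].shape
        assert np.all(res.final_biomass_per_cell >= 0)
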