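"""Growth-rate extraction, parameter estimation and validation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from mangrove_growth.extraction import (
    DegenerateDesignError,
    InfeasibleError,
    extract_G,
    extract_G_frame,
    fit_multipliers,
    fit_pollutant,
    stratified_split,
    validate,
)
from mangrove_growth.growth import grow_tree
from mangrove_growth.multipliers import pollutant_multiplier
from mangrove_growth.synthetic import SurveyGeneratorConfig, generate_inventory


class TestExtractG:
    def test_no_growth_returns_zero_with_warning(self, sp):
        with pytest.warns(UserWarning):
            assert extract_G(5.0, 5.0, 10, sp) == 0.0

    def test_unreachable_diameter_rejected(self, sp):
        with pytest.raises(InfeasibleError):
            extract_G(0.5, sp.Dmax, 30, sp)

    def test_bad_inputs(self, sp):
        with pytest.raises(ValueError):
            extract_G(0.5, 10.0, 0, sp)
        with pytest.raises(ValueError):
            extract_G(0.0, 10.0, 10, sp)

    def test_forward_simulation_round_trip(self, sp):
        """grow_tree at G = 250 for 30 yr, then extract_G on the endpoint."""
        traj = grow_tree(0.5, 30, sp, mul=250.0 / sp.Gopt)
        assert extract_G(0.5, traj[-1], 30, sp) == pytest.approx(250.0, abs=1e-4 * 250)

    @given(
        g=st.floats(30.0, 390.0),
        years=st.integers(5, 45),
        dbh0=st.floats(0.2, 2.0),
    )
    def test_round_trip_identity_property(self, sp, g, years, dbh0):
        traj = grow_tree(dbh0, years, sp, mul=g / sp.Gopt)
        assert extract_G(dbh0, traj[-1], years, sp) == pytest.approx(g, rel=1e-4)

    def test_strictly_increasing_in_final_diameter(self, sp):
        targets = np.linspace(2.0, 45.0, 25)
        gs = [extract_G(0.5, t, 30, sp) for t in targets]
        assert np.all(np.diff(gs) > 0)


def _inventory(seed=0, sigma=0.05, n=208):
    from mangrove_growth.params import load_params
    sp, mp, _ = load_params()
    cfg = SurveyGeneratorConfig(seed=seed, sigma=sigma, n_plots=n)
    inv = generate_inventory(cfg, sp, mp)
    return inv, sp, mp


class TestFit:
    def test_noiseless_parameter_recovery(self):
        """Generating thresholds are recovered from noise-free plots."""
        inv, sp, mp = _inventory(seed=5, sigma=0.0)
        inv["G_extracted"] = inv["G_true"]
        res = fit_multipliers(inv, sp, mp, seed=5)
        est = dict(zip(res.free_names, res.param_values))
        assert est["salinity.tr"] == pytest.approx(mp.salinity.tr, rel=1e-3)
        assert est["density.tr"] == pytest.approx(mp.density.tr, rel=1e-3)
        assert est["gopt"] == pytest.approx(sp.Gopt, rel=1e-3)
        assert res.r_squared > 0.999999

    def test_degenerate_covariate_is_named(self):
        inv, sp, mp = _inventory(seed=6, n=40)
        inv["salinity"] = 12.0
        inv["G_extracted"] = inv["G_true"]
        with pytest.raises(DegenerateDesignError, match="salinity"):
            fit_multipliers(inv, sp, mp, seed=0)

    def test_too_few_plots_rejected(self):
        inv, sp, mp = _inventory(seed=7, n=5)
        inv["G_extracted"] = inv["G_true"]
        with pytest.raises(ValueError):
            fit_multipliers(inv, sp, mp)

    def test_standard_errors_reported(self):
        inv, sp, mp = _inventory(seed=8)
        inv["G_extracted"] = extract_G_frame(inv, sp)
        res = fit_multipliers(inv, sp, mp, seed=8)
        assert res.param_se is not None
        assert len(res.param_se) == len(res.free_names)
        assert np.all(res.param_se >= 0)


class TestPollutantFit:
    def test_noiseless_dose_response_recovery(self, mp):
        p_true = mp.pollutants["Cr"]
        x = np.logspace(-1, 2.5, 60)
        y = pollutant_multiplier(x, p_true)
        est = fit_pollutant(x, y, "Cr", seed=1)
        assert pollutant_multiplier(30.0, est) == pytest.approx(
            pollutant_multiplier(30.0, p_true), rel=1e-3)
        assert est.th2 == pytest.approx(p_true.th2, rel=0.05)


class TestValidate:
    def test_perfect_fit_on_training_data(self):
        inv, sp, mp = _inventory(seed=9, sigma=0.0)
        inv["G_extracted"] = inv["G_true"]
        res = fit_multipliers(inv, sp, mp, seed=9)
        val = validate(inv, res, sp)
        assert val.r_squared == pytest.approx(1.0, abs=1e-4)

    def test_shuffled_labels_destroy_skill(self):
        """Negative control: permuting environments across plots kills R^2."""
        inv, sp, mp = _inventory(seed=10)
        inv["G_extracted"] = inv["G_true"]
        res = fit_multipliers(inv, sp, mp, seed=10)
        rng = np.random.default_rng(0)
        shuffled = inv.copy()
        shuffled["mean_dbh"] = rng.permutation(shuffled["mean_dbh"].to_numpy())
        val = validate(shuffled, res, sp)
        assert val.r_squared < 0.3

    def test_empty_validation_set_rejected(self):
        inv, sp, mp = _inventory(seed=11, n=20)
        inv["G_extracted"] = inv["G_true"]
        res = fit_multipliers(inv, sp, mp, seed=11)
        with pytest.raises(ValueError):
            validate(inv.iloc[:0], res, sp)


class TestStratifiedSplit:
    def test_sizes_and_disjointness(self):
        inv, _, _ = _inventory(seed=12)
        fit_set, hold = stratified_split(inv, 76, seed=3)
        assert len(fit_set) == 76 and len(hold) == len(inv) - 76
        assert set(fit_set.index).isdisjoint(hold.index)

    def test_fit_subset_spans_gradients(self):
        """Every salinity tercile contributes plots to the fitting subset."""
        inv, _, _ = _inventory(seed=13)
        fit_set, _ = stratified_split(inv, 76, seed=3)
        terciles = inv["salinity"].quantile([1 / 3, 2 / 3]).to_numpy()
        counts = np.histogram(fit_set["salinity"],
                              bins=[-np.inf, *terciles, np.inf])[0]
        assert np.all(counts > 10)

    def test_deterministic_under_seed(self):
        inv, _, _ = _inventory(seed=14)
        a, _ = stratified_split(inv, 76, seed=9)
        b, _ = stratified_split(inv, 76, seed=9)
        assert list(a.index) == list(b.index)


def test_extracted_g_decreases_with_salinity_in_matched_density(sp):
    """Printed-inventory sanity check: within plots of comparable density,
    extracted G falls along the salinity gradient (the negative correlation
    the survey reports)."""
    from mangrove_growth.synthetic import load_reference_tables

    _, plots = load_reference_tables()
    sub = plots[plots["density"] <= 30].sort_values("salinity")
    g = extract_G_frame(sub.rename(columns={"mean_dbh": "mean_dbh"}), sp)
    r = np.corrcoef(sub["salinity"], g)[0, 1]
    assert r < -0.5
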