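"""Mixed-model zonal testing, BH adjustment and reproducibility metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from zonemsi.stats import (
    bh_adjust,
    fit_random_intercept,
    lrt_zone,
    percent_cv,
    replicate_percent_cv,
    zonal_test,
    zonation_table,
)

MICE = np.repeat([f"m{i}" for i in range(5)], 9)
ZONES45 = np.tile(np.repeat(["Z1", "Z2", "Z3"], 3), 5)


def make_table(y):
    return pd.DataFrame({"mouse": MICE, "zone": ZONES45,
                         "median_intensity": y})


def simulate_lipid(rng, zone_effects=(0.0, 0.0), mouse_sd=0.2,
                   resid_sd=0.1, mu=1.0):
    b = rng.normal(0, mouse_sd, 5)
    eta = (mu + b[np.repeat(np.arange(5), 9)]
           + np.select([ZONES45 == "Z2", ZONES45 == "Z3"],
                       zone_effects, 0.0)
           + rng.normal(0, resid_sd, 45))
    return make_table(np.exp(eta))


class TestRandomInterceptFit:
    def test_matches_ols_when_no_mouse_variance(self):
        """When the ML variance ratio hits the zero boundary (no mouse
        variance generated), the fit collapses exactly to OLS."""
        rng = np.random.default_rng(2)
        tab = simulate_lipid(rng, zone_effects=(0.4, 0.8), mouse_sd=0.0,
                             resid_sd=0.15)
        fit = fit_random_intercept(tab, include_zone=True)
        y = np.log(tab["median_intensity"].to_numpy())
        X = np.column_stack([np.ones(45), ZONES45 == "Z2", ZONES45 == "Z3"])
        beta_ols, *_ = np.linalg.lstsq(X.astype(float), y, rcond=None)
        assert fit.var_mouse < 0.01 * fit.var_resid
        for est, ols in zip(fit.fixed_effects.values(), beta_ols):
            assert est == pytest.approx(ols, abs=1e-6)

    def test_parameter_recovery_over_many_lipids(self):
        """Mean estimates over 200 simulated lipids land within 15% of
        their ML expectations at n = 5 mice (the between-mouse variance
        carries the known ML shrinkage factor (g − 1)/g)."""
        rng = np.random.default_rng(1)
        g = 5
        true = {"var_mouse": 0.04, "var_resid": 0.01,
                "z2": 0.30, "z3": 0.60}
        expected = dict(true, var_mouse=true["var_mouse"] * (g - 1) / g)
        est = {"var_mouse": [], "var_resid": [], "z2": [], "z3": []}
        for _ in range(200):
            tab = simulate_lipid(rng, zone_effects=(true["z2"], true["z3"]),
                                 mouse_sd=np.sqrt(true["var_mouse"]),
                                 resid_sd=np.sqrt(true["var_resid"]))
            fit = fit_random_intercept(tab, include_zone=True)
            est["var_mouse"].append(fit.var_mouse)
            est["var_resid"].append(fit.var_resid)
            est["z2"].append(fit.fixed_effects["Z2-Z1"])
            est["z3"].append(fit.fixed_effects["Z3-Z1"])
        for key, target in expected.items():
            assert abs(np.mean(est[key]) - target) < 0.15 * target

    def test_location_equivariance(self):
        rng = np.random.default_rng(2)
        tab = simulate_lipid(rng, zone_effects=(0.2, 0.5))
        fit = fit_random_intercept(tab, include_zone=True)
        shifted = tab.copy()
        shifted["median_intensity"] *= np.e  # +1 on the log scale
        fit2 = fit_random_intercept(shifted, include_zone=True)
        assert fit2.fixed_effects["intercept"] == pytest.approx(
            fit.fixed_effects["intercept"] + 1.0, abs=1e-6)
        assert fit2.var_mouse == pytest.approx(fit.var_mouse, abs=1e-8)
        assert fit2.var_resid == pytest.approx(fit.var_resid, abs=1e-8)

    def test_agrees_with_statsmodels_mixedlm(self):
        """Independent ML fit via statsmodels reproduces the likelihood
        and fixed effects."""
        import statsmodels.formula.api as smf
        rng = np.random.default_rng(3)
        tab = simulate_lipid(rng, zone_effects=(0.3, 0.6))
        tab = tab.assign(logy=np.log(tab["median_intensity"]))
        sm_fit = smf.mixedlm("logy ~ C(zone)", tab,
                             groups=tab["mouse"]).fit(reml=False)
        fit = fit_random_intercept(tab, include_zone=True)
        assert fit.loglik_ml == pytest.approx(sm_fit.llf, abs=1e-3)
        assert fit.fixed_effects["intercept"] == pytest.approx(
            sm_fit.params["Intercept"], abs=1e-4)
        assert fit.fixed_effects["Z2-Z1"] == pytest.approx(
            sm_fit.params["C(zone)[T.Z2]"], abs=1e-4)

    def test_nonpositive_intensity_directs_to_pseudocount(self):
        tab = make_table(np.zeros(45))
        with pytest.raises(ValueError, match="pseudo-count"):
            fit_random_intercept(tab)


class TestLrt:
    def test_zero_statistic_gives_p_one(self):
        assert chi2.sf(0.0, 2) == 1.0
        rng = np.random.default_rng(4)
        tab = simulate_lipid(rng)
        full = fit_random_intercept(tab, True)
        null = fit_random_intercept(tab, False)
        chisq, p = lrt_zone(full, null)
        assert chisq >= 0 and 0 < p <= 1

    def test_critical_value_of_chi_square_2df(self):
        assert chi2.sf(5.991, 2) == pytest.approx(0.050, abs=5e-4)

    def test_scale_invariance_of_p(self):
        rng = np.random.default_rng(5)
        tab = simulate_lipid(rng, zone_effects=(0.3, 0.1))
        p1 = lrt_zone(fit_random_intercept(tab, True),
                      fit_random_intercept(tab, False))[1]
        scaled = tab.copy()
        scaled["median_intensity"] *= 37.5
        p2 = lrt_zone(fit_random_intercept(scaled, True),
                      fit_random_intercept(scaled, False))[1]
        assert p1 == pytest.approx(p2, rel=1e-6)

    def test_mismatched_fits_rejected(self):
        rng = np.random.default_rng(6)
        full = fit_random_intercept(simulate_lipid(rng), True)
        with pytest.raises(ValueError):
            lrt_zone(full, full)

    def test_type_one_error_calibrated(self):
        """Empirical size of the zone LRT at nominal 0.05 lies in
        [0.03, 0.08] over 1000 null simulations with 5 mice."""
        rng = np.random.default_rng(7)
        pvals = []
        for _ in range(1000):
            tab = simulate_lipid(rng, zone_effects=(0.0, 0.0),
                                 mouse_sd=0.15, resid_sd=0.06)
            full = fit_random_intercept(tab, True)
            null = fit_random_intercept(tab, False)
            pvals.append(lrt_zone(full, null)[1])
        rate = float(np.mean(np.asarray(pvals) <= 0.05))
        assert 0.03 <= rate <= 0.08


def brute_force_bh(pvalues):
    """Literal step-up definition: q_(i) = min_{j>=i} p_(j) m / j."""
    p = list(pvalues)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    for pos, idx in enumerate(order):
        q[idx] = min(min(p[order[j]] * m / (j + 1)
                         for j in range(pos, m)), 1.0)
    return q


class TestBhAdjust:
    def test_hand_computed_example(self):
        q = bh_adjust([0.005, 0.011, 0.02, 0.04])
        assert np.allclose(q, [0.02, 0.022, 0.0266667, 0.04], atol=1e-6)

    def test_single_p_is_itself(self):
        assert bh_adjust([0.123])[0] == pytest.approx(0.123)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=1, max_size=8))
    @settings(max_examples=200, deadline=None, derandomize=True)
    def test_matches_brute_force_definition(self, pvals):
        assert np.allclose(bh_adjust(pvals), brute_force_bh(pvals),
                           atol=1e-12)

    @given(st.lists(st.floats(min_value=1e-6, max_value=1.0),
                    min_size=1, max_size=8))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_dominates_input_and_capped(self, pvals):
        q = bh_adjust(pvals)
        assert np.all(q >= np.asarray(pvals) - 1e-15)
        assert np.all(q <= 1.0)

    def test_agrees_with_statsmodels(self):
        from statsmodels.stats.multitest import multipletests
        rng = np.random.default_rng(8)
        p = rng.uniform(1e-4, 1, 50)
        expected = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(bh_adjust(p), expected, atol=1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.0, 0.5])


class TestPercentCv:
    def test_nine_ten_eleven_is_ten_percent(self):
        assert percent_cv([9, 10, 11]) == pytest.approx(10.0)

    def test_constant_replicates_zero(self):
        assert percent_cv([5.0, 5.0, 5.0]) == 0.0

    def test_scale_invariance(self):
        x = [3.0, 4.0, 5.5]
        assert percent_cv(x) == pytest.approx(percent_cv([7 * v for v in x]))

    def test_zero_mean_flagged(self):
        with pytest.raises(ValueError):
            percent_cv([-1.0, 1.0])

    def test_single_replicate_rejected(self):
        with pytest.raises(ValueError):
            percent_cv([1.0])


class TestZonalTest:
    def _small_table(self, rng, n_diff=3, n_flat=5):
        tables = []
        for i in range(n_diff):
            t = simulate_lipid(rng, zone_effects=(0.7, 1.4), resid_sd=0.08)
            tables.append(t.assign(lipid_id=f"diff{i}", roi=1))
        for i in range(n_flat):
            t = simulate_lipid(rng, resid_sd=0.08)
            tables.append(t.assign(lipid_id=f"flat{i}", roi=1))
        return pd.concat(tables, ignore_index=True)

    def test_planted_effects_detected(self):
        rng = np.random.default_rng(9)
        res = zonal_test(self._small_table(rng), alpha=0.05)
        sig = set(res.loc[res["significant"], "lipid_id"])
        assert {"diff0", "diff1", "diff2"} <= sig

    def test_alpha_zero_yields_nothing(self):
        rng = np.random.default_rng(10)
        res = zonal_test(self._small_table(rng), alpha=0.0)
        assert not res["significant"].any()

    def test_report_includes_classes(self):
        rng = np.random.default_rng(11)
        res = zonal_test(self._small_table(rng, 1, 1))
        report = zonation_table(res, {"diff0": "FA", "flat0": "PC"})
        assert set(report["lipid_class"]) == {"FA", "PC"}

    def test_zero_medians_get_pseudocount(self):
        rng = np.random.default_rng(12)
        tab = self._small_table(rng, 1, 0)
        tab.loc[tab.index[:2], "median_intensity"] = 0.0
        res = zonal_test(tab)
        assert len(res) == 1 and np.isfinite(res["p"]).all()


class TestReplicateCv:
    def test_cv_computed_per_lipid(self):
        rng = np.random.default_rng(13)
        reps = []
        for _ in range(3):
            rows = []
            for lipid, base in (("A", 10.0), ("B", 100.0)):
                for zone in ("Z1", "Z2", "Z3"):
                    for roi in (1, 2, 3):
                        rows.append({
                            "lipid_id": lipid, "mouse": "m1", "zone": zone,
                            "roi": roi,
                            "median_intensity":
                                base * rng.lognormal(0.0, 0.05)})
            reps.append(pd.DataFrame(rows))
        out = replicate_percent_cv(reps)
        assert set(out["lipid_id"]) == {"A", "B"}
        assert (out["cv_percent"] < 30).all()

    def test_requires_two_replicates(self):
        with pytest.raises(ValueError):
            replicate_percent_cv([pd.DataFrame()])
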