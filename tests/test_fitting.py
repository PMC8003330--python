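"""Two-stage and free global regression: recovery, bias, and diagnostics."""

import numpy as np
import pandas as pd
import pytest

import glyatkin as gk
from glyatkin import (
    ConvergenceError,
    DesignError,
    HillBisubstrateModel,
    SimulationDesign,
)
from glyatkin.fitting import PARAM_NAMES

TRUTH = {"vf": 0.85, "s05_gly": 23.0, "h_gly": 1.6,
         "s05_benz": 97.0, "h_benz": 2.1}


def _rates(params, seed=None, **design_kw):
    kw = dict(noise_cv=0.0, noise_floor=0.0, n_replicates=1)
    kw.update(design_kw)
    return gk.simulate_rates(params, SimulationDesign(**kw), seed=seed)


class TestStage1:
    def test_exact_recovery_from_unisubstrate_truth(self):
        gly = np.array([1, 2, 5, 10, 20, 50, 100, 200], float)
        rates = pd.DataFrame({
            "gly_mM": gly, "benz_uM": 200.0,
            "rate": gk.rate_unisubstrate(0.85, 23.0, 1.6, gly),
        })
        fit = gk.fit_stage1_kcat(rates)
        assert fit.vmax == pytest.approx(0.85, rel=1e-6)
        assert fit.s05 == pytest.approx(23.0, rel=1e-6)
        assert fit.h == pytest.approx(1.6, rel=1e-6)

    def test_plateau_bias_at_finite_benzoyl_coa(self, ref_params,
                                                noiseless_design):
        """The stage-1 plateau at 200 uM benzoyl-CoA is Vf times that
        level's saturation fraction, not Vf itself."""
        rates = gk.simulate_rates(ref_params, noiseless_design)
        fit = gk.fit_stage1_kcat(rates)
        sat_frac = float(gk.hill_fraction(200.0, 97.0, 2.1))
        assert sat_frac == pytest.approx(0.8205, abs=5e-4)
        assert fit.vmax == pytest.approx(0.85 * sat_frac, rel=0.01)
        assert fit.vmax < 0.85 * 0.99  # clearly not the true Vf

    def test_too_few_glycine_levels(self, ref_params):
        rates = _rates(ref_params, gly_levels_mM=(5.0, 50.0, 200.0))
        with pytest.raises(DesignError):
            gk.fit_stage1_kcat(rates)

    def test_all_zero_rates(self, ref_params, noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        rates["rate"] = 0.0
        with pytest.raises(ConvergenceError):
            gk.fit_stage1_kcat(rates)


class TestStage2AndTwoStage:
    def test_exact_shape_recovery_with_true_vf(self, ref_params,
                                               noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        fit = gk.fit_stage2_global(rates, fixed_vf=0.85)
        for name in ("s05_gly", "h_gly", "s05_benz", "h_benz"):
            assert getattr(fit.params, name) == pytest.approx(
                TRUTH[name], rel=1e-6)

    def test_fixed_parameter_contract(self, ref_params, noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        fit = gk.fit_stage2_global(rates, fixed_vf=0.7)
        assert fit.params.vf == 0.7          # never moved
        assert fit.bse["vf"] == 0.0          # exactly zero variance
        assert (fit.cov_params().loc["vf"] == 0).all()
        assert "vf" in fit.fixed

    def test_single_benzoyl_level_is_design_error(self, ref_params):
        rates = _rates(ref_params, benz_levels_uM=(100.0,))
        with pytest.raises(DesignError):
            gk.fit_stage2_global(rates, fixed_vf=0.85)

    def test_empty_table_is_design_error(self):
        with pytest.raises(DesignError):
            HillBisubstrateModel(pd.DataFrame(columns=["gly_mM", "benz_uM",
                                                       "rate"]))

    def test_two_stage_matches_free_when_top_level_saturates(self, ref_params):
        """At a saturating top benzoyl-CoA level (50x s05) the stage-1 bias
        all but vanishes; the residual (50)^-h saturation deficit (~3e-4 on
        Vf) bounds the remaining discrepancy."""
        rates = _rates(ref_params,
                       benz_levels_uM=(100.0, 500.0, 1500.0, 4850.0))
        two = gk.fit_two_stage(rates)
        free = gk.fit_global_free(rates)
        for name in PARAM_NAMES:
            assert getattr(two.params, name) == pytest.approx(
                getattr(free.params, name), rel=2e-3)
        assert two.stage1 is not None
        assert two.params.vf == two.stage1.vmax

    def test_two_stage_on_default_grid_reports_both_fits(self, ref_params,
                                                         noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        two = gk.fit_two_stage(rates)
        free = gk.fit_global_free(rates)
        # documented systematic discrepancy: two-stage Vf carries the
        # stage-1 saturation bias, the free fit recovers the truth
        assert free.params.vf == pytest.approx(0.85, rel=1e-5)
        assert two.params.vf == pytest.approx(0.697, abs=0.005)


class TestFreeFit:
    def test_noiseless_exact_recovery(self, ref_params, noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        fit = gk.fit_global_free(rates)
        for name in PARAM_NAMES:
            assert getattr(fit.params, name) == pytest.approx(
                TRUTH[name], rel=1e-5)
        assert fit.ssr < 1e-20
        assert fit.converged

    def test_row_order_invariance(self, ref_params):
        rates = gk.simulate_rates(ref_params, SimulationDesign(), seed=3)
        shuffled = rates.sample(frac=1.0, random_state=9).reset_index(
            drop=True)
        a = gk.fit_global_free(rates, seed=5)
        b = gk.fit_global_free(shuffled, seed=5)
        for name in PARAM_NAMES:
            assert abs(getattr(a.params, name) - getattr(b.params, name)) \
                <= 1e-10 * max(abs(getattr(a.params, name)), 1.0)

    def test_consistency_as_noise_vanishes(self, ref_params):
        """Estimator bias shrinks with the noise level on the default grid."""
        tolerances = {0.03: 0.20, 0.01: 0.06, 0.001: 0.01}
        errors = {}
        for cv, tol in tolerances.items():
            rates = gk.simulate_rates(
                ref_params, SimulationDesign(noise_cv=cv), seed=17)
            fit = gk.fit_global_free(rates, seed=17)
            rel = max(abs(getattr(fit.params, n) - TRUTH[n]) / TRUTH[n]
                      for n in PARAM_NAMES)
            errors[cv] = rel
            assert rel < tol
        assert errors[0.001] < errors[0.03]

    def test_optimum_beats_dense_grid_search(self, ref_params):
        """Brute-force oracle on a tiny 3x3 design: the optimiser's SSR is
        at least as low as a dense parameter-grid scan, and the estimates
        land within one grid step of the scan's argmin."""
        rates = _rates(ref_params, noise_cv=0.05, n_replicates=2,
                       gly_levels_mM=(5.0, 20.0, 100.0),
                       benz_levels_uM=(40.0, 80.0, 200.0), seed=7)
        fit = gk.fit_global_free(rates, seed=7)

        G = rates["gly_mM"].to_numpy()
        B = rates["benz_uM"].to_numpy()
        y = rates["rate"].to_numpy()
        axes = {
            "vf": np.geomspace(0.4, 1.8, 9),
            "s05_gly": np.geomspace(8.0, 70.0, 9),
            "h_gly": np.linspace(0.8, 3.0, 9),
            "s05_benz": np.geomspace(30.0, 320.0, 9),
            "h_benz": np.linspace(0.8, 3.6, 9),
        }
        mesh = np.meshgrid(*axes.values(), indexing="ij")
        flat = [m.reshape(-1, 1) for m in mesh]
        vf, sg, hg, sb, hb = flat
        xg = (G[None, :] / sg) ** hg
        xb = (B[None, :] / sb) ** hb
        pred = vf * (xg / (1 + xg)) * (xb / (1 + xb))
        ssr = ((pred - y[None, :]) ** 2).sum(axis=1)
        best = int(np.argmin(ssr))
        assert fit.ssr <= ssr[best] + 1e-12
        argmin = {name: float(flat[i][best, 0])
                  for i, name in enumerate(axes)}
        for name, axis in axes.items():
            step = np.max(np.abs(np.diff(axis)))
            assert abs(getattr(fit.params, name) - argmin[name]) \
                <= step + 1e-12

    def test_standard_error_coverage(self, ref_params):
        """With vf held at truth, ~all shape estimates land within 3 SE of
        their generating values over seeded replicate experiments."""
        inside = total = 0
        for seed in range(1, 11):
            rates = gk.simulate_rates(ref_params, SimulationDesign(),
                                      seed=seed)
            fit = gk.fit_stage2_global(rates, fixed_vf=0.85, seed=seed)
            for name in ("s05_gly", "h_gly", "s05_benz", "h_benz"):
                total += 1
                inside += (abs(getattr(fit.params, name) - TRUTH[name])
                           <= 3.0 * fit.bse[name])
        assert inside / total >= 0.85


class TestCooperativityTest:
    def test_hyperbolic_data_prefers_constrained(self, ref_params):
        mm = ref_params.replace(h_gly=1.0, h_benz=1.0, kcat=None)
        wins = sum(
            gk.cooperativity_test(
                gk.simulate_rates(mm, SimulationDesign(), seed=s), seed=s
            ).favoured == "constrained"
            for s in range(1, 11)
        )
        assert wins >= 8

    def test_cooperative_data_prefers_free(self, ref_params):
        wins = sum(
            gk.cooperativity_test(
                gk.simulate_rates(ref_params, SimulationDesign(), seed=s),
                seed=s
            ).favoured == "free"
            for s in range(1, 11)
        )
        assert wins >= 9

    def test_noiseless_cooperative_data_guards_f_statistic(self, ref_params,
                                                           noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        result = gk.cooperativity_test(rates)
        assert result.constrained.ssr > 1e3 * max(result.free.ssr, 1e-300)
        assert np.isinf(result.f_stat) or result.f_stat > 1e3
        assert result.favoured == "free"


class TestResultsObject:
    def test_summary_and_dict(self, ref_params, noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        fit = gk.fit_two_stage(rates, label="156Asn>Ser")
        text = fit.summary()
        assert "156Asn>Ser" in text and "two-stage" in text
        assert "s05_benz" in text
        d = fit.to_dict()
        assert d["fixed"] == ["vf"]
        assert d["nobs"] == len(rates)
        assert set(d["estimates"]) == set(PARAM_NAMES)

    def test_predict_and_residuals(self, ref_params, noiseless_design):
        rates = gk.simulate_rates(ref_params, noiseless_design)
        model = HillBisubstrateModel(rates, label="ref")
        fit = model.fit(method="free")
        assert np.allclose(fit.resid, 0.0, atol=1e-9)
        assert fit.predict(23.0, 1e9) == pytest.approx(0.85 / 2, rel=1e-4)
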