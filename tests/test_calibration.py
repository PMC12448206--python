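import math

import numpy as np
import pandas as pd
import pytest
from scipy.integrate import solve_ivp
from scipy import stats

from pfastk.calibration import (FitSpec, PKCalibrator, PKDataset,
                                collinearity_index, collinearity_report,
                                factor_coverage, fit, fixed_param_sensitivity,
                                gamma_from_sensitivities, msle, objective,
                                predict_dataset, run_mcmc)
from pfastk.model import DoseSchedule, ModelState, rhs
from pfastk.params import ChemicalParams, PhysioParams, derive_rates
from pfastk.synth import gen_primate_study


class TestObjective:
    def test_perfect_predictions_give_zero(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        from dataclasses import replace
        ds = gen_primate_study(physio, chem, replace(small_design,
                                                     residual_sd=0.0))
        assert objective(chem, ds, physio) == pytest.approx(0.0, abs=1e-12)

    def test_decade_offset_gives_n(self, pfos_monkey, small_design):
        """Predictions exactly 10x observations: SSR equals the number of
        observations (one squared decade each)."""
        physio, chem = pfos_monkey
        from dataclasses import replace
        ds = gen_primate_study(physio, chem, replace(small_design,
                                                     residual_sd=0.0))
        obs = ds.observations.copy()
        obs["conc_ug_per_mL"] = obs["conc_ug_per_mL"] / 10.0
        ds10 = PKDataset(obs, ds.schedules, ds.body_weights)
        n = len(obs)
        assert objective(chem, ds10, physio) == pytest.approx(n, rel=1e-9)

    def test_matches_naive_reimplementation(self, pfos_monkey):
        """Five-point IV dataset: SSR agrees with an independent
        brute-force pipeline built from the raw rhs() and solve_ivp."""
        physio, chem = pfos_monkey
        times = np.array([1.0, 24.0, 168.0, 500.0, 1000.0])
        sch = DoseSchedule.iv_bolus(2.0)
        obs_vals = np.array([8.0, 4.0, 4.2, 3.9, 3.5])
        obs = pd.DataFrame({
            "subject": ["m1"] * 5, "group": ["iv"] * 5, "route": ["iv"] * 5,
            "time_h": times, "conc_ug_per_mL": obs_vals})
        ds = PKDataset(obs, {"iv": sch}, {"iv": physio.BW})

        r = derive_rates(physio, chem)

        def f(t, y):
            state = ModelState(*y)
            d = rhs(state, t, r, chem)
            return d.as_array()

        y0 = np.zeros(6)
        y0[1] = 2.0 * physio.BW
        sol = solve_ivp(f, (0.0, 1000.0), y0, method="LSODA", t_eval=times,
                        rtol=1e-10, atol=1e-12)
        ssr_naive = float(np.sum(
            (np.log10(sol.y[1] / r.Vc) - np.log10(obs_vals)) ** 2))
        assert objective(chem, ds, physio) == pytest.approx(ssr_naive,
                                                            rel=1e-6)

    def test_order_invariance_and_additivity(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        ds = gen_primate_study(physio, chem, small_design)
        shuffled = PKDataset(
            ds.observations.sample(frac=1.0, random_state=0)
            .reset_index(drop=True), ds.schedules, ds.body_weights)
        assert objective(chem, shuffled, physio) == pytest.approx(
            objective(chem, ds, physio), rel=1e-9)
        # additivity over a disjoint split
        obs = ds.observations
        a = PKDataset(obs.iloc[:50].reset_index(drop=True), ds.schedules,
                      ds.body_weights)
        b = PKDataset(obs.iloc[50:].reset_index(drop=True), ds.schedules,
                      ds.body_weights)
        assert objective(chem, a, physio) + objective(chem, b, physio) == \
            pytest.approx(objective(chem, ds, physio), rel=1e-9)


class TestCollinearity:
    def test_orthonormal_columns_give_one(self):
        S = np.eye(6)[:, :3]
        assert gamma_from_sensitivities(S) == pytest.approx(1.0)

    def test_duplicated_column_diverges(self):
        col = np.arange(1.0, 7.0)
        S = np.column_stack([col, col, np.ones(6)])
        assert gamma_from_sensitivities(S) > 1e6

    def test_zero_column_reports_inf(self):
        S = np.column_stack([np.arange(6.0), np.zeros(6)])
        assert gamma_from_sensitivities(S) == math.inf

    def test_matches_svd_oracle(self, rng):
        """gamma equals 1/(smallest singular value of the column-normalized
        matrix) — an independent linear-algebra route."""
        for _ in range(5):
            S = rng.standard_normal((6, 3))
            Sn = S / np.linalg.norm(S, axis=0)
            oracle = 1.0 / np.linalg.svd(Sn, compute_uv=False)[-1]
            assert gamma_from_sensitivities(S) == pytest.approx(oracle,
                                                                rel=1e-10)

    def test_subset_size_validated(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        ds = gen_primate_study(physio, chem, small_design)
        with pytest.raises(ValueError):
            collinearity_index(ds, physio, chem, ("VCC",))

    def test_free_fraction_collinear_with_resorption(self, pfos_monkey):
        """On the full 26-week multi-dose design, Free is nearly redundant
        with the resorption parameters (the published fits hold it fixed
        for exactly this reason), while the default free set
        {VCC, Tmc, Kt} stays identifiable (gamma below the conventional
        threshold of 20)."""
        physio, chem = pfos_monkey
        from pfastk.synth import default_study_design
        from dataclasses import replace
        design = replace(default_study_design(residual_sd=0.0, seed=0),
                         n_subjects=1)
        ds = gen_primate_study(physio, chem, design)
        rep = collinearity_report(ds, physio, chem,
                                  ("VCC", "Tmc", "Kt", "Free"))
        rep = rep.set_index(rep["subset"].astype(str))
        g_default = rep.loc[str(("VCC", "Tmc", "Kt")), "gamma"]
        g_with_free = rep.loc[str(("VCC", "Tmc", "Kt", "Free")), "gamma"]
        assert g_with_free > 5 * g_default
        assert g_default < 20.0


class TestFit:
    def test_all_fixed_returns_fixed(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        ds = gen_primate_study(physio, chem, small_design)
        spec = FitSpec.from_reference(chem, free=())
        res = fit(ds, spec, physio)
        assert res.estimates == {}
        assert res.ssr == pytest.approx(objective(chem, ds, physio), rel=1e-9)

    def test_noise_free_recovery(self, pfos_monkey, small_design):
        """Fitting {VCC, Tmc, Kt} on noise-free data recovers the
        generating values to well under 1% from distant starting points."""
        physio, chem = pfos_monkey
        from dataclasses import replace
        ds = gen_primate_study(physio, chem,
                               replace(small_design, residual_sd=0.0))
        spec = FitSpec.from_reference(
            chem, start={"VCC": 0.5, "Tmc": 0.9, "Kt": 0.015})
        cal = PKCalibrator(spec, physio).fit(ds)
        assert cal.converged_
        for k in spec.free:
            assert cal.estimates_[k] == pytest.approx(getattr(chem, k),
                                                      rel=0.01)
        assert cal.predict(ds) == pytest.approx(
            ds.observations["conc_ug_per_mL"].to_numpy(), rel=1e-4)

    def test_estimator_api(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        spec = FitSpec.from_reference(chem)
        cal = PKCalibrator(spec, physio)
        assert "spec" in cal.get_params()
        with pytest.raises(RuntimeError):
            cal.predict(gen_primate_study(physio, chem, small_design))


class TestMCMC:
    def test_conjugate_toy_posterior(self):
        """A one-parameter problem that is a Gaussian location model in
        disguise: IV bolus with negligible elimination makes log10 serum =
        const - log10(VCC), so the marginal posterior of log10(VCC) under
        the vague variance prior is Student-t around the sample mean.  The
        sampler must reproduce the closed-form centre and 95% interval."""
        physio = PhysioParams(BW=70.0, QCC=12.5)
        chem = ChemicalParams(bioAv=0.9, VCC=0.2, Tmc=1e-12, Kt=0.004,
                              Free=1e-6, k12=0.0, k21=3.4, ka=132.0)
        times = np.array([1.0, 2.0, 3.0, 4.0])
        rng = np.random.default_rng(11)
        n_pts, sigma = 24, 0.1
        rows = []
        d0 = 2.0 * physio.BW
        c0 = d0 / (chem.VCC * physio.BW)
        eps = rng.standard_normal(n_pts) * sigma
        for i in range(n_pts):
            rows.append({"subject": f"s{i}", "group": "iv", "route": "iv",
                         "time_h": times[i % 4],
                         "conc_ug_per_mL": c0 * 10.0 ** eps[i]})
        ds = PKDataset(pd.DataFrame(rows), {"iv": DoseSchedule.iv_bolus(2.0)},
                       {"iv": physio.BW})
        spec = FitSpec.from_reference(chem, free=("VCC",))
        mc = run_mcmc(ds, spec, physio, n_iter=6000, seed=5, n_walkers=12)
        # closed form: log10(VCC_hat) = log10(VCC_true) - mean(eps)
        x = mc.chain[:, 0]  # the chain is already in log10 space
        x_hat = math.log10(chem.VCC) - float(np.mean(eps))
        s = float(np.std(eps, ddof=1))
        se = s / math.sqrt(n_pts)
        t975 = stats.t.ppf(0.975, n_pts - 1)
        assert np.mean(x) == pytest.approx(x_hat, abs=4 * se / 10)
        lo, hi = np.percentile(x, [2.5, 97.5])
        assert hi - lo == pytest.approx(2 * t975 * se, rel=0.25)

    def test_seed_reproducibility(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        ds = gen_primate_study(physio, chem, small_design)
        spec = FitSpec.from_reference(chem)
        a = run_mcmc(ds, spec, physio, n_iter=300, seed=9, n_walkers=8)
        b = run_mcmc(ds, spec, physio, n_iter=300, seed=9, n_walkers=8)
        assert np.array_equal(a.chain, b.chain)
        assert a.acceptance_rate == b.acceptance_rate

    def test_reports_diagnostics(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        ds = gen_primate_study(physio, chem, small_design)
        spec = FitSpec.from_reference(chem)
        mc = run_mcmc(ds, spec, physio, n_iter=300, seed=9, n_walkers=8)
        assert 0.0 < mc.acceptance_rate < 1.0
        assert set(mc.rhat) == {"VCC", "Tmc", "Kt", "sigma_log10"}
        assert (mc.cri.loc["VCC", "q2.5"] <= mc.cri.loc["VCC", "median"]
                <= mc.cri.loc["VCC", "q97.5"])


class TestFixedParamSensitivity:
    def test_unit_factor_is_zero_change(self, pfos_monkey, small_design):
        physio, chem = pfos_monkey
        from dataclasses import replace
        ds = gen_primate_study(physio, chem,
                               replace(small_design, residual_sd=0.0))
        spec = FitSpec.from_reference(chem)
        tab = fixed_param_sensitivity(ds, spec, physio, params=("ka",),
                                      factors=(1.0,), solver_rtol=1e-6)
        for k in spec.free:
            assert abs(tab[f"pct_change_{k}"].iloc[0]) < 0.5

    def test_absorption_rate_barely_matters(self, pfos_monkey, small_design):
        """Perturbing ka by two orders of magnitude changes the fitted
        {VCC, Tmc, Kt} by well under 10% on average: absorption is fast on
        the sampling timescale, so the data carry almost no information
        about it."""
        physio, chem = pfos_monkey
        from dataclasses import replace
        ds = gen_primate_study(physio, chem,
                               replace(small_design, residual_sd=0.0))
        spec = FitSpec.from_reference(chem)
        tab = fixed_param_sensitivity(ds, spec, physio, params=("ka",),
                                      factors=(0.01, 100.0),
                                      solver_rtol=1e-6)
        changes = tab[[f"pct_change_{k}" for k in spec.free]].abs()
        assert changes.mean().mean() < 10.0

    def test_deep_exchange_ratio_moves_vcc(self, pfos_monkey, small_design):
        """Pushing k12/k21 up a hundredfold forces the apparent central
        volume to absorb the extra deep-compartment mass: VCC shifts by
        more than 10% (directional identifiability limit)."""
        physio, chem = pfos_monkey
        from dataclasses import replace
        ds = gen_primate_study(physio, chem,
                               replace(small_design, residual_sd=0.0))
        spec = FitSpec.from_reference(chem)
        tab = fixed_param_sensitivity(ds, spec, physio, params=("k12",),
                                      factors=(100.0,), solver_rtol=1e-6)
        assert abs(tab["pct_change_VCC"].iloc[0]) > 10.0


class TestMetrics:
    def test_perfect_fit(self):
        x = np.array([1.0, 2.0, 5.0])
        assert msle(x, x) == 0.0
        assert factor_coverage(x, x) == 1.0

    def test_uniform_twofold_bias(self):
        """pred = 2*obs: MSLE = (log10 2)^2 ~ 0.0906 and factor-2 coverage
        is exactly 1 (the band is boundary-inclusive)."""
        obs = np.array([0.5, 1.0, 10.0, 40.0])
        pred = 2.0 * obs
        assert msle(pred, obs) == pytest.approx(math.log10(2.0) ** 2,
                                                rel=1e-12)
        assert factor_coverage(pred, obs, factor=2.0) == 1.0

    def test_half_log_band_boundary(self):
        """3.17x is just outside the half-decade band (10^0.5 ~ 3.162)."""
        obs = np.ones(4)
        assert factor_coverage(3.17 * obs, obs, factor=10**0.5) == 0.0
        assert factor_coverage(3.15 * obs, obs, factor=10**0.5) == 1.0

    def test_configurable_base(self):
        obs = np.ones(3)
        assert msle(math.e * obs, obs, base=math.e) == pytest.approx(1.0)

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            msle([0.0, 1.0], [1.0, 1.0])
        with pytest.raises(ValueError):
            factor_coverage([1.0], [-1.0])
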