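"""Two-level regressions, BH correction, mixed models, and power."""

import numpy as np
import pandas as pd
import pytest
import scipy.stats

from predinf import (
    FirstLevelFit,
    build_first_level_design,
    correlate_r2_with_trait,
    fit_first_level,
    fit_second_level,
    fits_to_frame,
    group_tests,
    lr_trait_regression,
    regression_power,
    specificity_panel,
    trajectory_mixed_model,
)


def _trials(update, pe, cpp, ru, subject="s1"):
    return pd.DataFrame({
        "subject_id": subject, "update": update, "pe": pe, "cpp": cpp, "ru": ru,
        "valid": 1,
    })


def _random_trials(rng, n=120, noise=0.0, w=(0.7, 0.3, 0.2)):
    pe = rng.normal(0, 10, n)
    cpp = rng.beta(0.5, 3, n)
    ru = rng.beta(2, 3, n) * 0.8
    update = w[0] * pe + w[1] * pe * cpp + w[2] * pe * ru + rng.normal(0, noise, n)
    return _trials(update, pe, cpp, ru)


class TestFirstLevel:
    def test_matches_normal_equations_oracle(self, rng):
        """OLS equals an independently coded normal-equations solve to 1e-8."""
        t = _random_trials(rng, noise=2.0)
        fit = fit_first_level(t)
        X = np.column_stack([
            t["pe"] - t["pe"].mean(),
            t["pe"] * t["cpp"] - (t["pe"] * t["cpp"]).mean(),
            t["pe"] * t["ru"] - (t["pe"] * t["ru"]).mean(),
        ])
        X = np.column_stack([np.ones(len(t)), X])
        beta = np.linalg.solve(X.T @ X, X.T @ t["update"].to_numpy())
        assert fit.beta0 == pytest.approx(beta[0], abs=1e-8)
        assert fit.beta_pe == pytest.approx(beta[1], abs=1e-8)
        assert fit.beta_pecpp == pytest.approx(beta[2], abs=1e-8)
        assert fit.beta_peru == pytest.approx(beta[3], abs=1e-8)

    def test_exact_linear_agent(self, rng):
        pe = rng.normal(0, 10, 100)
        cpp = rng.beta(0.5, 3, 100)
        ru = rng.beta(2, 3, 100)
        t = _trials(0.7 * pe, pe, cpp, ru)
        fit = fit_first_level(t)
        assert fit.beta_pe == pytest.approx(0.7, abs=1e-10)
        assert fit.beta_pecpp == pytest.approx(0.0, abs=1e-10)
        assert fit.r2 == pytest.approx(1.0, abs=1e-12)

    def test_pure_noise_agent_explains_nothing(self, rng):
        pe = rng.normal(0, 10, 2000)
        t = _trials(rng.normal(0, 5, 2000), pe, rng.beta(0.5, 3, 2000),
                    rng.beta(2, 3, 2000))
        fit = fit_first_level(t)
        assert fit.r2 < 0.02

    def test_noisy_agent_weights_recovered_within_tolerance(self):
        """A simulated agent with known weights and response noise SD 2 is
        recovered to +/-0.05 from one 280-trial session."""
        from predinf import (AgentParams, ObserverConfig, TaskConfig,
                             build_trial_table, generate_session,
                             run_conditioned, simulate_agent)
        rng = np.random.default_rng(17)
        obs = ObserverConfig()
        params = AgentParams(w_pe=0.5, w_cpp=0.3, w_ru=0.2, noise_sd=2.0,
                             p_lapse0=0.0, p_lapse1=0.0)
        est = []
        for _ in range(10):
            runs = generate_session(TaskConfig(constrained=True), rng)
            session = simulate_agent(params, runs, obs, rng)
            traj = run_conditioned(session.predictions, runs, obs, valid=session.valid)
            fit = fit_first_level(build_trial_table(session, runs, traj))
            est.append([fit.beta_pe, fit.beta_pecpp, fit.beta_peru])
        mean = np.mean(est, axis=0)
        assert mean[0] == pytest.approx(0.5, abs=0.05)
        assert mean[1] == pytest.approx(0.3, abs=0.05)
        assert mean[2] == pytest.approx(0.2, abs=0.05)

    def test_centering_leaves_outcome_untouched(self, rng):
        t = _random_trials(rng, noise=1.0)
        y, _ = build_first_level_design(t)
        np.testing.assert_array_equal(y.to_numpy(), t["update"].to_numpy())

    def test_degenerate_regressor_flagged(self, rng):
        t = _random_trials(rng, noise=1.0)
        t["cpp"] = 0.0  # pe*cpp identically zero
        with pytest.raises(ValueError, match="degenerate"):
            build_first_level_design(t)

    def test_too_few_trials_marks_fit_unreliable(self, rng):
        t = _random_trials(rng, n=10)
        fit = fit_first_level(t)
        assert not fit.reliable and fit.n_trials_used == 0


def _fits(betas, r2=0.8):
    return [FirstLevelFit(f"s{i}", 0.0, b[0], b[1], b[2], r2, 200)
            for i, b in enumerate(betas)]


class TestGroupTests:
    def test_planted_mean_recovered(self, rng):
        betas = np.column_stack([rng.normal(0.77, 0.1, 50),
                                 rng.normal(0.08, 0.05, 50),
                                 rng.normal(0.07, 0.05, 50)])
        g = group_tests(_fits(betas))
        assert g.loc["beta_pe", "mean"] == pytest.approx(0.77, abs=0.05)
        assert g.loc["beta_pe", "ci_low"] < g.loc["beta_pe", "mean"] < g.loc["beta_pe", "ci_high"]
        assert g.loc["beta_pe", "p"] < 1e-10

    def test_sign_balanced_cohort_has_small_t(self, rng):
        half = rng.normal(0.5, 0.01, 20)
        betas = np.column_stack([np.r_[half, -half], np.zeros(40), np.zeros(40)])
        g = group_tests(_fits(betas))
        assert abs(g.loc["beta_pe", "mean"]) < 0.01
        assert abs(g.loc["beta_pe", "t"]) < 1.0

    def test_identical_fits_reported_degenerate(self):
        g = group_tests(_fits(np.tile([0.5, 0.1, 0.1], (10, 1))))
        assert g.loc["beta_pe", "ci_low"] == g.loc["beta_pe", "ci_high"] == 0.5
        assert np.isnan(g.loc["beta_pe", "t"])

    def test_ci_matches_t_interval_oracle(self, rng):
        x = rng.normal(0.3, 0.2, 40)
        betas = np.column_stack([x, x, x])
        g = group_tests(_fits(betas))
        lo, hi = scipy.stats.t.interval(0.95, 39, loc=x.mean(),
                                        scale=x.std(ddof=1) / np.sqrt(40))
        assert g.loc["beta_pe", "ci_low"] == pytest.approx(lo)
        assert g.loc["beta_pe", "ci_high"] == pytest.approx(hi)


class TestSecondLevel:
    def _panel_and_fits(self, rng, n=80):
        betas = np.column_stack([rng.normal(0.7, 0.2, n),
                                 rng.normal(0.1, 0.1, n),
                                 rng.normal(0.1, 0.1, n)])
        fits = _fits(betas)
        panel = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)]})
        return panel, fits, betas

    def test_planted_identity_outcome(self, rng):
        panel, fits, betas = self._panel_and_fits(rng)
        panel["ple"] = -betas[:, 0]
        res = fit_second_level(panel, fits, "ple", zscore_outcome=False)
        assert res.table.loc["beta_pe", "beta"] == pytest.approx(-1.0, abs=1e-8)
        assert res.r2 == pytest.approx(1.0, abs=1e-10)

    def test_null_outcome_gives_flat_pvalues(self):
        rng = np.random.default_rng(101)
        panel, fits, _ = self._panel_and_fits(rng, n=300)
        rejections = 0
        pvals = []
        for _ in range(200):
            panel["ple"] = rng.standard_normal(len(panel))
            res = fit_second_level(panel, fits, "ple")
            pvals.extend(res.table["p"].tolist())
            rejections += (res.table["p"] < 0.05).sum()
        rate = rejections / len(pvals)
        assert 0.02 < rate < 0.08
        # p-values approximately uniform
        ks = scipy.stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_join_losing_too_many_subjects_fails(self, rng):
        panel, fits, betas = self._panel_and_fits(rng)
        panel["ple"] = 0.5 * betas[:, 0] + rng.normal(0, 1, len(panel))
        panel.loc[: len(panel) * 0.7, "subject_id"] = "missing"
        with pytest.raises(ValueError, match="join lost"):
            fit_second_level(panel, fits, "ple")


class TestR2Correlation:
    def test_exact_negative_identity(self):
        fits = [FirstLevelFit(f"s{i}", 0, 0.5, 0.1, 0.1, r2, 200)
                for i, r2 in enumerate([0.3, 0.5, 0.7, 0.9])]
        panel = pd.DataFrame({"subject_id": [f"s{i}" for i in range(4)],
                              "ple": [-0.3, -0.5, -0.7, -0.9]})
        r, _ = correlate_r2_with_trait(fits, panel)
        assert r == pytest.approx(-1.0)

    def test_constant_trait_errors(self):
        fits = _fits(np.random.default_rng(0).normal(size=(10, 3)))
        panel = pd.DataFrame({"subject_id": [f"s{i}" for i in range(10)], "ple": 1.0})
        with pytest.raises(ValueError):
            correlate_r2_with_trait(fits, panel)


class TestSpecificityPanel:
    def _setup(self, rng, n=60):
        betas = np.column_stack([rng.normal(0.7, 0.2, n),
                                 rng.normal(0.1, 0.1, n),
                                 rng.normal(0.1, 0.1, n)])
        fits = _fits(betas)
        panel = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n)]})
        for q in ("pdi", "asi", "caps", "ocir", "stai_t", "aes", "audit"):
            panel[q] = rng.normal(10, 3, n)
        return panel, fits

    def test_family_is_21_tests_and_bh_monotone(self, rng):
        panel, fits = self._setup(rng)
        results = specificity_panel(panel, fits)
        all_raw = np.concatenate([r.table["p"] for r in results])
        all_adj = np.concatenate([r.table["p_bh"] for r in results])
        assert len(all_raw) == 21
        assert (all_adj >= all_raw - 1e-12).all()
        # BH preserves the p-value ordering
        order = np.argsort(all_raw)
        assert (np.diff(all_adj[order]) >= -1e-12).all()

    def test_bh_arithmetic_on_single_small_p(self):
        from statsmodels.stats.multitest import multipletests
        raw = np.r_[0.001, np.ones(20)]
        _, adj, _, _ = multipletests(raw, method="fdr_bh")
        assert adj[0] == pytest.approx(0.021)

    def test_missing_score_skipped_with_warning(self, rng):
        panel, fits = self._setup(rng)
        panel = panel.drop(columns=["audit"])
        with pytest.warns(UserWarning, match="audit"):
            results = specificity_panel(panel, fits)
        assert len(results) == 6


class TestBinnedLRRegression:
    def test_directions_share_t_statistic(self, rng):
        n = 50
        binned = pd.DataFrame({
            "lr_hi": rng.uniform(0, 1, n), "lr_lo": rng.uniform(0, 1, n),
        }, index=[f"s{i}" for i in range(n)])
        panel = pd.DataFrame({"subject_id": binned.index,
                              "ple": -binned["lr_hi"].to_numpy() + rng.normal(0, 0.2, n)})
        res = lr_trait_regression(binned, panel, "lr_hi")
        assert res.loc["lr_on_trait", "t"] == pytest.approx(res.loc["trait_on_lr", "t"])
        assert res.loc["lr_on_trait", "slope"] < 0

    def test_excessive_missingness_errors(self):
        binned = pd.DataFrame({"lr_hi": [np.nan, np.nan, 0.5], "lr_lo": [0.1] * 3},
                              index=["a", "b", "c"])
        panel = pd.DataFrame({"subject_id": ["a", "b", "c"], "ple": [0.1, 0.2, 0.3]})
        with pytest.raises(ValueError):
            lr_trait_regression(binned, panel, "lr_hi")


@pytest.fixture(scope="module")
def planted():
    """Synthetic trials with known fixed-effect signs:
    perf error falls across TAC, rises with noise, rises with trait."""
    rng = np.random.default_rng(77)
    rows = []
    n_subj = 40
    ple = rng.standard_normal(n_subj)
    for i in range(n_subj):
        intercept = 8 + rng.normal(0, 1)
        for run, cond in enumerate(["low", "low", "high", "high"], start=1):
            tac = np.tile(np.arange(1, 11), 2)
            noise = 1.0 if cond == "high" else 0.0
            y = (intercept - 0.4 * tac + 4.0 * noise + 0.8 * ple[i]
                 + 0.2 * ple[i] * tac + rng.normal(0, 1.5, len(tac)))
            rows.append(pd.DataFrame({
                "subject_id": f"s{i}", "run_index": run, "condition": cond,
                "tac": tac, "perf_error": y, "valid": 1,
            }))
    trials = pd.concat(rows, ignore_index=True)
    panel = pd.DataFrame({"subject_id": [f"s{i}" for i in range(n_subj)],
                          "ple": ple})
    return trials, panel


class TestTrajectoryMixedModel:
    def test_recovers_planted_signs(self, planted):
        trials, panel = planted
        res = trajectory_mixed_model(trials, panel, outcome="perf_error")
        fe = res.fixed_effects
        assert fe.loc["tac", "beta"] < 0
        assert fe.loc["noise_high", "beta"] > 0
        assert fe.loc["trait_score", "beta"] > 0
        assert fe.loc["tac:trait_score", "beta"] > 0
        assert fe.loc["tac", "p"] < 0.001
        assert res.selection_log  # selection path is logged

    def test_null_trait_terms_small(self, planted):
        trials, panel = planted
        rng = np.random.default_rng(5)
        panel = panel.assign(ple=rng.standard_normal(len(panel)))
        res = trajectory_mixed_model(trials, panel, outcome="perf_error")
        assert res.fixed_effects.loc["trait_score", "p"] > 0.01


class TestPower:
    def test_zero_effect_power_equals_alpha(self):
        assert regression_power(300, 3, 0.0, 0.05) == pytest.approx(0.05)

    def test_closed_form_single_predictor_checkpoint(self):
        # lambda = (z_{0.975} + z_{0.95})^2 gives ~95% power for df1=1
        lam = (scipy.stats.norm.ppf(0.975) + scipy.stats.norm.ppf(0.95)) ** 2
        power = regression_power(300, 1, lam / 300, 0.05)
        assert power == pytest.approx(0.95, abs=0.005)

    def test_study_design_reaches_95_percent(self):
        assert regression_power(300, 3, 0.058, 0.05) >= 0.95

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            regression_power(4, 3, 0.058)
        with pytest.raises(ValueError):
            regression_power(300, 3, -0.1)
        with pytest.raises(ValueError):
            regression_power(300, 3, 0.058, alpha=1.5)
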