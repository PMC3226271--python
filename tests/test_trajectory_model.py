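import dataclasses

import numpy as np
import pytest
from scipy import stats

from pgsa.data_model import load_artifact, save_artifact
from pgsa.synthetic_cohort import generate_baseline, generate_outcomes
from pgsa.trajectory_model import (
    ScheduleError,
    fit_lmm,
    fit_trajectory,
    marginal_cov,
    marginal_sd,
    mci_trajectory_fixture,
    csf_trajectory_fixture,
    predict_trajectory,
    simulate_control_trajectories,
    simulate_trajectory_matrix,
)
from conftest import noise_free


def _subject(**overrides):
    from pgsa.data_model import SubjectBaseline

    kw = dict(
        subject_id="S1", age=74.0, gender="female", education=16.0, bmi=26.1,
        apoe4_count=1, hachinski=1, faq=2, mmse=27, adascog_bl=18.6,
        npbatt_bl=-1.0,
    )
    kw.update(overrides)
    return SubjectBaseline(**kw)


def _simulate_panel(n_sub, seed, beta=(-1.0, -0.09, 0.4), g=(0.19, 0.068, 0.65),
                    sw=0.25, visits=(0, 1, 2, 3, 4, 6)):
    """Random-intercept/slope panel with one continuous covariate."""
    rng = np.random.default_rng(seed)
    t = np.tile(np.asarray(visits, float), n_sub)
    subj = np.repeat(np.arange(n_sub), len(visits))
    x = rng.normal(size=n_sub)
    si, ss, rho = g
    G = np.array([[si**2, rho * si * ss], [rho * si * ss, ss**2]])
    b = rng.multivariate_normal([0, 0], G, n_sub)
    y = (beta[0] + beta[1] * t + beta[2] * x[subj]
         + b[subj, 0] + b[subj, 1] * t + rng.normal(0, sw, len(t)))
    X = np.column_stack([np.ones_like(t), t, x[subj]])
    return y, X, subj, t


# --------------------------------------------------------------------------
# Core solver vs statsmodels MixedLM (independent oracle)
# --------------------------------------------------------------------------

class TestLmmSolver:
    def test_matches_mixedlm_on_random_slope_panel(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        y, X, subj, t = _simulate_panel(200, seed=1)
        ours = fit_lmm(y, X, subj, t, terms=["intercept", "visit", "x"])
        sm_fit = MixedLM(
            y, X, groups=subj, exog_re=np.column_stack([np.ones_like(t), t])
        ).fit(reml=True)
        np.testing.assert_allclose(ours.beta, sm_fit.fe_params, atol=2e-4)
        np.testing.assert_allclose(ours.se, sm_fit.bse_fe, rtol=0.02, atol=1e-5)
        cov_re = np.asarray(sm_fit.cov_re)
        assert ours.sd_intercept == pytest.approx(np.sqrt(cov_re[0, 0]), rel=0.02)
        assert ours.sd_slope == pytest.approx(np.sqrt(cov_re[1, 1]), rel=0.02)
        assert ours.sigma_w == pytest.approx(np.sqrt(sm_fit.scale), rel=0.02)

    def test_matches_mixedlm_with_unbalanced_patterns(self):
        from statsmodels.regression.mixed_linear_model import MixedLM

        y, X, subj, t = _simulate_panel(150, seed=2)
        rng = np.random.default_rng(3)
        keep = rng.random(len(y)) < 0.8
        # keep every subject's first observation so none disappears entirely
        keep[np.unique(subj, return_index=True)[1]] = True
        y, X, subj, t = y[keep], X[keep], subj[keep], t[keep]
        ours = fit_lmm(y, X, subj, t, terms=["intercept", "visit", "x"])
        sm_fit = MixedLM(
            y, X, groups=subj, exog_re=np.column_stack([np.ones_like(t), t])
        ).fit(reml=True)
        np.testing.assert_allclose(ours.beta, sm_fit.fe_params, atol=5e-4)
        np.testing.assert_allclose(ours.se, sm_fit.bse_fe, rtol=0.02, atol=1e-5)

    def test_recovers_generating_parameters(self):
        y, X, subj, t = _simulate_panel(1500, seed=4)
        res = fit_lmm(y, X, subj, t)
        assert res.beta[1] == pytest.approx(-0.09, abs=3 * res.se[1])
        assert res.sd_slope == pytest.approx(0.068, rel=0.15)
        assert res.sigma_w == pytest.approx(0.25, rel=0.05)

    def test_time_rescaling_rescales_slope_terms(self):
        # refitting with months instead of visit numbers divides slope
        # estimates by exactly 6
        y, X, subj, t = _simulate_panel(300, seed=5)
        res_v = fit_lmm(y, X, subj, t, terms=["intercept", "visit", "x"])
        Xm = X.copy()
        Xm[:, 1] = X[:, 1] * 6.0
        res_m = fit_lmm(y, Xm, subj, t * 6.0, terms=["intercept", "month", "x"])
        assert res_m.beta[1] == pytest.approx(res_v.beta[1] / 6.0, rel=1e-4)
        assert res_m.sd_slope == pytest.approx(res_v.sd_slope / 6.0, rel=1e-3)
        assert res_m.beta[0] == pytest.approx(res_v.beta[0], rel=1e-5)

    def test_lrt_calibration_under_zero_slope_variance(self):
        # with no true slope variance the naive 2-df LRT is conservative:
        # retention of random slopes should not exceed the nominal rate
        retained = 0
        n_reps = 40
        for rep in range(n_reps):
            rng = np.random.default_rng(100 + rep)
            n_sub, visits = 80, np.array([0, 1, 2, 3, 4, 6], float)
            t = np.tile(visits, n_sub)
            subj = np.repeat(np.arange(n_sub), len(visits))
            b0 = rng.normal(0, 0.2, n_sub)
            y = -1.0 - 0.09 * t + b0[subj] + rng.normal(0, 0.25, len(t))
            X = np.column_stack([np.ones_like(t), t])
            full = fit_lmm(y, X, subj, t, random_slopes=True)
            null = fit_lmm(y, X, subj, t, random_slopes=False)
            lrt = 2 * (full.loglik - null.loglik)
            if stats.chi2.sf(max(lrt, 0), 2) < 0.05:
                retained += 1
        assert retained / n_reps <= 0.125  # nominal 0.05 plus binomial slack


# --------------------------------------------------------------------------
# Prediction
# --------------------------------------------------------------------------

class TestPredict:
    def test_apoe4_changes_slope_by_its_interaction(self, trajectory_fit):
        a = _subject(apoe4_count=0)
        b = _subject(subject_id="S2", apoe4_count=1)
        mu = predict_trajectory(trajectory_fit, [a, b], [0, 1, 2])
        slopes = np.diff(mu, axis=1)
        # per-visit slope difference equals the visit x ApoE4 coefficient,
        # -0.03558; the level difference at t=0 is the ApoE4 main effect
        assert slopes[1, 0] - slopes[0, 0] == pytest.approx(-0.03558)
        assert mu[1, 0] - mu[0, 0] == pytest.approx(0.03383)

    def test_baseline_npbatt_shifts_all_visits_equally(self, trajectory_fit):
        a = _subject(npbatt_bl=-1.0)
        b = _subject(subject_id="S2", npbatt_bl=0.0)
        mu = predict_trajectory(trajectory_fit, [a, b], [0, 1, 4, 6])
        np.testing.assert_allclose(mu[1] - mu[0], 0.97529, rtol=1e-9)

    def test_visit_zero_unaffected_by_time_interactions(self, trajectory_fit):
        base = _subject()
        stripped = dataclasses.replace(
            trajectory_fit,
            terms=list(trajectory_fit.terms),
            coef=np.where(
                [t.startswith("visit") for t in trajectory_fit.terms],
                0.0, trajectory_fit.coef,
            ),
        )
        mu_full = predict_trajectory(trajectory_fit, [base], [0])
        mu_stripped = predict_trajectory(stripped, [base], [0])
        assert mu_full[0] == pytest.approx(mu_stripped[0])

    def test_illegal_visit_rejected(self, trajectory_fit):
        with pytest.raises(ScheduleError):
            predict_trajectory(trajectory_fit, [_subject()], [0, 5])


# --------------------------------------------------------------------------
# Simulation and marginal variance
# --------------------------------------------------------------------------

class TestSimulate:
    def test_degenerate_fit_gives_deterministic_means(self, trajectory_fit):
        quiet = noise_free(trajectory_fit)
        sims = simulate_trajectory_matrix(
            quiet, [_subject()], [0, 2, 4], n_replicates=3, seed=6
        )
        mu = predict_trajectory(quiet, [_subject()], [0, 2, 4])
        for r in range(3):
            np.testing.assert_allclose(sims[r, 0], mu, atol=1e-6)

    def test_marginal_sd_closed_form_reference_points(self, trajectory_fit):
        assert marginal_sd(trajectory_fit, 0) == pytest.approx(
            np.hypot(0.1856, 0.25), rel=1e-9
        )
        flat = dataclasses.replace(trajectory_fit, sd_slope=1e-12, corr=0.0)
        assert marginal_sd(flat, 0) == pytest.approx(marginal_sd(flat, 6))
        sds = [marginal_sd(trajectory_fit, t) for t in range(7)]
        assert np.all(np.diff(sds) > 0)  # corr >= 0 makes it increasing

    def test_empirical_visit_covariance_matches_closed_form(self, trajectory_fit):
        # covariance across visits of one subject's residuals around the
        # fixed-effect mean: sd_i^2 + st*sd_s^2 + (s+t)*rho*sd_i*sd_s
        subjects = [_subject()] * 1  # single covariate profile
        fit = dataclasses.replace(
            trajectory_fit, cov=np.zeros_like(trajectory_fit.cov)
        )
        sims = simulate_trajectory_matrix(
            fit, subjects, [0, 2, 6], n_replicates=40_000, seed=7,
            param_uncertainty=False,
        )[:, 0, :]
        emp = np.cov(sims.T)
        for i, s in enumerate([0, 2, 6]):
            for j, t in enumerate([0, 2, 6]):
                assert emp[i, j] == pytest.approx(
                    marginal_cov(fit, s, t), rel=0.05, abs=0.004
                )

    def test_replicate_datasets_reproducible(self, trajectory_fit, small_cohort):
        a = simulate_control_trajectories(trajectory_fit, small_cohort,
                                          n_replicates=2, seed=8)
        b = simulate_control_trajectories(trajectory_fit, small_cohort,
                                          n_replicates=2, seed=8)
        assert [d.visits for d in a] == [d.visits for d in b]


# --------------------------------------------------------------------------
# Selection on simulated data
# --------------------------------------------------------------------------

class TestFitTrajectory:
    def test_recovers_structure_from_simulated_cohort(self, trajectory_fit):
        cohort = generate_baseline(500, seed=40)
        ds = generate_outcomes(cohort, trajectory=trajectory_fit,
                               schedule=[0, 1, 2, 3, 4, 6], seed=41,
                               param_uncertainty=False)
        fit = fit_trajectory(
            ds,
            candidates=["bmi2", "bmi3", "apoe4", "age", "faq", "adascog_bl",
                        "npbatt_bl"],
            scan_baseline_interactions=False,
        )
        assert fit.random_slopes
        assert "npbatt_bl" in fit.terms
        i = fit.terms.index("npbatt_bl")
        se = np.sqrt(fit.cov[i, i])
        assert fit.coef[i] == pytest.approx(0.97529, abs=3 * se)
        assert fit.within_sd == pytest.approx(0.25, rel=0.08)
        # marginality: every interaction's parents are retained
        mains = {t for t in fit.terms if ":" not in t}
        for t in fit.terms:
            if ":" in t:
                assert set(t.split(":")) <= mains

    def test_refit_with_fixed_terms_is_idempotent(self, trajectory_fit):
        from pgsa.data_model import design_matrix
        from pgsa.trajectory_model import _trajectory_frame
        from pgsa.data_model import CodingConfig

        cohort = generate_baseline(250, seed=42)
        ds = generate_outcomes(cohort, trajectory=trajectory_fit,
                               schedule=[0, 1, 2, 3, 4, 6], seed=43,
                               param_uncertainty=False)
        frame = _trajectory_frame(ds, CodingConfig(), include_csf=False)
        terms = ["intercept", "visit", "npbatt_bl", "visit:apoe4"]
        X = design_matrix(frame, terms)
        args = (frame["npbatt"].to_numpy(float), X,
                frame["subject_id"].to_numpy(), frame["visit"].to_numpy(float))
        a = fit_lmm(*args, terms=terms)
        b = fit_lmm(*args, terms=terms)
        np.testing.assert_array_equal(a.beta, b.beta)
        assert a.sd_slope == b.sd_slope

    def test_csf_variant_artifact_loads_and_predicts(self):
        fit = csf_trajectory_fixture()
        a = _subject(csf_ratio=1.0)
        b = _subject(subject_id="S2", csf_ratio=3.0)
        mu = predict_trajectory(fit, [a, b], [0, 1])
        slope_diff = (mu[1, 1] - mu[1, 0]) - (mu[0, 1] - mu[0, 0])
        # higher CSF ratio flattens the decline
        assert slope_diff == pytest.approx(2.0 * 0.02229)

    def test_artifact_round_trip(self, trajectory_fit, tmp_path):
        path = str(tmp_path / "traj.json")
        save_artifact(trajectory_fit, path)
        again = load_artifact(path)
        assert again.terms == trajectory_fit.terms
        np.testing.assert_allclose(again.coef, trajectory_fit.coef)
        assert again.G == pytest.approx(trajectory_fit.G)
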