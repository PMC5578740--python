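"""Variance decomposition, trajectories, and mean-matched subsampling."""

import numpy as np
import pandas as pd
import pytest

from statevar.masks import VolumeSeries
from statevar.variability import (
    decompose_variance,
    fit_trajectory,
    individual_slope_correlation,
    mean_match_subsample,
    per_subject_coefficients,
)


class TestDecomposeVariance:
    def test_pure_vme_residuals(self, patterns, mask):
        v = patterns.volumes["vme_mean"].values
        resid = VolumeSeries(np.tile(v[:, None], (1, 30)), mask)
        vd = decompose_variance(resid, patterns, None, [5, 15], window=range(6))
        assert np.isclose(vd.total_brain_state_variability, 1.0)
        assert vd.ss_maint < 1e-20 and vd.ss_retr < 1e-20

    def test_orthogonal_residuals_zero_ratio(self, patterns, mask, rng):
        y = rng.normal(size=mask.n_voxels)
        X = patterns.matrix()
        y = y - X @ np.linalg.lstsq(X, y, rcond=None)[0]
        y = y - y.mean()
        resid = VolumeSeries(np.tile(y[:, None], (1, 30)), mask)
        vd = decompose_variance(resid, patterns, None, [5, 15])
        assert vd.total_brain_state_variability < 1e-15

    def test_projection_matrix_oracle(self, patterns, mask, rng):
        """SS values equal a brute-force decomposition built from explicit
        projection matrices over nested column spans."""
        from statevar.nuisance import build_nuisance_set

        nuis = build_nuisance_set(rng.normal(size=(28, mask.n_voxels)), None, mask)
        resid = VolumeSeries(rng.normal(size=(mask.n_voxels, 40)), mask)
        mgs = [4, 20]
        vd = decompose_variance(resid, patterns, nuis, mgs)

        X = np.column_stack([nuis.matrix(), patterns.matrix()])
        trs = np.concatenate([np.arange(m, m + 6) for m in mgs])
        Y = resid.data[:, trs]

        def proj(cols):
            A = X[:, :cols]
            return A @ np.linalg.pinv(A)

        n_nuis = len(nuis)
        total = np.sum(Y**2)
        ss = []
        prev = np.zeros((mask.n_voxels, mask.n_voxels))
        for cols in (n_nuis, n_nuis + 2, n_nuis + 4, n_nuis + 6):
            P = proj(cols)
            ss.append(np.sum(((P - prev) @ Y) ** 2))
            prev = P
        assert abs(vd.ss_vme - ss[1]) < 1e-8 * max(1, ss[1])
        assert abs(vd.ss_maint - ss[2]) < 1e-8 * max(1, ss[2])
        assert abs(vd.ss_retr - ss[3]) < 1e-8 * max(1, ss[3])
        assert abs(vd.ss_error - (total - np.sum((prev @ Y) ** 2))) < 1e-6

    def test_additivity_exact(self, patterns, mask, rng):
        resid = VolumeSeries(rng.normal(size=(mask.n_voxels, 60)), mask)
        vd = decompose_variance(resid, patterns, None, [10, 30, 45])
        lhs = vd.ss_brain
        rhs = vd.ss_vme + vd.ss_maint + vd.ss_retr
        assert abs(lhs - rhs) <= 1e-9 * rhs

    def test_white_noise_matches_basis_dimension(self, patterns, mask, rng):
        """Projecting white noise on a 6-dim basis captures ~6/n_voxels of
        the variance (analytic expectation, Monte-Carlo tolerance)."""
        ratios = []
        for _ in range(20):
            resid = VolumeSeries(rng.normal(size=(mask.n_voxels, 24)), mask)
            vd = decompose_variance(resid, patterns, None, [4, 12], window=range(6))
            ratios.append(vd.total_brain_state_variability)
        expected = 6 / mask.n_voxels
        assert abs(np.mean(ratios) - expected) < 0.4 * expected

    def test_empty_trials_rejected(self, patterns, mask):
        resid = VolumeSeries(np.zeros((mask.n_voxels, 10)), mask)
        with pytest.raises(ValueError):
            decompose_variance(resid, patterns, None, [])

    def test_monotone_in_component_gain_sd(self, design, patterns):
        """Scaling one component's injected gain SD scales its SS share
        monotonically."""
        from statevar.deconvolution import FIRDeconvolver, build_fir_design
        from statevar.synthetic import GainGroundTruth, generate_session

        shares = []
        for sd in (0.1, 0.3, 0.6):
            gain_sd = {c: 0.2 for c in patterns.volumes}
            gain_sd["retr_mean"] = sd
            truth = GainGroundTruth(gain_sd=gain_sd, p_incorrect=0.0)
            sess = generate_session(design, patterns, truth, seed=21)
            fir = build_fir_design(sess.trials, design.n_tr_per_run,
                                   design.n_runs, motion=sess.motion)
            dec = FIRDeconvolver().fit(sess.bold, fir)
            vd = decompose_variance(dec.residuals_.series, patterns, None,
                                    sess.trials["mgs_tr"])
            shares.append(vd.component_ratio("retr"))
        assert shares[0] < shares[1] < shares[2]


class TestTrajectoryFit:
    @staticmethod
    def _cohort_df(rng, n_sub=12, n_sess=3, b0=0.5, b1=0.0, form="linear_age",
                   noise=0.0, re_sd=0.0):
        rows = []
        for s in range(n_sub):
            entry = rng.uniform(8, 28)
            off = rng.normal(0, re_sd)
            for k in range(n_sess):
                age = entry + 1.5 * k
                x = age if form == "linear_age" else 1 / age
                rows.append(dict(subject=s, age=age,
                                 y=b0 + b1 * x + off + rng.normal(0, noise)))
        return pd.DataFrame(rows)

    def test_exact_inverse_age_recovery(self, rng):
        df = self._cohort_df(rng, b1=2.0, form="inverse_age")
        fit = fit_trajectory(df["y"], df["age"], df["subject"], form="inverse_age")
        assert abs(fit.fixed_effects["Intercept"] - 0.5) < 1e-6
        assert abs(fit.age_slope - 2.0) < 1e-6

    def test_aic_prefers_true_linear_form(self, rng):
        """Under a linear-age truth the linear form wins the AIC comparison
        in nearly all seeded replicates (simulation oracle)."""
        wins = 0
        n_rep = 60
        for _ in range(n_rep):
            df = self._cohort_df(rng, b1=-0.02, noise=0.05, re_sd=0.03)
            lin = fit_trajectory(df["y"], df["age"], df["subject"], form="linear_age")
            inv = fit_trajectory(df["y"], df["age"], df["subject"], form="inverse_age")
            wins += lin.aic < inv.aic
        assert wins >= 0.9 * n_rep

    def test_uncorrelated_covariate_leaves_slope(self, rng):
        df = self._cohort_df(rng, b1=-0.02, noise=0.05, re_sd=0.03)
        fd = pd.DataFrame({"mean_fd": rng.normal(size=len(df))})
        base = fit_trajectory(df["y"], df["age"], df["subject"])
        with_cov = fit_trajectory(df["y"], df["age"], df["subject"], covariates=fd)
        assert abs(with_cov.age_slope - base.age_slope) < 2 * base.fixed_se["age_term"]

    def test_endpoint_change_from_fixed_effects(self, rng):
        df = self._cohort_df(rng, b1=-0.01)
        fit = fit_trajectory(df["y"], df["age"], df["subject"])
        assert np.isclose(fit.endpoint_change, -0.01 * (8 - 33), atol=1e-6)

    def test_aic_identity(self, rng):
        df = self._cohort_df(rng, b1=-0.01, noise=0.02, re_sd=0.02)
        fit = fit_trajectory(df["y"], df["age"], df["subject"])
        assert np.isclose(fit.aic, 2 * fit.n_params - 2 * fit.loglik)


class TestSlopeCorrelation:
    def test_exact_negative_linear_relation(self):
        brain = pd.Series({i: -0.01 * i for i in range(10)})
        behav = pd.Series({i: 0.02 * i + 1 for i in range(10)})
        r, _ = individual_slope_correlation(brain, behav)
        assert np.isclose(r, -1.0)

    def test_independent_coefficients_rarely_large(self, rng):
        """With 29 independent subjects, |r| < 0.5 in >=95% of null draws."""
        hits = 0
        for _ in range(100):
            a = pd.Series(rng.normal(size=29))
            b = pd.Series(rng.normal(size=29))
            r, _ = individual_slope_correlation(a, b)
            hits += abs(r) < 0.5
        assert hits >= 95

    def test_too_few_subjects(self):
        with pytest.raises(ValueError):
            individual_slope_correlation(pd.Series({1: 0.1}), pd.Series({1: 0.2}))

    def test_per_subject_coefficients_filter(self, rng):
        df = pd.DataFrame({
            "subject": [0] * 4 + [1] * 2,
            "age": [8, 10, 12, 14, 20, 22],
            "y": [1, 2, 3, 4, 5, 6],
        })
        coefs = per_subject_coefficients(df["y"], df["age"], df["subject"],
                                         min_sessions=4)
        assert list(coefs.index) == [0]


class TestMeanMatchSubsample:
    def test_identical_groups_centered_at_zero(self, rng):
        fd = rng.uniform(0.02, 0.2, 80)
        y = rng.normal(size=80)
        out = mean_match_subsample(fd, y, fd.copy(), y.copy(), n_boot=300, seed=0)
        lo, hi = out["ci95"]
        assert lo < 0 < hi

    def test_group_difference_survives_fd_bias(self, rng):
        """y independent of FD with a true group difference delta: the biased
        bootstrap difference stays near delta."""
        delta = 0.5
        fd_a = rng.uniform(0.02, 0.2, 100)
        fd_b = rng.uniform(0.02, 0.2, 100)
        y_a = rng.normal(delta, 0.1, 100)
        y_b = rng.normal(0.0, 0.1, 100)
        out = mean_match_subsample(fd_a, y_a, fd_b, y_b, bias="b_greater",
                                   n_boot=400, seed=1)
        assert out["fd_mean_b"].mean() > out["fd_mean_a"].mean()
        assert abs(out["difference"].mean() - delta) < 0.1

    def test_seeded_reproducibility(self, rng):
        fd = rng.uniform(0, 1, 50)
        y = rng.normal(size=50)
        a = mean_match_subsample(fd, y, fd, y, n_boot=50, seed=3)
        b = mean_match_subsample(fd, y, fd, y, n_boot=50, seed=3)
        np.testing.assert_array_equal(a["difference"], b["difference"])

    def test_unachievable_bias_raises(self):
        fd_a = np.full(20, 0.01)
        fd_b = np.full(20, 0.5)
        with pytest.raises(ValueError):
            mean_match_subsample(fd_a, np.zeros(20), fd_b, np.zeros(20),
                                 bias="a_greater", n_boot=10, seed=0)
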