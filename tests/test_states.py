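"""State extraction: masks, epochs, orthogonalization, symmetrization."""

import numpy as np
import pytest

from statevar.masks import Mask, MaskedVolume
from statevar.states import (
    COMPONENTS,
    BrainStateSet,
    StateExtractor,
    build_state_mask,
    extract_epoch_pattern,
    group_average_timecourses,
    mean_spatial_decompose,
    mirror_symmetrize,
    orthogonalize,
)


def _toy_mask(n=6):
    coords = np.column_stack([np.arange(n), np.zeros(n, int), np.zeros(n, int)])
    pairing = np.arange(n)[::-1]
    return Mask(coords, pairing)


class TestStateMask:
    def test_all_pass(self):
        m = _toy_mask()
        sm = build_state_mask(MaskedVolume(np.ones(6), m), MaskedVolume(np.ones(6), m))
        assert sm.include.all()

    def test_empty_raises(self):
        m = _toy_mask()
        with pytest.raises(ValueError):
            build_state_mask(MaskedVolume(np.zeros(6), m), MaskedVolume(np.ones(6), m))

    def test_mixed_thresholds_match_boolean_oracle(self):
        m = _toy_mask()
        gray = np.array([0.0, 0.4, 0.5, 0.9, 1.0, 0.6])
        r2 = np.array([0.5, 0.5, 0.2, 0.27, 0.9, 0.26])
        sm = build_state_mask(MaskedVolume(gray, m), MaskedVolume(r2, m))
        expected = np.array([(g >= 0.5) and (r >= 0.27) for g, r in zip(gray, r2)])
        np.testing.assert_array_equal(sm.include, expected)


class TestEpochExtraction:
    def test_vme_uses_four_long_delay_volumes(self, deconvolved_default):
        dec, _ = deconvolved_default
        vols = extract_epoch_pattern(dec.trial_averages_, "encode")
        assert len(vols) == 4  # 2 long-delay conditions x 2 hemifields

    def test_lag_zero_returns_stored_volume(self, deconvolved_default):
        dec, _ = deconvolved_default
        vols = extract_epoch_pattern(dec.trial_averages_, "encode", lag_tr=0)
        for key, vol in vols.items():
            np.testing.assert_array_equal(
                vol.values, dec.trial_averages_.averages[key][0])

    def test_out_of_range_lag_raises(self, deconvolved_default):
        dec, _ = deconvolved_default
        with pytest.raises(ValueError):
            extract_epoch_pattern(dec.trial_averages_, "encode", lag_tr=99)


class TestOrthogonalize:
    def test_target_in_span_becomes_zero(self, rng):
        R = rng.normal(size=(100, 3))
        target = R @ np.array([1.0, -2.0, 0.5])
        (out,) = orthogonalize([target], [R[:, 0], R[:, 1], R[:, 2]])
        assert np.max(np.abs(np.asarray(out))) < 1e-10

    def test_orthogonal_target_unchanged(self, rng):
        R = rng.normal(size=(200, 2))
        t = rng.normal(size=200)
        t -= t.mean()
        X = np.column_stack([np.ones(200), R])
        t -= X @ np.linalg.lstsq(X, t, rcond=None)[0]
        (out,) = orthogonalize([t], [R[:, 0], R[:, 1]])
        np.testing.assert_allclose(np.asarray(out), t, atol=1e-10)

    def test_projection_matrix_oracle(self, rng):
        R = rng.normal(size=(100, 4))
        t = rng.normal(size=100)
        X = np.column_stack([np.ones(100), R])
        M = np.eye(100) - X @ np.linalg.solve(X.T @ X, X.T)
        (out,) = orthogonalize([t], list(R.T))
        np.testing.assert_allclose(np.asarray(out), M @ t, atol=1e-8)

    def test_collinear_references_raise(self, rng):
        r = rng.normal(size=50)
        with pytest.raises(ValueError):
            orthogonalize([rng.normal(size=50)], [r, 2 * r])


class TestMeanSpatial:
    def test_arithmetic(self):
        m = _toy_mask()
        mean, spatial = mean_spatial_decompose(
            MaskedVolume(np.full(6, 2.0), m), MaskedVolume(np.zeros(6), m))
        assert np.all(mean.values == 1.0) and np.all(spatial.values == 2.0)

    def test_equal_hemifields_zero_spatial(self, rng):
        m = _toy_mask()
        v = MaskedVolume(rng.normal(size=6), m)
        _, spatial = mean_spatial_decompose(v, v)
        assert np.all(spatial.values == 0)

    def test_recomposition_identity(self, rng):
        m = _toy_mask()
        r = MaskedVolume(rng.normal(size=6), m)
        l = MaskedVolume(rng.normal(size=6), m)
        mean, spatial = mean_spatial_decompose(r, l)
        np.testing.assert_allclose(mean.values + spatial.values / 2, r.values,
                                   rtol=0, atol=1e-15)
        np.testing.assert_allclose(mean.values - spatial.values / 2, l.values,
                                   rtol=0, atol=1e-15)


class TestMirrorSymmetrize:
    def _states_from(self, mask, rng):
        vols = {c: MaskedVolume(rng.normal(size=mask.n_voxels), mask)
                for c in COMPONENTS}
        return BrainStateSet(vols)

    def test_symmetric_mean_is_fixed_point(self, mask, rng):
        v = rng.normal(size=mask.n_voxels)
        v = (v + mask.mirror(v)) / 2
        vols = {c: MaskedVolume(v if c.endswith("_mean") else v - mask.mirror(v),
                                mask) for c in COMPONENTS}
        out = mirror_symmetrize(BrainStateSet(vols))
        np.testing.assert_allclose(out.volumes["vme_mean"].values, v)

    def test_antisymmetric_input_as_mean_vanishes(self, mask, rng):
        a = rng.normal(size=mask.n_voxels)
        a = (a - mask.mirror(a)) / 2
        vols = {c: MaskedVolume(a, mask) for c in COMPONENTS}
        out = mirror_symmetrize(BrainStateSet(vols))
        assert np.max(np.abs(out.volumes["maint_mean"].values)) < 1e-12

    def test_outputs_exactly_symmetric(self, mask, rng):
        out = mirror_symmetrize(self._states_from(mask, rng))
        for name, vol in out.volumes.items():
            mirrored = mask.mirror(vol.values)
            target = vol.values if name.endswith("_mean") else -vol.values
            np.testing.assert_array_equal(mirrored, target)


class TestGroupAverage:
    def test_no_covariates_is_plain_mean(self, deconvolved_default):
        dec, _ = deconvolved_default
        ta = dec.trial_averages_
        group = group_average_timecourses([ta, ta])
        for key in ta.averages:
            np.testing.assert_allclose(group.averages[key], ta.averages[key])


class TestStateExtractorRecovery:
    def test_recovers_ground_truth_patterns(self, design, patterns):
        """On a multi-session synthetic group average, the six extracted
        states match ground truth up to scale (|cosine| > 0.95)."""
        from statevar.deconvolution import FIRDeconvolver, build_fir_design
        from statevar.synthetic import GainGroundTruth, generate_session

        decs = []
        for seed in range(6):
            sess = generate_session(design, patterns, GainGroundTruth(), seed=100 + seed)
            fir = build_fir_design(sess.trials, design.n_tr_per_run, design.n_runs,
                                   motion=sess.motion)
            decs.append(FIRDeconvolver().fit(sess.bold, fir))
        group = group_average_timecourses(
            [d.trial_averages_ for d in decs], ages=[10, 14, 18, 22, 26, 30])
        ext = StateExtractor().fit(group)
        cos = np.abs(np.diag(ext.states_.matrix().T @ patterns.matrix()))
        assert np.all(cos > 0.95), cos

    def test_components_unit_norm_and_symmetric(self, design, patterns, noise_free_truth):
        from statevar.deconvolution import FIRDeconvolver, build_fir_design
        from statevar.synthetic import generate_session

        sess = generate_session(design, patterns, noise_free_truth, seed=4)
        fir = build_fir_design(sess.trials, design.n_tr_per_run, design.n_runs)
        dec = FIRDeconvolver(scale_by_residual_sd=False).fit(sess.bold, fir)
        states = StateExtractor().fit(dec.trial_averages_).states_
        m = states.mask
        for name, vol in states.volumes.items():
            assert np.isclose(np.linalg.norm(vol.values), 1.0)
            sign = 1.0 if name.endswith("_mean") else -1.0
            np.testing.assert_allclose(m.mirror(vol.values), sign * vol.values,
                                       atol=1e-12)
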