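"""Saccade detection, behavior scoring, snippets, trial-wise regression."""

import numpy as np
import pandas as pd
import pytest

from statevar.projection import ExpressionSeries
from statevar.states import COMPONENTS
from statevar.synthetic import make_eye_trace, make_velocity_trace
from statevar.trialwise import (
    SnippetStack,
    behavioral_summaries,
    detect_saccades,
    extract_snippets,
    prepare_behavior,
    score_trials,
    speed_accuracy_quadratic,
    trialwise_regression,
    trialwise_scan,
)


def oracle_detect(v, min_peak=30.0, frac=0.1):
    """Independent brute-force scan used as the detection oracle."""
    v = np.asarray(v, float)
    n = len(v)
    peaks = [i for i in range(1, n - 1)
             if v[i] > v[i - 1] and v[i] >= v[i + 1] and v[i] >= min_peak]
    peaks.sort(key=lambda i: -v[i])
    taken = [False] * n
    events = []
    for p in peaks:
        if taken[p]:
            continue
        th = frac * v[p]
        s = p
        while s > 0 and v[s - 1] >= th:
            s -= 1
        e = p
        while e < n - 1 and v[e + 1] >= th:
            e += 1
        if any(taken[s:e + 1]):
            continue
        for i in range(s, e + 1):
            taken[i] = True
        events.append((s, p, e))
    return sorted(events)


class TestDetectSaccades:
    def test_flat_trace_no_events(self):
        assert detect_saccades(np.zeros(100)) == []

    def test_triangular_pulse_boundaries(self):
        v = make_velocity_trace([(0.5, 100.0, 0.3)], total_s=2.0)
        events = detect_saccades(v)
        assert len(events) == 1
        assert events == oracle_detect(v)
        s, p, e = events[0]
        assert v[s] >= v[p] / 10 and (s == 0 or v[s - 1] < v[p] / 10)
        assert v[e] >= v[p] / 10 and (e == len(v) - 1 or v[e + 1] < v[p] / 10)

    def test_two_pulses_in_order(self):
        v = make_velocity_trace([(0.4, 120.0, 0.2), (1.5, 90.0, 0.2)], total_s=2.5)
        events = detect_saccades(v)
        assert len(events) == 2
        assert events[0][0] < events[1][0]

    def test_matches_oracle_on_random_traces(self):
        rng = np.random.default_rng(7)
        for _ in range(100):
            n_ev = rng.integers(0, 4)
            evs = [(float(rng.uniform(0.2, 4.0)), float(rng.uniform(20, 200)),
                    float(rng.uniform(0.1, 0.4))) for _ in range(n_ev)]
            v = make_velocity_trace(evs, total_s=5.0, noise_sd=rng.uniform(0, 5),
                                    seed=int(rng.integers(2**31)))
            assert detect_saccades(v) == oracle_detect(v)


class TestScoreTrials:
    def _trials(self):
        return pd.DataFrame({
            "target_onset_s": [0.5, 4.0],
            "fixation_off_s": [2.0, 5.5],
            "target_deg": [6.0, -3.0],
            "presentation_s": [1.5, 1.5],
            "delay_s": [1.5, 1.5],
        })

    def test_rt_and_zero_se_by_construction(self):
        # per trial: encoding saccade to the target, return to fixation, and
        # an MGS back to the target exactly 300 ms after fixation offset
        sacc = [(0.5, 6.0, 0.15), (1.4, -6.0, 0.15), (2.3, 6.0, 0.15),
                (3.0, -6.0, 0.15),
                (4.0, -3.0, 0.15), (4.8, 3.0, 0.15), (5.8, -3.0, 0.15)]
        vel, pos = make_eye_trace(sacc, total_s=7.0)
        events = detect_saccades(vel)
        scored, flags = score_trials(events, pos, self._trials())
        assert not flags["excluded"]
        assert np.allclose(scored["rt_ms"], 300.0, atol=1000 / 60 + 1e-9)
        assert np.allclose(scored["se_deg"], 0.0, atol=0.2)

    def test_missing_mgs_marks_incorrect_and_flags(self):
        vel, pos = make_eye_trace([(0.5, 6.0, 0.15)], total_s=7.0)
        events = detect_saccades(vel)
        scored, flags = score_trials(events, pos, self._trials())
        assert not scored["correct"].any()
        assert flags["excluded"]  # under 50% measurable in these trial types


class TestBehavioralSummaries:
    def test_inaccuracy_and_imprecision_arithmetic(self):
        trials = pd.DataFrame({
            "presentation_s": [1.5] * 2, "delay_s": [9.0] * 2,
            "hemifield": [1, 1], "eccentricity_deg": [6, 6],
            "rt_ms": [400.0, 400.0], "se_deg": [0.5, -0.5],
            "correct": [True, True],
        })
        out = behavioral_summaries(trials)
        assert np.isclose(out["inaccuracy_deg"].iloc[0], 0.0)
        assert np.isclose(out["imprecision_deg"].iloc[0], np.sqrt(0.5), atol=1e-9)
        assert out["sd_rt_ms"].iloc[0] == 0.0

    def test_insufficient_trials_give_nan(self):
        trials = pd.DataFrame({
            "presentation_s": [1.5], "delay_s": [9.0],
            "hemifield": [1], "eccentricity_deg": [6],
            "rt_ms": [400.0], "se_deg": [0.5], "correct": [True],
        })
        out = behavioral_summaries(trials)
        assert np.isnan(out["imprecision_deg"].iloc[0])


def _fluct(weights):
    labels = tuple(COMPONENTS)
    return ExpressionSeries(weights, labels, zscored=True)


class TestSnippets:
    def test_center_column_is_mgs_tr(self):
        W = np.arange(6 * 60, dtype=float).reshape(6, 60)
        trials = pd.DataFrame({"mgs_tr": [30]})
        stack = extract_snippets(_fluct(W), trials)
        np.testing.assert_array_equal(stack.at(0)[0], W[:, 30])

    def test_out_of_bounds_cells_nan(self):
        W = np.zeros((6, 20))
        stack = extract_snippets(_fluct(W), pd.DataFrame({"mgs_tr": [2]}))
        assert np.isnan(stack.at(-15)[0]).all()
        assert np.isfinite(stack.at(0)[0]).all()

    def test_spike_alignment_oracle(self):
        W = np.zeros((6, 100))
        mgs = [20, 50, 80]
        W[:, mgs] = 5.0
        stack = extract_snippets(_fluct(W), pd.DataFrame({"mgs_tr": mgs}))
        assert np.all(stack.at(0) == 5.0)
        assert np.all(stack.at(3) == 0.0)


def _make_stack(rng, n_trials=300, coupling=0.0, rel_peak=0, n_subjects=2):
    """Synthetic snippet stack with optional maintenance-gain/RT coupling."""
    rel = np.arange(-15, 16)
    data = rng.normal(size=(n_trials, rel.size, 6))
    trials = pd.DataFrame({
        "run_index": rng.integers(1, 4, n_trials),
        "hemifield": rng.choice([-1, 1], n_trials),
        "eccentricity_code": rng.integers(1, 4, n_trials),
        "presentation_s": rng.choice([1.5, 3.0], n_trials),
        "delay_s": rng.choice([1.5, 9.0], n_trials),
        "subject": rng.integers(0, n_subjects, n_trials),
        "mgs_tr": np.full(n_trials, 50),
    })
    maint = data[:, 15 + rel_peak, 2]  # maint_mean at the peak relative TR
    trials["rt_ms"] = 450 + coupling * maint + rng.normal(0, 100, n_trials)
    trials["se_deg"] = rng.normal(0, 1, n_trials)
    trials["correct"] = True
    return SnippetStack(data, rel, trials)


class TestTrialwiseRegression:
    def test_delta_r2_nonnegative(self, rng):
        stack = _make_stack(rng)
        tw = prepare_behavior(stack.trials)
        stack = SnippetStack(stack.data, stack.rel_tr, tw)
        fit = trialwise_regression(stack, "rt", 0, n_sim=200, seed=0)
        assert fit.delta_r2 >= -1e-12
        assert 0 < fit.p_sim <= 1

    def test_coupled_rt_detected_at_peak(self, rng):
        stack = _make_stack(rng, n_trials=400, coupling=-60.0, rel_peak=1)
        tw = prepare_behavior(stack.trials)
        stack = SnippetStack(stack.data, stack.rel_tr, tw)
        scan = trialwise_scan(stack, "rt", rel_trs=range(-3, 5), n_sim=400, seed=1)
        peak = scan.loc[scan["delta_r2"].idxmax()]
        assert peak["rel_tr"] == 1
        assert peak["p_sim"] < 0.01
        assert peak["coef_maint_mean"] < 0  # faster RT with greater expression

    def test_small_nsim_warns(self, rng):
        stack = _make_stack(rng)
        stack = SnippetStack(stack.data, stack.rel_tr, prepare_behavior(stack.trials))
        with pytest.warns(UserWarning):
            trialwise_regression(stack, "rt", 0, n_sim=50, seed=0)

    def test_null_p_values_not_degenerate(self, rng):
        ps = []
        for k in range(10):
            stack = _make_stack(rng, n_trials=200)
            stack = SnippetStack(stack.data, stack.rel_tr,
                                 prepare_behavior(stack.trials))
            ps.append(trialwise_regression(stack, "rt", 0, n_sim=300, seed=k).p_sim)
        assert min(ps) > 0.001 and max(ps) <= 1.0
        assert np.median(ps) > 0.2  # roughly uniform under the null


class TestPrepareBehavior:
    def test_zscore_within_cells(self, rng):
        stack = _make_stack(rng)
        tw = prepare_behavior(stack.trials)
        grp = tw.groupby(["subject", "presentation_s", "delay_s"])["rt_z"]
        assert np.allclose(grp.mean(), 0, atol=1e-10)
        assert (tw["se_zr"] >= 0).all()


class TestSpeedAccuracy:
    def test_exact_quadratic(self, rng):
        rt_z = rng.normal(size=200)
        coef, se, p = speed_accuracy_quadratic(rt_z, rt_z**2)
        assert np.isclose(coef, 1.0, atol=1e-8)
        assert p < 1e-10

    def test_null_coefficient_small(self, rng):
        hits = 0
        for _ in range(40):
            rt_z = rng.normal(size=150)
            se_vals = rng.normal(size=150)
            coef, se, _ = speed_accuracy_quadratic(rt_z, se_vals)
            hits += abs(coef) < 2 * se
        assert hits >= 34  # ~95% nominal coverage, seeded

    def test_u_shaped_generator_recovered(self, rng):
        rt_z = rng.normal(size=300)
        se_vals = 0.5 * rt_z**2 + rng.normal(0, 0.5, 300)
        coef, _, p = speed_accuracy_quadratic(rt_z, se_vals)
        assert coef > 0 and p < 1e-6
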