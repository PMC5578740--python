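"""Timing- vs amplitude-mechanism simulations of the BOLD/RT relationship.

A trial-to-trial correlation between reaction time and brain-state
expression could arise trivially from *timing*: slower saccades shift the
evoked BOLD later, so the state looks under-expressed early and
over-expressed late.  Or it could reflect genuine *amplitude* (gain)
fluctuations.  The two mechanisms separate in the time integral of the mean
residual series for fast vs slow trials (median split):

* timing only  -> both integrals converge to zero (a pure shift preserves
  the integral of the response);
* amplitude only -> integrals converge to non-zero values of opposite sign,
  the fast half positive (fast trials get the positive modulation);
* mixed -> an initial bifurcation followed by partial re-convergence toward
  the amplitude-only terminal value.

Simulated trials are unit impulses in 60 ms bins convolved with the
canonical HRF; 400 trials by default.  Amplitude modulation is linear in RT
between +0.25 (fastest trial) and -0.25 (slowest).
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from scipy.interpolate import PchipInterpolator

from .hrf import hrf_kernel

__all__ = [
    "MechanismSim",
    "simulate_mechanism",
    "amplitude_oracle_integral",
    "integral_signature",
    "EmpiricalSignature",
    "empirical_signature",
    "default_rt_distribution",
]

BIN_S = 0.060
N_TRIALS = 400
AMP_MOD_MAX = 0.25
MODES = ("timing", "amplitude", "mixed")


def default_rt_distribution(n: int, rng) -> np.ndarray:
    """Log-normal MGS reaction times (seconds), median ~0.45 s."""
    return rng.lognormal(mean=np.log(0.45), sigma=0.30, size=n)


def _modulation(rts: np.ndarray, amp_mod_max: float) -> np.ndarray:
    """Linear in RT: +amp_mod_max at the fastest trial, -amp_mod_max at the slowest."""
    lo, hi = rts.min(), rts.max()
    if hi == lo:
        return np.zeros_like(rts)
    return amp_mod_max * (1.0 - 2.0 * (rts - lo) / (hi - lo))


@dataclass(frozen=True)
class MechanismSim:
    mode: str
    rts_s: np.ndarray
    bin_s: float
    fast: np.ndarray  # boolean per trial (median split; fast = at or below median)
    mean_series: np.ndarray
    resid_fast: np.ndarray
    resid_slow: np.ndarray
    cumint_fast: np.ndarray
    cumint_slow: np.ndarray

    @property
    def terminal_fast(self) -> float:
        return float(self.cumint_fast[-1])

    @property
    def terminal_slow(self) -> float:
        return float(self.cumint_slow[-1])


def simulate_mechanism(
    mode: str,
    rt_distribution=None,
    n_trials: int = N_TRIALS,
    seed: int = 0,
    bin_s: float = BIN_S,
    amp_mod_max: float = AMP_MOD_MAX,
    duration_s: float = 40.0,
) -> MechanismSim:
    """Simulate per-trial HRF series under one brain/behavior mechanism.

    ``rt_distribution`` may be an array of RTs in seconds (sampled with
    replacement), a callable ``f(n, rng) -> rts``, or None for the built-in
    log-normal.  The series window (``duration_s``) covers the slowest RT
    plus the full HRF so that a pure time shift leaves the trial integral
    unchanged.
    """
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    rng = np.random.default_rng(seed)
    if rt_distribution is None:
        rts = default_rt_distribution(n_trials, rng)
    elif callable(rt_distribution):
        rts = np.asarray(rt_distribution(n_trials, rng), dtype=float)
    else:
        pool = np.asarray(rt_distribution, dtype=float)
        rts = pool if pool.size == n_trials else rng.choice(pool, n_trials)
    if np.any(rts <= 0):
        raise ValueError("RT distribution must be strictly positive")

    kern = hrf_kernel(bin_s)
    n_bins = int(round(duration_s / bin_s))
    if n_bins < int(rts.max() / bin_s) + kern.size:
        n_bins = int(rts.max() / bin_s) + kern.size + 1

    mod = _modulation(rts, amp_mod_max)
    mean_rt_bin = int(round(rts.mean() / bin_s))
    series = np.zeros((rts.size, n_bins))
    for i, rt in enumerate(rts):
        if mode == "timing":
            idx, height = int(round(rt / bin_s)), 1.0
        elif mode == "amplitude":
            idx, height = mean_rt_bin, 1.0 + mod[i]
        else:
            idx, height = int(round(rt / bin_s)), 1.0 + mod[i]
        end = min(idx + kern.size, n_bins)
        series[i, idx:end] += height * kern[: end - idx]

    mean_series = series.mean(axis=0)
    resid = series - mean_series
    fast = rts <= np.median(rts)
    if fast.all() or not fast.any():
        fast = np.zeros(rts.size, dtype=bool)
        fast[: rts.size // 2] = True
    resid_fast = resid[fast].mean(axis=0)
    resid_slow = resid[~fast].mean(axis=0)
    return MechanismSim(
        mode=mode, rts_s=rts, bin_s=bin_s, fast=fast,
        mean_series=mean_series, resid_fast=resid_fast, resid_slow=resid_slow,
        cumint_fast=np.cumsum(resid_fast) * bin_s,
        cumint_slow=np.cumsum(resid_slow) * bin_s,
    )


def amplitude_oracle_integral(rts_s, fast, bin_s: float = BIN_S,
                              amp_mod_max: float = AMP_MOD_MAX) -> float:
    """Closed-form terminal integral of the fast-half mean residual under the
    amplitude mechanism: (mean modulation of fast trials - grand mean
    modulation) times the HRF time integral."""
    rts = np.asarray(rts_s, dtype=float)
    mod = _modulation(rts, amp_mod_max)
    kern = hrf_kernel(bin_s)
    hrf_integral = kern.sum() * bin_s
    return float((mod[fast].mean() - mod.mean()) * hrf_integral)


def integral_signature(
    sim: MechanismSim,
    timing_fraction: float = 0.05,
    reconvergence_ratio: float = 0.75,
) -> str:
    """Classify a simulation from its residual time integrals.

    The reference magnitude is the amplitude-mechanism closed-form terminal
    integral at the same RTs.  Both terminals below ``timing_fraction`` of
    it -> ``"timing"``; opposite-signed terminals (fast positive) without
    re-convergence -> ``"amplitude"``; with substantial re-convergence from
    the peak -> ``"mixed"``; anything else -> ``"indeterminate"``.
    """
    ref = abs(amplitude_oracle_integral(sim.rts_s, sim.fast, sim.bin_s))
    if ref == 0:
        return "indeterminate"
    tf, ts = sim.terminal_fast, sim.terminal_slow
    if abs(tf) < timing_fraction * ref and abs(ts) < timing_fraction * ref:
        return "timing"
    if tf > 0 and ts < 0:
        peak = max(np.max(np.abs(sim.cumint_fast)), abs(tf))
        if abs(tf) >= reconvergence_ratio * peak:
            return "amplitude"
        return "mixed"
    return "indeterminate"


@dataclass(frozen=True)
class EmpiricalSignature:
    fast_series: np.ndarray
    slow_series: np.ndarray
    cumint_fast: np.ndarray
    cumint_slow: np.ndarray
    bin_s: float


def empirical_signature(
    snippets: np.ndarray,
    rts_ms,
    tr_seconds: float = 1.5,
    bin_s: float = BIN_S,
    min_per_half: int = 10,
) -> EmpiricalSignature:
    """Median-split mean fluctuation series at 60 ms resolution.

    ``snippets`` is (n_trials, n_tr) of a single component's fluctuation
    values beginning at the MGS TR.  Group means are interpolated to
    ``bin_s`` with shape-preserving piecewise-cubic (PCHIP) interpolation
    and cumulatively integrated for comparison with the simulated
    mechanisms.  If the input is already at ``bin_s`` resolution it passes
    through unchanged.
    """
    snip = np.asarray(snippets, dtype=float)
    rts = np.asarray(rts_ms, dtype=float)
    ok = np.isfinite(rts) & np.all(np.isfinite(snip), axis=1)
    snip, rts = snip[ok], rts[ok]
    fast = rts <= np.median(rts)
    if fast.sum() < min_per_half or (~fast).sum() < min_per_half:
        warnings.warn("fewer than %d trials per RT half" % min_per_half, stacklevel=2)

    def interp(series):
        if abs(tr_seconds - bin_s) < 1e-12:
            return series.copy()
        t = np.arange(series.size) * tr_seconds
        tq = np.arange(0.0, t[-1] + bin_s / 2, bin_s)
        return PchipInterpolator(t, series)(tq)

    fast_series = interp(snip[fast].mean(axis=0))
    slow_series = interp(snip[~fast].mean(axis=0))
    return EmpiricalSignature(
        fast_series=fast_series, slow_series=slow_series,
        cumint_fast=np.cumsum(fast_series) * bin_s,
        cumint_slow=np.cumsum(slow_series) * bin_s,
        bin_s=bin_s,
    )
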