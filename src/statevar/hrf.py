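"""Canonical hemodynamic response function.

Double-gamma HRF (response peak at 6 s, undershoot at 16 s, undershoot ratio
1/6) normalized to unit peak amplitude.  The same kernel is used at TR
(1.5 s) resolution by the synthetic generator and at 60 ms resolution by the
reaction-time mechanism simulations.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import gamma as gamma_dist

__all__ = ["double_gamma_hrf", "hrf_kernel"]

PEAK_DELAY_S = 6.0
UNDERSHOOT_DELAY_S = 16.0
DISPERSION_S = 1.0
UNDERSHOOT_RATIO = 1.0 / 6.0


def double_gamma_hrf(t: np.ndarray) -> np.ndarray:
    """Evaluate the canonical double-gamma HRF at times ``t`` (seconds).

    Zero for t < 0; normalized so the positive peak equals 1.
    """
    t = np.asarray(t, dtype=float)
    peak = gamma_dist.pdf(t, PEAK_DELAY_S / DISPERSION_S, scale=DISPERSION_S)
    under = gamma_dist.pdf(
        t, UNDERSHOOT_DELAY_S / DISPERSION_S, scale=DISPERSION_S
    )
    h = peak - UNDERSHOOT_RATIO * under
    # normalize by the analytic peak on a fine grid (unit peak convention)
    tf = np.arange(0, 32, 0.01)
    hf = gamma_dist.pdf(tf, PEAK_DELAY_S / DISPERSION_S, scale=DISPERSION_S) \
        - UNDERSHOOT_RATIO * gamma_dist.pdf(
            tf, UNDERSHOOT_DELAY_S / DISPERSION_S, scale=DISPERSION_S)
    h = h / hf.max()
    return np.where(t >= 0, h, 0.0)


def hrf_kernel(dt_seconds: float, duration_seconds: float = 32.0) -> np.ndarray:
    """Sampled HRF kernel starting at t=0 with bin width ``dt_seconds``."""
    t = np.arange(0.0, duration_seconds, dt_seconds)
    return double_gamma_hrf(t)
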