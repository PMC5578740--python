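"""FIR deconvolution of task fMRI with drift and lagged-motion nuisance.

Voxel-wise average trial time courses for each of the eight trial types
(4 conditions x 2 hemifields) are estimated with a finite-impulse-response
(FIR) regression: one 0/1 indicator column per trial type and per lag, over
a window spanning the trial duration plus 15 extra TRs (22.5 s).  Nuisance
columns model per-run signal drift (third-order Legendre polynomials) and
head motion (seven motion series -- six rigid components plus total
displacement -- each contributing a leading copy at -1 TR and lagging copies
at +1 and +2 TRs, 28 columns in all).

After the fit, trial-average coefficients are rescaled voxel-wise by the
standard deviation of the regression residuals; the residual series itself
is returned unscaled together with its per-voxel SD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.polynomial import legendre as npleg
from sklearn.base import BaseEstimator

from .masks import Mask, MotionSeries, VolumeSeries

__all__ = [
    "legendre_drift",
    "lagged_motion_regressors",
    "framewise_displacement",
    "FIRDesign",
    "build_fir_design",
    "FIRDeconvolver",
    "fir_deconvolve",
    "TrialAverageSet",
    "ResidualSeries",
    "RankDeficientDesignError",
]

MOTION_LAGS = (-1, 0, 1, 2)
FIR_EXTRA_TRS = 15


class RankDeficientDesignError(ValueError):
    """Raised when the FIR design is rank deficient; names collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "rank-deficient design; collinear columns: " + ", ".join(self.columns)
        )


def legendre_drift(n_tr: int, order: int = 3) -> np.ndarray:
    """Legendre drift regressors P_0..P_order evaluated on [-1, 1].

    Returns an (n_tr, order+1) matrix; column k is the degree-k Legendre
    polynomial sampled at ``n_tr`` equally spaced points spanning the run.
    """
    if n_tr < order + 1:
        raise ValueError(f"need at least {order + 1} TRs for order {order}")
    x = np.linspace(-1.0, 1.0, n_tr)
    return npleg.legvander(x, order)


def lagged_motion_regressors(motion: MotionSeries | np.ndarray) -> np.ndarray:
    """Lead/lag copies of the seven motion series.

    Each series m contributes four columns: the leading copy m[t+1] (-1 TR),
    the original m[t], and lagging copies m[t-1] and m[t-2] (+1, +2 TRs).
    Out-of-range samples are filled with the edge value.  Returns
    (n_tr, 28); column order is series-major, lag order (-1, 0, +1, +2).
    """
    if isinstance(motion, MotionSeries):
        stacked = motion.stacked()
    else:
        stacked = np.asarray(motion, dtype=float)
    if stacked.ndim != 2 or stacked.shape[1] != 7:
        raise ValueError("expected 7 motion components (6 rigid + total displacement)")
    n = stacked.shape[0]
    t = np.arange(n)
    cols = []
    for j in range(7):
        for lag in MOTION_LAGS:
            idx = np.clip(t - lag, 0, n - 1)
            cols.append(stacked[idx, j])
    return np.column_stack(cols)


def framewise_displacement(
    motion: MotionSeries | np.ndarray, head_radius_mm: float = 50.0
) -> tuple[np.ndarray, float]:
    """Framewise displacement: Euclidean norm of the motion derivative.

    Rotations (degrees) are converted to arc length at ``head_radius_mm``.
    The first TR is defined as 0.  Returns ``(fd_series, mean_fd)``.
    """
    params = motion.params if isinstance(motion, MotionSeries) else np.asarray(motion, float)
    if params.shape[0] < 2:
        raise ValueError("need at least 2 TRs")
    if not np.all(np.isfinite(params)):
        raise ValueError("non-finite motion values")
    scaled = params.copy()
    scaled[:, 3:6] = np.deg2rad(scaled[:, 3:6]) * head_radius_mm
    d = np.diff(scaled, axis=0)
    fd = np.concatenate([[0.0], np.linalg.norm(d, axis=1)])
    return fd, float(fd.mean())


def _trial_duration_tr(presentation_s, delay_s, tr_seconds) -> int:
    """TRs from stimulus presentation through the MGS, inclusive."""
    return int(round((presentation_s + delay_s) / tr_seconds)) + 1


@dataclass(frozen=True)
class FIRDesign:
    """A TRs x regressors design matrix with partitioned column labels."""

    matrix: np.ndarray
    labels: tuple[str, ...]
    kinds: tuple[str, ...]  # "fir" | "drift" | "motion" per column

    def __post_init__(self):
        if self.matrix.shape[1] != len(self.labels) or len(self.labels) != len(self.kinds):
            raise ValueError("labels/kinds must match column count")

    @property
    def n_tr(self) -> int:
        return self.matrix.shape[0]

    def columns_of_kind(self, kind: str) -> np.ndarray:
        return np.array([k == kind for k in self.kinds])

    def fir_key(self, presentation_s, delay_s, hemifield) -> str:
        return f"p{presentation_s:g}_d{delay_s:g}_h{'R' if hemifield > 0 else 'L'}"


def build_fir_design(
    trials: pd.DataFrame,
    n_tr_per_run: int,
    n_runs: int,
    motion: MotionSeries | None = None,
    tr_seconds: float = 1.5,
    drift_order: int = 3,
) -> FIRDesign:
    """Assemble the session FIR design matrix.

    ``trials`` needs columns run_index, presentation_s, delay_s, hemifield,
    encode_tr, mgs_tr (global TR indices across concatenated runs).  All
    trials enter the FIR model, including incorrect ones.
    """
    n_tr = n_tr_per_run * n_runs
    cols, labels, kinds = [], [], []

    cond_keys = sorted(
        set(zip(trials["presentation_s"], trials["delay_s"], trials["hemifield"]))
    )
    for pres, delay, hemi in cond_keys:
        sub = trials[
            (trials["presentation_s"] == pres)
            & (trials["delay_s"] == delay)
            & (trials["hemifield"] == hemi)
        ]
        n_lags = _trial_duration_tr(pres, delay, tr_seconds) + FIR_EXTRA_TRS
        key = f"p{pres:g}_d{delay:g}_h{'R' if hemi > 0 else 'L'}"
        for lag in range(n_lags):
            col = np.zeros(n_tr)
            for t0 in sub["encode_tr"].to_numpy():
                t = int(t0) + lag
                if t < n_tr:
                    col[t] = 1.0
            cols.append(col)
            labels.append(f"fir:{key}:lag{lag:02d}")
            kinds.append("fir")

    for run in range(n_runs):
        drift = legendre_drift(n_tr_per_run, drift_order)
        for k in range(drift.shape[1]):
            col = np.zeros(n_tr)
            col[run * n_tr_per_run : (run + 1) * n_tr_per_run] = drift[:, k]
            cols.append(col)
            labels.append(f"drift:run{run + 1}:P{k}")
            kinds.append("drift")

    if motion is not None:
        mot = lagged_motion_regressors(motion)
        if mot.shape[0] != n_tr:
            raise ValueError("motion series length does not match design")
        names = ["tx", "ty", "tz", "rx", "ry", "rz", "td"]
        j = 0
        for name in names:
            for lag in MOTION_LAGS:
                cols.append(mot[:, j])
                labels.append(f"motion:{name}:lag{lag:+d}")
                kinds.append("motion")
                j += 1

    return FIRDesign(np.column_stack(cols), tuple(labels), tuple(kinds))


@dataclass(frozen=True)
class TrialAverageSet:
    """FIR coefficient maps per trial type: {key: (n_lags, n_voxels)}."""

    averages: dict
    mask: Mask
    scaled: bool
    tr_seconds: float = 1.5


@dataclass(frozen=True)
class ResidualSeries:
    """Unscaled FIR residuals with their per-voxel standard deviation."""

    series: VolumeSeries
    sd: np.ndarray


class FIRDeconvolver(BaseEstimator):
    """Per-voxel OLS finite-impulse-response deconvolution.

    A single design matrix is shared across voxels and solved by least
    squares (no prewhitening).  Rank deficiency is detected by pivoted QR at
    relative tolerance ``rank_tol`` and reported as an explicit error naming
    the offending columns.

    Attributes (after ``fit``)
    --------------------------
    coef_ : (n_regressors, n_voxels) unscaled coefficients
    trial_averages_ : TrialAverageSet (scaled if ``scale_by_residual_sd``)
    residuals_ : ResidualSeries
    motion_coef_maps_ : (28, n_voxels) motion coefficients, or None
    """

    def __init__(self, scale_by_residual_sd: bool = True, rank_tol: float = 1e-10):
        self.scale_by_residual_sd = scale_by_residual_sd
        self.rank_tol = rank_tol

    def fit(self, series: VolumeSeries, design: FIRDesign):
        X = design.matrix
        if X.shape[0] != series.n_tr:
            raise ValueError("design rows must equal series TR count")

        from scipy.linalg import qr

        _, R, piv = qr(X, mode="economic", pivoting=True)
        diag = np.abs(np.diag(R))
        rank = int(np.sum(diag > self.rank_tol * diag[0]))
        if rank < X.shape[1]:
            dropped = [design.labels[p] for p in piv[rank:]]
            raise RankDeficientDesignError(dropped)

        Y = series.data.T  # TRs x voxels
        coef, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ coef
        sd = resid.std(axis=0, ddof=0)

        self.design_ = design
        self.coef_ = coef
        self.residual_sd_ = sd
        self.residuals_ = ResidualSeries(
            VolumeSeries(resid.T, series.mask, series.tr_seconds), sd
        )

        averages = {}
        labels = np.asarray(design.labels)
        safe_sd = np.where(sd > 0, sd, 1.0)
        fir_mask = design.columns_of_kind("fir")
        keys = sorted({lab.split(":")[1] for lab in labels[fir_mask]})
        for key in keys:
            idx = [i for i, lab in enumerate(labels) if lab.startswith(f"fir:{key}:")]
            block = coef[idx, :]
            if self.scale_by_residual_sd:
                block = block / safe_sd[None, :]
            averages[key] = block
        self.trial_averages_ = TrialAverageSet(
            averages, series.mask, self.scale_by_residual_sd, series.tr_seconds
        )

        mot_idx = np.where(design.columns_of_kind("motion"))[0]
        if mot_idx.size:
            block = coef[mot_idx, :]
            self.motion_coef_maps_ = block
        else:
            self.motion_coef_maps_ = None
        return self


def fir_deconvolve(
    series: VolumeSeries, design: FIRDesign, scale_by_residual_sd: bool = True
) -> tuple[TrialAverageSet, ResidualSeries]:
    """Functional wrapper over :class:`FIRDeconvolver`."""
    dec = FIRDeconvolver(scale_by_residual_sd=scale_by_residual_sd).fit(series, design)
    return dec.trial_averages_, dec.residuals_
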