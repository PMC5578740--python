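"""Canonical task brain states.

Three task processes -- the visuomotor/encoding saccade (VME), working-memory
maintenance, and retrieval (the memory-guided saccade, MGS) -- are each
summarized by a whole-brain pattern extracted from long-delay average trial
time courses.  Each state is split into a *mean* component (hemifield-averaged
pattern) and a *spatial* component (right-target minus left-target pattern),
so that per-hemifield activity is a linear combination of the two:
``right = mean + spatial/2`` and ``left = mean - spatial/2``.

Construction steps:

1. epoch extraction at a 4-TR (6 s) hemodynamic lag after the encoding
   saccade (VME) and after the MGS (retrieval), and at the TR immediately
   before the MGS (maintenance);
2. sequential orthogonalization -- maintenance patterns are residualized on
   every pattern up to and including the encoding saccade, retrieval patterns
   on every pattern before the MGS;
3. mean/spatial decomposition;
4. mirror symmetrization: mean components are averaged with their left/right
   mirror, spatial components with their sign-inverted mirror, making them
   exactly symmetric / antisymmetric under the mask's voxel pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .deconvolution import TrialAverageSet, _trial_duration_tr
from .masks import Mask, MaskedVolume

__all__ = [
    "COMPONENTS",
    "BrainStateSet",
    "StateMask",
    "build_state_mask",
    "extract_epoch_pattern",
    "orthogonalize",
    "mean_spatial_decompose",
    "mirror_symmetrize",
    "StateExtractor",
    "group_average_timecourses",
]

#: canonical component order used everywhere downstream
COMPONENTS = (
    "vme_mean",
    "vme_spatial",
    "maint_mean",
    "maint_spatial",
    "retr_mean",
    "retr_spatial",
)

HEMODYNAMIC_LAG_TR = 4


@dataclass(frozen=True)
class BrainStateSet:
    """The six canonical patterns: (VME|maint|retr) x (mean|spatial)."""

    volumes: dict  # component name -> MaskedVolume
    lag_tr: int = HEMODYNAMIC_LAG_TR
    provenance: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = set(COMPONENTS) - set(self.volumes)
        if missing:
            raise ValueError(f"missing components: {sorted(missing)}")

    @property
    def mask(self) -> Mask:
        return self.volumes[COMPONENTS[0]].mask

    def matrix(self) -> np.ndarray:
        """(n_voxels, 6) pattern matrix in canonical component order."""
        return np.column_stack([self.volumes[c].values for c in COMPONENTS])

    def normalized(self) -> "BrainStateSet":
        """Unit-vector-norm copy of every component."""
        vols = {
            c: MaskedVolume(v.values / np.linalg.norm(v.values), v.mask)
            for c, v in self.volumes.items()
        }
        return BrainStateSet(vols, self.lag_tr, dict(self.provenance))


@dataclass(frozen=True)
class StateMask:
    """Voxel subset where states are defined (gray matter, reliably imaged)."""

    include: np.ndarray
    mask: Mask
    p_thresh: float = 0.5
    r2_thresh: float = 0.27

    def __post_init__(self):
        inc = np.asarray(self.include, dtype=bool)
        if inc.shape != (self.mask.n_voxels,):
            raise ValueError("include length must equal mask voxel count")
        if not inc.any():
            raise ValueError("state mask is empty")
        object.__setattr__(self, "include", inc)


def build_state_mask(
    gray_prob: MaskedVolume,
    group_r2: MaskedVolume,
    p_thresh: float = 0.5,
    r2_thresh: float = 0.27,
) -> StateMask:
    """Intersect a gray-matter probability map with a group R^2 map.

    A voxel is kept iff ``gray_prob >= p_thresh`` and ``group_r2 >= r2_thresh``.
    """
    if gray_prob.mask is not group_r2.mask and gray_prob.mask.mask_id != group_r2.mask.mask_id:
        raise ValueError("volumes must share a mask")
    include = (gray_prob.values >= p_thresh) & (group_r2.values >= r2_thresh)
    return StateMask(include, gray_prob.mask, p_thresh, r2_thresh)


def _parse_key(key: str) -> tuple[float, float, int]:
    pres_s, delay_s, hemi_s = key.split("_")
    return float(pres_s[1:]), float(delay_s[1:]), (+1 if hemi_s[1:] == "R" else -1)


def extract_epoch_pattern(
    trial_avg: TrialAverageSet,
    event: str,
    lag_tr: int = HEMODYNAMIC_LAG_TR,
    long_delay_s: float = 9.0,
) -> dict:
    """Extract per-trial-type volumes at an event-locked lag.

    ``event`` is ``"encode"`` (lag counted from the encoding saccade),
    ``"mgs"`` (from the MGS), or ``"pre-mgs"`` (fixed -1 TR from the MGS;
    ``lag_tr`` is ignored).  Only long-delay trial types contribute.
    Returns {key: MaskedVolume} for the long-delay keys.
    """
    out = {}
    for key, block in trial_avg.averages.items():
        pres, delay, _ = _parse_key(key)
        if delay != long_delay_s:
            continue
        mgs_lag = _trial_duration_tr(pres, delay, trial_avg.tr_seconds) - 1
        if event == "encode":
            idx = lag_tr
        elif event == "mgs":
            idx = mgs_lag + lag_tr
        elif event == "pre-mgs":
            idx = mgs_lag - 1
        else:
            raise ValueError(f"unknown event {event!r}")
        if not 0 <= idx < block.shape[0]:
            raise ValueError(f"lag {idx} out of range for trial type {key}")
        out[key] = MaskedVolume(block[idx], trial_avg.mask)
    if not out:
        raise ValueError("no long-delay trial types present")
    return out


def orthogonalize(targets, references) -> list:
    """Residualize each target volume on the reference volumes across voxels.

    OLS with an intercept; residuals are orthogonal to every (centered)
    reference within numerical tolerance.  References must be linearly
    independent.
    """
    tgt = [np.asarray(t) for t in targets]
    mask = targets[0].mask if isinstance(targets[0], MaskedVolume) else None
    R = np.column_stack([np.asarray(r) for r in references])
    X = np.column_stack([np.ones(R.shape[0]), R])
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("collinear references")
    coef, *_ = np.linalg.lstsq(X, np.column_stack(tgt), rcond=None)
    resid = np.column_stack(tgt) - X @ coef
    out = []
    for j in range(resid.shape[1]):
        v = resid[:, j]
        out.append(MaskedVolume(v, mask) if mask is not None else v)
    return out


def mean_spatial_decompose(right: MaskedVolume, left: MaskedVolume):
    """mean = (right + left)/2, spatial = right - left."""
    if right.mask.mask_id != left.mask.mask_id:
        raise ValueError("mask mismatch")
    mean = MaskedVolume((right.values + left.values) / 2.0, right.mask)
    spatial = MaskedVolume(right.values - left.values, right.mask)
    return mean, spatial


def mirror_symmetrize(states: BrainStateSet) -> BrainStateSet:
    """Average each component with its (sign-inverted, for spatial) mirror.

    Output mean components are exactly symmetric and spatial components
    exactly antisymmetric under the mask's left/right voxel pairing.
    """
    vols = {}
    for name, vol in states.volumes.items():
        mirrored = vol.mask.mirror(vol.values)
        if name.endswith("_spatial"):
            vals = (vol.values - mirrored) / 2.0
        else:
            vals = (vol.values + mirrored) / 2.0
        vols[name] = MaskedVolume(vals, vol.mask)
    return BrainStateSet(vols, states.lag_tr, dict(states.provenance, mirrored=True))


def group_average_timecourses(
    trial_avg_sets: list,
    ages=None,
    displacement=None,
    incorrect_prop=None,
) -> TrialAverageSet:
    """Covariate-adjusted group-average trial time courses.

    Fixed-effects OLS per voxel and lag with mean-centered age, total
    displacement, and incorrect-trial-proportion covariates; the returned
    averages are the model predictions at mean age, zero displacement and
    perfect performance (the estimand of a covariate-adjusted group mean).
    With no covariates this reduces to the plain across-session average.
    """
    n = len(trial_avg_sets)
    if n == 0:
        raise ValueError("no sessions")
    cols = [np.ones(n)]
    targets = []
    if ages is not None:
        a = np.asarray(ages, dtype=float)
        cols.append(a - a.mean())
        targets.append(0.0)
    if displacement is not None:
        cols.append(np.asarray(displacement, dtype=float))
        targets.append(0.0)
    if incorrect_prop is not None:
        cols.append(np.asarray(incorrect_prop, dtype=float))
        targets.append(0.0)
    X = np.column_stack(cols)
    x0 = np.concatenate([[1.0], np.asarray(targets)])

    keys = trial_avg_sets[0].averages.keys()
    out = {}
    for key in keys:
        stack = np.stack([s.averages[key] for s in trial_avg_sets])  # n x lags x vox
        flat = stack.reshape(n, -1)
        coef, *_ = np.linalg.lstsq(X, flat, rcond=None)
        out[key] = (x0 @ coef).reshape(stack.shape[1:])
    first = trial_avg_sets[0]
    return TrialAverageSet(out, first.mask, first.scaled, first.tr_seconds)


class StateExtractor(BaseEstimator):
    """Build the six canonical brain states from group trial averages.

    Parameters
    ----------
    lag_tr : hemodynamic lag in TRs for the VME and retrieval epochs (4 TRs
        = 6 s at TR 1.5 s).
    long_delay_s : which delay condition counts as "long"; only those trials
        are used, maximizing separation of the three epochs.
    normalize : return unit-norm components (the convention assumed by the
        projection stage).

    After ``fit``, ``states_`` holds the BrainStateSet.
    """

    def __init__(self, lag_tr: int = HEMODYNAMIC_LAG_TR, long_delay_s: float = 9.0,
                 normalize: bool = True, ref_norm_floor: float = 0.05,
                 ref_sv_tol: float = 0.08):
        self.lag_tr = lag_tr
        self.long_delay_s = long_delay_s
        self.normalize = normalize
        self.ref_norm_floor = ref_norm_floor
        self.ref_sv_tol = ref_sv_tol

    def _residualize(self, patterns: dict, refs, scale: float,
                     extra_refs=()) -> dict:
        kept = [r for r in refs if np.linalg.norm(r) >= self.ref_norm_floor * scale]
        basis = _principal_directions(kept, self.ref_sv_tol) if kept else []
        basis += [np.asarray(r) / np.linalg.norm(r) for r in extra_refs]
        if not basis:
            return patterns
        keys = sorted(patterns)
        out = orthogonalize([patterns[k] for k in keys], basis)
        return dict(zip(keys, out))

    def fit(self, trial_avg: TrialAverageSet):
        lag, longd = self.lag_tr, self.long_delay_s
        vme = extract_epoch_pattern(trial_avg, "encode", lag, longd)
        maint = extract_epoch_pattern(trial_avg, "pre-mgs", lag, longd)
        retr = extract_epoch_pattern(trial_avg, "mgs", lag, longd)

        # reference sets for the sequential orthogonalization: maintenance is
        # residualized on the patterns up to and including the encoding
        # saccade plus the extracted VME patterns; retrieval on every pattern
        # occurring before the MGS TR
        pre_encode_refs, pre_mgs_refs = [], []
        for key, block in trial_avg.averages.items():
            pres, delay, _ = _parse_key(key)
            if delay != longd:
                continue
            mgs_lag = _trial_duration_tr(pres, delay, trial_avg.tr_seconds) - 1
            pre_encode_refs.append(block[0])  # the encoding-saccade TR
            for i in range(mgs_lag):
                pre_mgs_refs.append(block[i])

        def decompose(pats):
            rights = [v for k, v in sorted(pats.items()) if _parse_key(k)[2] > 0]
            lefts = [v for k, v in sorted(pats.items()) if _parse_key(k)[2] < 0]
            if not rights or not lefts:
                raise ValueError("need both hemifields among long-delay trial types")
            right = MaskedVolume(np.mean([np.asarray(v) for v in rights], axis=0),
                                 trial_avg.mask)
            left = MaskedVolume(np.mean([np.asarray(v) for v in lefts], axis=0),
                                trial_avg.mask)
            return mean_spatial_decompose(right, left)

        scale = max(np.linalg.norm(r) for r in pre_mgs_refs)
        vme_mean, vme_spatial = decompose(vme)
        maint = self._residualize(
            maint, pre_encode_refs, scale,
            extra_refs=[vme_mean.values, vme_spatial.values],
        )
        retr = self._residualize(retr, pre_mgs_refs, scale)

        vols = {"vme_mean": vme_mean, "vme_spatial": vme_spatial}
        for prefix, pats in (("maint", maint), ("retr", retr)):
            mean, spatial = decompose(pats)
            vols[f"{prefix}_mean"] = mean
            vols[f"{prefix}_spatial"] = spatial

        states = BrainStateSet(vols, lag, {"long_delay_s": longd})
        states = mirror_symmetrize(states)
        if self.normalize:
            states = states.normalized()
        self.states_ = states
        return self


def _principal_directions(vectors, sv_tol: float = 0.08) -> list:
    """Principal directions of a reference set with relative SV >= sv_tol.

    Residualizing targets on this subspace, rather than on the raw noisy
    reference volumes, prevents reference noise and small estimation leakage
    from spanning (and hence removing) directions the references do not
    actually contain.
    """
    M = np.column_stack([np.asarray(v) for v in vectors])
    U, s, _ = np.linalg.svd(M, full_matrices=False)
    if s.size == 0 or s[0] == 0:
        return []
    keep = s >= sv_tol * s[0]
    return [U[:, i] for i in range(s.size) if keep[i]]
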