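"""Spatial nuisance templates: motion-artifact patterns plus trivial modes.

Motion templates capture the spatial structure of linear motion artifacts
remaining after deconvolution.  Each of the 28 lagged-motion coefficient maps
(7 motion series x 4 lags, averaged across sessions) is divided voxel-wise
by the residual SD, spatial-mean-centered, and scaled to a common vector
magnitude; an uncentered PCA over the 28 maps then yields the smallest set
of orthonormal templates capturing more than ``variance_target`` (90%) of
their variability.

To these are added templates for trivial modes of whole-volume signal
change: a whole-volume constant, a state-mask constant, three linear spatial
gradients (voxel coordinates relative to the mask's center of mass, zeroed
outside the mask), and their three pairwise products.  With 11 motion
templates the full set has 19 members.
"""

from __future__ import annotations

from dataclasses import dataclass
import warnings

import numpy as np
from sklearn.base import BaseEstimator

from .masks import Mask, MaskedVolume

__all__ = [
    "NuisanceSet",
    "MotionTemplatePCA",
    "motion_templates",
    "spatial_gradient_templates",
    "build_nuisance_set",
]


@dataclass(frozen=True)
class NuisanceSet:
    """Ordered nuisance volumes: motion templates then constants/gradients."""

    volumes: dict  # name -> MaskedVolume
    motion_variance_captured: np.ndarray  # explained-variance fraction per template

    @property
    def n_motion(self) -> int:
        return sum(1 for k in self.volumes if k.startswith("motion_pc"))

    @property
    def names(self) -> tuple:
        return tuple(self.volumes)

    def matrix(self) -> np.ndarray:
        return np.column_stack([v.values for v in self.volumes.values()])

    def __len__(self) -> int:
        return len(self.volumes)


class MotionTemplatePCA(BaseEstimator):
    """Principal motion-artifact templates from lagged-motion coefficient maps.

    The PCA is uncentered across maps: maps are already spatial-mean-centered
    and scaled to a common vector magnitude, so the decomposition preserves
    that normalization rather than re-centering across the 28-map set.

    Attributes (after ``fit``)
    --------------------------
    templates_ : (k, n_voxels) orthonormal template vectors
    explained_variance_ratio_ : fraction of map-set variance per template
    n_templates_ : smallest k with cumulative variance > variance_target
    """

    def __init__(self, variance_target: float = 0.90):
        self.variance_target = variance_target

    def fit(self, coef_maps: np.ndarray, residual_sd: np.ndarray | None = None):
        M = np.asarray(coef_maps, dtype=float)  # n_maps x n_voxels
        if M.ndim != 2 or M.shape[0] < 2:
            raise ValueError("need at least 2 coefficient maps")
        if residual_sd is not None:
            sd = np.asarray(residual_sd, dtype=float)
            M = M / np.where(sd > 0, sd, 1.0)[None, :]
        M = M - M.mean(axis=1, keepdims=True)
        norms = np.linalg.norm(M, axis=1)
        M = M / np.where(norms > 0, norms, 1.0)[:, None]

        # uncentered PCA = SVD of the normalized map stack
        _, s, Vt = np.linalg.svd(M, full_matrices=False)
        var = s**2
        total = var.sum()
        ratio = var / total if total > 0 else var
        cum = np.cumsum(ratio)
        k = int(np.searchsorted(cum, self.variance_target) + 1)
        k = min(k, len(ratio))
        self.templates_ = Vt[:k]
        self.explained_variance_ratio_ = ratio[:k]
        self.n_templates_ = k
        return self


def motion_templates(
    coef_maps, residual_sd=None, variance_target: float = 0.90, mask: Mask | None = None
):
    """Functional wrapper: returns (list of MaskedVolume or arrays, ratios)."""
    if isinstance(coef_maps, (list, tuple)) and coef_maps and isinstance(coef_maps[0], MaskedVolume):
        mask = coef_maps[0].mask
        coef_maps = np.stack([v.values for v in coef_maps])
    pca = MotionTemplatePCA(variance_target).fit(
        np.asarray(coef_maps), None if residual_sd is None else np.asarray(residual_sd)
    )
    if mask is not None:
        vols = [MaskedVolume(t, mask) for t in pca.templates_]
    else:
        vols = list(pca.templates_)
    return vols, pca.explained_variance_ratio_


def spatial_gradient_templates(mask: Mask, state_include: np.ndarray | None = None) -> dict:
    """Constant and gradient templates from the mask geometry.

    Returns, in order: whole-volume constant, state-mask constant, x/y/z
    gradients relative to the mask center of mass, and the xy/xz/yz products.
    Gradients are zero outside the mask by construction (the mask is the
    voxel universe here).
    """
    coords = mask.coords.astype(float)
    centered = coords - coords.mean(axis=0)
    if np.linalg.matrix_rank(centered) < 3:
        warnings.warn("degenerate mask geometry: voxels are coplanar", stacklevel=2)
    out = {
        "const_whole": MaskedVolume(np.ones(mask.n_voxels), mask),
        "grad_x": MaskedVolume(centered[:, 0], mask),
        "grad_y": MaskedVolume(centered[:, 1], mask),
        "grad_z": MaskedVolume(centered[:, 2], mask),
        "grad_xy": MaskedVolume(centered[:, 0] * centered[:, 1], mask),
        "grad_xz": MaskedVolume(centered[:, 0] * centered[:, 2], mask),
        "grad_yz": MaskedVolume(centered[:, 1] * centered[:, 2], mask),
    }
    if state_include is not None and not bool(np.all(state_include)):
        # a state-mask constant identical to the whole-volume constant would
        # be collinear; include it only when the state mask is a proper subset
        items = list(out.items())
        items.insert(1, ("const_statemask",
                         MaskedVolume(np.asarray(state_include, float), mask)))
        out = dict(items)
    return out


def build_nuisance_set(
    coef_maps,
    residual_sd,
    mask: Mask,
    variance_target: float = 0.90,
    state_include: np.ndarray | None = None,
) -> NuisanceSet:
    """Assemble motion templates plus the 8 constant/gradient templates."""
    vols, ratios = motion_templates(coef_maps, residual_sd, variance_target, mask)
    volumes = {f"motion_pc{i + 1}": v for i, v in enumerate(vols)}
    volumes.update(spatial_gradient_templates(mask, state_include))
    return NuisanceSet(volumes, np.asarray(ratios))
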