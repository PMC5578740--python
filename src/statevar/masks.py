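"""Masked whole-brain containers.

Every stage of the pipeline operates on voxel vectors restricted to a fixed
brain mask.  A :class:`Mask` carries the voxel coordinates (for NIfTI
round-trips and spatial-gradient templates) and a left/right voxel pairing
used by the mirror-symmetrization step.  :class:`MaskedVolume` is a single
whole-brain pattern, :class:`VolumeSeries` a voxels x TRs matrix, and
:class:`MotionSeries` the six rigid-body parameters plus total displacement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "Mask",
    "MaskedVolume",
    "VolumeSeries",
    "MotionSeries",
    "volume_to_nifti",
    "series_to_nifti",
    "series_from_nifti",
    "motion_to_csv",
    "motion_from_csv",
]


@dataclass(frozen=True)
class Mask:
    """A fixed set of in-brain voxels.

    Parameters
    ----------
    coords : (n_voxels, 3) int array
        Integer grid coordinates of each voxel, used when embedding masked
        vectors back into a 3D volume and when building spatial-gradient
        templates.
    pairing : (n_voxels,) int array
        Index of the left/right mirror partner of each voxel.  Must be an
        involution (``pairing[pairing] == arange(n)``).  Midline voxels may
        map to themselves.
    mask_id : str
        Identifier carried by every volume defined on this mask; volumes from
        different masks never mix silently.
    """

    coords: np.ndarray
    pairing: np.ndarray
    mask_id: str = "mask"

    def __post_init__(self):
        coords = np.asarray(self.coords, dtype=int)
        pairing = np.asarray(self.pairing, dtype=int)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be (n_voxels, 3)")
        if pairing.shape != (coords.shape[0],):
            raise ValueError("pairing length must equal voxel count")
        if not np.array_equal(pairing[pairing], np.arange(coords.shape[0])):
            raise ValueError("pairing must be an involution on the mask")
        object.__setattr__(self, "coords", coords)
        object.__setattr__(self, "pairing", pairing)

    @property
    def n_voxels(self) -> int:
        return self.coords.shape[0]

    @property
    def grid_shape(self) -> tuple[int, int, int]:
        return tuple(int(m) + 1 for m in self.coords.max(axis=0))

    def mirror(self, values: np.ndarray) -> np.ndarray:
        """Apply the left/right pairing along the voxel axis."""
        return np.asarray(values)[self.pairing]


def _check_values(values, mask: Mask, n_axis_len=None):
    values = np.asarray(values, dtype=float)
    if values.shape[0] != mask.n_voxels:
        raise ValueError(
            f"expected {mask.n_voxels} voxels, got {values.shape[0]}"
        )
    if not np.all(np.isfinite(values)):
        raise ValueError("non-finite voxel values")
    return values


@dataclass(frozen=True)
class MaskedVolume:
    """A single whole-brain pattern restricted to a mask."""

    values: np.ndarray
    mask: Mask

    def __post_init__(self):
        object.__setattr__(self, "values", _check_values(self.values, self.mask))

    def mirrored(self) -> "MaskedVolume":
        return MaskedVolume(self.mask.mirror(self.values), self.mask)

    def __array__(self, dtype=None, copy=None):
        return np.asarray(self.values, dtype=dtype)


@dataclass(frozen=True)
class VolumeSeries:
    """A voxels x TRs BOLD matrix on a fixed mask."""

    data: np.ndarray
    mask: Mask
    tr_seconds: float = 1.5

    def __post_init__(self):
        data = _check_values(self.data, self.mask)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (voxels x TRs)")
        object.__setattr__(self, "data", data)

    @property
    def n_tr(self) -> int:
        return self.data.shape[1]

    def volume(self, t: int) -> MaskedVolume:
        return MaskedVolume(self.data[:, t], self.mask)


@dataclass(frozen=True)
class MotionSeries:
    """Rigid-body head motion: 3 translations (mm), 3 rotations (deg)."""

    params: np.ndarray
    head_radius_mm: float = 50.0
    total_displacement: np.ndarray = field(default=None)

    def __post_init__(self):
        params = np.asarray(self.params, dtype=float)
        if params.ndim != 2 or params.shape[1] != 6:
            raise ValueError("params must be (n_tr, 6)")
        if not np.all(np.isfinite(params)):
            raise ValueError("non-finite motion values")
        object.__setattr__(self, "params", params)
        if self.total_displacement is None:
            from .deconvolution import framewise_displacement

            fd, _ = framewise_displacement(params, self.head_radius_mm)
            object.__setattr__(self, "total_displacement", fd)
        else:
            td = np.asarray(self.total_displacement, dtype=float)
            if td.shape != (params.shape[0],) or np.any(td < 0):
                raise ValueError("total_displacement must be nonnegative per TR")
            object.__setattr__(self, "total_displacement", td)

    @property
    def n_tr(self) -> int:
        return self.params.shape[0]

    def stacked(self) -> np.ndarray:
        """(n_tr, 7): six rigid components plus total displacement."""
        return np.column_stack([self.params, self.total_displacement])


# ---------------------------------------------------------------------------
# standard-format I/O (NIfTI-1 via nibabel, CSV via pandas)

def _embed(mask: Mask, values: np.ndarray) -> np.ndarray:
    grid = np.zeros(mask.grid_shape + values.shape[1:], dtype=np.float32)
    grid[tuple(mask.coords.T)] = values
    return grid


def volume_to_nifti(vol: MaskedVolume, affine=None) -> nib.Nifti1Image:
    affine = np.eye(4) if affine is None else affine
    return nib.Nifti1Image(_embed(vol.mask, vol.values[:, None])[..., 0], affine)


def series_to_nifti(series: VolumeSeries, affine=None) -> nib.Nifti1Image:
    affine = np.eye(4) if affine is None else affine
    img = nib.Nifti1Image(_embed(series.mask, series.data), affine)
    img.header["pixdim"][4] = series.tr_seconds
    return img


def mask_to_nifti(mask: Mask, affine=None) -> nib.Nifti1Image:
    affine = np.eye(4) if affine is None else affine
    grid = np.zeros(mask.grid_shape, dtype=np.uint8)
    grid[tuple(mask.coords.T)] = 1
    return nib.Nifti1Image(grid, affine)


def series_from_nifti(img, mask: Mask, tr_seconds: float = 1.5) -> VolumeSeries:
    data = np.asanyarray(img.dataobj, dtype=float)
    return VolumeSeries(data[tuple(mask.coords.T)], mask, tr_seconds)


MOTION_COLUMNS = ["trans_x_mm", "trans_y_mm", "trans_z_mm",
                  "rot_x_deg", "rot_y_deg", "rot_z_deg"]


def motion_to_csv(motion: MotionSeries, path) -> None:
    df = pd.DataFrame(motion.params, columns=MOTION_COLUMNS)
    df["total_displacement_mm"] = motion.total_displacement
    df.to_csv(path, index=False)


def motion_from_csv(path) -> MotionSeries:
    df = pd.read_csv(path, sep=None, engine="python")
    return MotionSeries(
        df[MOTION_COLUMNS].to_numpy(),
        total_displacement=df["total_displacement_mm"].to_numpy()
        if "total_displacement_mm" in df else None,
    )
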