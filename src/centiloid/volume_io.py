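"""NIfTI-1 volume I/O, header-only rigid reorientation, and resampling.

All images in the pipeline are carried as :class:`Volume` (a 3-D scalar
lattice plus a voxel-to-world affine in RAS+ millimetres) or
:class:`MaskVolume` (weights in [0, 1]).  The world convention follows the
NIfTI sform; the qform is used only as a fallback on read.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "Volume",
    "MaskVolume",
    "read_volume",
    "write_volume",
    "reorient_by_header",
    "resample_to",
    "grid_of",
]


class VolumeFormatError(ValueError):
    """Raised when a file is not a readable single-frame NIfTI-1 volume."""


@dataclass
class Volume:
    """A 3-D scalar image with a voxel-to-world affine (mm, RAS+)."""

    data: np.ndarray
    affine: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        self.affine = np.asarray(self.affine, dtype=np.float64)
        if self.data.ndim != 3:
            raise VolumeFormatError(
                f"expected a 3-D volume, got shape {self.data.shape}"
            )
        if self.affine.shape != (4, 4):
            raise ValueError(f"affine must be 4x4, got {self.affine.shape}")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine upper-left 3x3 block is singular")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.data.shape

    @property
    def voxel_sizes(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.sqrt((self.affine[:3, :3] ** 2).sum(axis=0))

    def copy(self) -> "Volume":
        return Volume(self.data.copy(), self.affine.copy(), dict(self.meta))


@dataclass
class MaskVolume(Volume):
    """A weight volume in [0, 1]; ``binary`` masks hold only {0, 1}."""

    kind: Literal["binary", "probabilistic"] = "binary"

    def __post_init__(self) -> None:
        super().__post_init__()
        d = self.data
        if d.min() < 0 or d.max() > 1:
            raise ValueError("mask values must lie in [0, 1]")
        if self.kind == "binary" and not np.isin(np.unique(d), (0, 1)).all():
            raise ValueError("binary mask contains values outside {0, 1}")
        if d.sum() <= 0:
            raise ValueError("mask is empty (sum of weights is 0)")


def grid_of(vol: Volume) -> tuple[tuple[int, int, int], np.ndarray]:
    """Return the (shape, affine) grid specification of a volume."""
    return vol.shape, vol.affine


def _as_grid(target) -> tuple[tuple[int, ...], np.ndarray]:
    if isinstance(target, Volume):
        return target.shape, target.affine
    shape, affine = target
    return tuple(int(s) for s in shape), np.asarray(affine, dtype=np.float64)


def read_volume(path: str | Path) -> Volume:
    """Read a single-frame NIfTI-1 volume.

    The world affine is taken from the sform when its code is valid,
    otherwise from the qform.  Intensity scaling (``scl_slope`` /
    ``scl_inter``) is applied by nibabel on load.
    """
    path = Path(path)
    try:
        img = nib.load(str(path))
    except Exception as exc:  # nibabel raises several unrelated types
        raise VolumeFormatError(f"cannot read {path} as NIfTI-1: {exc}") from exc
    if not isinstance(img, nib.Nifti1Image):
        raise VolumeFormatError(f"{path} is not a NIfTI-1 image ({type(img).__name__})")
    shape = img.shape
    if len(shape) == 4 and shape[3] == 1:
        pass  # single-frame 4-D is squeezed below
    elif len(shape) != 3:
        raise VolumeFormatError(
            f"{path} has shape {shape}; only single-frame 3-D volumes are supported"
        )
    sform, sform_code = img.get_sform(coded=True)
    qform, qform_code = img.get_qform(coded=True)
    if sform_code > 0:
        affine = sform
    elif qform_code > 0:
        affine = qform
    else:
        affine = img.affine
    data = np.asarray(img.get_fdata(dtype=np.float32))
    if data.ndim == 4:
        data = data[..., 0]
    return Volume(
        data,
        affine,
        meta={"source": str(path), "sform_code": int(sform_code)},
    )


def write_volume(vol: Volume, path: str | Path, dtype=np.float32) -> Path:
    """Write a volume as NIfTI-1 with the sform set (code 2, 'aligned')."""
    path = Path(path)
    img = nib.Nifti1Image(np.asarray(vol.data, dtype=dtype), vol.affine)
    img.set_sform(vol.affine, code=2)
    img.set_qform(vol.affine, code=2)
    nib.save(img, str(path))
    return path


def _check_rigid(rigid: np.ndarray) -> np.ndarray:
    rigid = np.asarray(rigid, dtype=np.float64)
    if rigid.shape != (4, 4):
        raise ValueError("rigid transform must be a 4x4 homogeneous matrix")
    R = rigid[:3, :3]
    if np.abs(R.T @ R - np.eye(3)).max() > 1e-6:
        raise ValueError("matrix rotation block is not orthonormal: not a rigid-body transform")
    if np.abs(rigid[3] - (0, 0, 0, 1)).max() > 1e-9:
        raise ValueError("last row of a homogeneous rigid transform must be (0,0,0,1)")
    return rigid


def reorient_by_header(vol: Volume, rigid: np.ndarray) -> Volume:
    """Rigidly reorient a volume by updating its affine only.

    The voxel lattice is untouched — no interpolation happens; the world
    pose changes because the new affine is ``rigid @ old_affine``.  This is
    the header-update rigid pre-registration step: the transform is stored
    in the sform instead of resampling the image.
    """
    rigid = _check_rigid(rigid)
    out = vol.copy()
    out.affine = rigid @ vol.affine
    out.meta.setdefault("reorientations", []).append(rigid.tolist())
    return out


def resample_to(
    vol: Volume,
    target_grid,
    interpolation: Literal["trilinear", "nearest"] = "trilinear",
) -> Volume:
    """Resample a volume onto a target grid (a Volume or ``(shape, affine)``).

    Pull-back sampling: each target voxel centre is mapped through the two
    affines into source voxel coordinates and interpolated there.  Voxels
    outside the source support are set to 0 and counted in
    ``meta["n_out_of_support"]``; a boolean validity mask is stored in
    ``meta["support_mask"]`` so downstream VOI statistics can exclude them.
    """
    shape, affine = _as_grid(target_grid)
    if any(s <= 0 for s in shape):
        raise ValueError(f"degenerate target grid with shape {shape}")
    src2vox = np.linalg.inv(vol.affine) @ affine
    coords = _voxel_coords(shape, src2vox)
    order = {"trilinear": 1, "nearest": 0}[interpolation]
    out = ndimage.map_coordinates(
        np.asarray(vol.data, dtype=np.float64), coords, order=order,
        mode="constant", cval=0.0,
    ).reshape(shape)
    lim = np.asarray(vol.shape, dtype=np.float64) - 1
    inside = np.ones(shape, dtype=bool).reshape(-1)
    for ax in range(3):
        inside &= (coords[ax].ravel() >= -0.5) & (coords[ax].ravel() <= lim[ax] + 0.5)
    inside = inside.reshape(shape)
    meta = dict(vol.meta)
    meta["n_out_of_support"] = int((~inside).sum())
    meta["support_mask"] = inside
    return Volume(out.astype(vol.data.dtype, copy=False), affine, meta)


def _voxel_coords(shape: tuple[int, ...], vox2vox: np.ndarray) -> np.ndarray:
    """Source voxel coordinates of every target voxel centre, shape (3, N)."""
    idx = np.indices(shape, dtype=np.float64).reshape(3, -1)
    return (vox2vox[:3, :3] @ idx) + vox2vox[:3, 3:4]
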