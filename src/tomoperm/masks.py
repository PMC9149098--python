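"""Geometric binary masks, per-particle placement, and shell growth.

Masks are {0,1} voxel grids in the same cubic box as the subtomogram they
will be applied to.  A mask defined in the reference frame is placed on a
particle by applying the inverse of the particle's stored alignment,
``M_rot_trans = R^-1 M - T``, so the masked region tracks the object of
interest in each raw subtomogram.  Shell growth partitions the outside of
a mask into concentric pseudo-shells of equal Euclidean-distance width,
the geometric substrate of the graded permutation schedule.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .geometry import RigidTransform, resample_volume_data

__all__ = [
    "BinaryMask",
    "make_sphere_mask",
    "make_cylinder_mask",
    "transform_mask",
    "grow_mask_shells",
    "mask_from_volume",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class BinaryMask:
    """Boolean voxel mask with its pixel size and a shape descriptor."""

    data: np.ndarray
    pixel_size: float
    shape_spec: str = ""

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data).astype(bool)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"mask must be cubic, got {self.data.shape}")

    @property
    def box(self) -> int:
        return self.data.shape[0]

    def count(self) -> int:
        return int(self.data.sum())


def _grid(box: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    ax = np.arange(box, dtype=float)
    return np.meshgrid(ax, ax, ax, indexing="ij")


def make_sphere_mask(
    box: int,
    diameter: float,
    pixel_size: float,
    center=None,
) -> BinaryMask:
    """Spherical mask of physical ``diameter`` (Angstrom).

    E.g. a 350 A sphere at 2.62 A/voxel has radius 350/(2*2.62) = 66.79
    voxels.  The mask must fit inside the box.
    """
    radius = diameter / (2.0 * pixel_size)
    if 2.0 * radius > box:
        raise ValueError(
            f"sphere of {diameter} A ({2 * radius:.1f} voxels) exceeds box {box}"
        )
    c = np.full(3, box // 2, float) if center is None else np.asarray(center, float)
    x, y, z = _grid(box)
    d2 = (x - c[0]) ** 2 + (y - c[1]) ** 2 + (z - c[2]) ** 2
    return BinaryMask(
        d2 <= radius**2, pixel_size, f"sphere:d={diameter}A@{pixel_size}A/vox"
    )


def make_cylinder_mask(
    box: int,
    length: float,
    diameter: float,
    pixel_size: float = 1.0,
    axis: str = "z",
    center=None,
) -> BinaryMask:
    """Cylindrical mask with ``length`` and ``diameter`` in voxels.

    Voxels within ``diameter/2`` of the axis line and within
    ``+-length/2`` along it.
    """
    if length > box or diameter > box:
        raise ValueError(
            f"cylinder {length}x{diameter} voxels exceeds box {box}"
        )
    if axis not in _AXES:
        raise ValueError(f"axis must be one of x|y|z, got {axis!r}")
    c = np.full(3, box // 2, float) if center is None else np.asarray(center, float)
    coords = _grid(box)
    k = _AXES[axis]
    along = np.abs(coords[k] - c[k])
    radial2 = sum(
        (coords[j] - c[j]) ** 2 for j in range(3) if j != k
    )
    mask = (along <= length / 2.0) & (radial2 <= (diameter / 2.0) ** 2)
    return BinaryMask(mask, pixel_size, f"cylinder:{length}x{diameter}vox@{axis}")


def transform_mask(mask: BinaryMask, xf: RigidTransform) -> BinaryMask:
    """Place a reference-frame mask on a particle: ``R^-1 M - T``.

    The {0,1} field is resampled with trilinear interpolation under
    ``x -> R^-1 (x - c) - T + c`` about the box center and re-binarized at
    0.5.  Voxels mapped from outside the box become 0.
    """
    field = resample_volume_data(mask.data.astype(np.float32), xf.R, xf.T, order=1)
    return BinaryMask(field >= 0.5, mask.pixel_size, mask.shape_spec + "+xf")


def grow_mask_shells(
    mask: BinaryMask, step: float, n_shells: int
) -> tuple[list[BinaryMask], BinaryMask]:
    """Partition the outside of ``mask`` into distance shells + residual.

    ``shell_k`` holds voxels whose Euclidean distance to the mask lies in
    ``((k-1)*step, k*step]`` (an isotropic dilation difference); the
    residual is everything farther than ``n_shells*step``.  Mask, shells
    and residual tile the box exactly.
    """
    if step < 1:
        raise ValueError(f"step must be >= 1 voxel, got {step}")
    if n_shells < 0:
        raise ValueError(f"n_shells must be >= 0, got {n_shells}")
    outside = ~mask.data
    if not mask.data.any():
        # empty mask: no finite distances, everything is residual
        shells = [
            BinaryMask(np.zeros_like(outside), mask.pixel_size, f"shell{k + 1}")
            for k in range(n_shells)
        ]
        return shells, BinaryMask(outside, mask.pixel_size, "residual")
    dist = ndimage.distance_transform_edt(outside)
    shells = []
    for k in range(1, n_shells + 1):
        sel = outside & (dist > (k - 1) * step) & (dist <= k * step)
        shells.append(BinaryMask(sel, mask.pixel_size, f"shell{k}"))
    residual = outside & (dist > n_shells * step)
    return shells, BinaryMask(residual, mask.pixel_size, "residual")


def mask_from_volume(data: np.ndarray, pixel_size: float, threshold: float) -> BinaryMask:
    """Binarize a density map at a user threshold (data-derived masks)."""
    return BinaryMask(
        np.asarray(data) >= threshold, pixel_size, f"imported:thr={threshold}"
    )
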