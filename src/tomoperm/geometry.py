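"""Feature-guided alignment geometry.

Orientations are encoded as ZYZ intrinsic Euler angles ``(rot, tilt, psi)``
in degrees, the convention of the downstream refinement package::

    A(rot, tilt, psi) = Rz(psi) @ Ry(tilt) @ Rz(rot)

``A`` is the stored alignment matrix of a particle.  The defining contract
of feature-guided alignment is that applying the *inverse* of the stored
rotation to the picked feature vector ``v`` maps it onto +z.  Because
``A @ ez = Rz(psi) @ Ry(tilt) @ ez``, the feature direction is carried by
``(tilt, psi)`` alone and ``rot`` parameterizes the in-plane spin about
``v`` — which is why ``rot`` is drawn at random at assignment time and
left to the subsequent restrained rotational search.

Angle conventions: ``tilt`` in [0, 180]; ``rot``/``psi`` in [-180, 180).
All math kernels work in radians internally.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import ParticleTable

__all__ = [
    "RigidTransform",
    "AxisAngle",
    "axis_angle_from_vector",
    "rotation_from_axis_angle",
    "euler_from_matrix",
    "matrix_from_euler",
    "assign_feature_guided_angles",
    "resample_volume_data",
    "load_coordinate_pairs",
]

_GIMBAL_TILT_DEG = 1e-6


@dataclass
class RigidTransform:
    """Rotation matrix ``R`` plus translation ``T`` (voxels)."""

    R: np.ndarray
    T: np.ndarray

    def __post_init__(self) -> None:
        self.R = np.asarray(self.R, float)
        self.T = np.asarray(self.T, float).reshape(3)
        err = np.abs(self.R.T @ self.R - np.eye(3)).max()
        if err > 1e-8:
            raise ValueError(f"R is not orthonormal (|R^T R - I|_max = {err:.2e})")
        det = np.linalg.det(self.R)
        if abs(det - 1.0) > 1e-8:
            raise ValueError(f"R is not proper (det = {det:.10f})")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.R.T, -self.R @ self.T)


@dataclass
class AxisAngle:
    """Unit rotation axis ``r`` and angle ``theta`` in degrees, [0, 180]."""

    r: np.ndarray
    theta: float

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, float).reshape(3)
        n = np.linalg.norm(self.r)
        if abs(n - 1.0) > 1e-10:
            raise ValueError(f"axis must be unit length, |r| = {n}")


def axis_angle_from_vector(v, a=(0.0, 0.0, 1.0)) -> AxisAngle:
    """Axis/angle rotating reference direction ``a`` onto ``v``.

    r = (a x v) / |a x v|,  theta = acos(a.v / (|a||v|)).

    Degenerate cases: parallel vectors give theta = 0 with axis [1,0,0]
    (any axis is valid); antiparallel vectors give theta = 180 with axis
    fixed to [1,0,0] for determinism.
    """
    v = np.asarray(v, float).reshape(3)
    a = np.asarray(a, float).reshape(3)
    nv = np.linalg.norm(v)
    if nv == 0:
        raise ValueError("zero-length feature vector")
    a = a / np.linalg.norm(a)
    cross = np.cross(a, v)
    nc = np.linalg.norm(cross)
    cos_t = np.clip(a @ v / nv, -1.0, 1.0)
    theta = float(np.degrees(np.arccos(cos_t)))
    if nc < 1e-12 * nv:
        # parallel or antiparallel: any perpendicular axis works; pin x
        return AxisAngle(np.array([1.0, 0.0, 0.0]), 0.0 if cos_t > 0 else 180.0)
    return AxisAngle(cross / nc, theta)


def rotation_from_axis_angle(aa: AxisAngle) -> np.ndarray:
    """Rodrigues rotation matrix for axis ``r`` and angle ``theta``."""
    t = np.radians(aa.theta)
    kx, ky, kz = aa.r
    K = np.array([[0.0, -kz, ky], [kz, 0.0, -kx], [-ky, kx, 0.0]])
    return np.eye(3) + np.sin(t) * K + (1.0 - np.cos(t)) * (K @ K)


def matrix_from_euler(rot: float, tilt: float, psi: float) -> np.ndarray:
    """ZYZ intrinsic Euler angles (degrees) -> rotation matrix.

    A = Rz(psi) @ Ry(tilt) @ Rz(rot).
    """
    ca, sa = np.cos(np.radians(rot)), np.sin(np.radians(rot))
    cb, sb = np.cos(np.radians(tilt)), np.sin(np.radians(tilt))
    cg, sg = np.cos(np.radians(psi)), np.sin(np.radians(psi))
    Rrot = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1.0]])
    Rtilt = np.array([[cb, 0, sb], [0, 1.0, 0], [-sb, 0, cb]])
    Rpsi = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1.0]])
    return Rpsi @ Rtilt @ Rrot


def euler_from_matrix(R: np.ndarray) -> tuple[float, float, float]:
    """Rotation matrix -> ZYZ intrinsic Euler angles (rot, tilt, psi).

    ``tilt`` lands in [0, 180].  Gimbal tie-break: when ``tilt`` is within
    1e-6 deg of 0 (or 180), ``rot`` is set to 0 and the full in-plane
    angle is folded into ``psi``.
    """
    R = np.asarray(R, float)
    if np.abs(R.T @ R - np.eye(3)).max() > 1e-8 or np.linalg.det(R) < 0:
        raise ValueError("input is not a proper rotation matrix")
    cb = np.clip(R[2, 2], -1.0, 1.0)
    tilt = float(np.degrees(np.arccos(cb)))
    if tilt < _GIMBAL_TILT_DEG:
        # A ~ Rz(psi + rot): put everything into psi
        return 0.0, 0.0, float(np.degrees(np.arctan2(R[1, 0], R[0, 0])))
    if tilt > 180.0 - _GIMBAL_TILT_DEG:
        # A ~ Rz(psi - rot) @ Ry(180)
        return 0.0, 180.0, float(np.degrees(np.arctan2(-R[1, 0], -R[0, 0])))
    rot = float(np.degrees(np.arctan2(R[2, 1], -R[2, 0])))
    psi = float(np.degrees(np.arctan2(R[1, 2], R[0, 2])))
    return rot, tilt, psi


def assign_feature_guided_angles(
    table: ParticleTable,
    feature_coords: np.ndarray,
    seed: int,
) -> ParticleTable:
    """Initialize particle orientations from picked coordinate pairs.

    ``feature_coords`` is an (n, 6) array of per-particle coordinate pairs
    ``(object point, feature point)``; the feature vector is
    ``v = feature - object`` so the feature ends up on top (+z).  ``tilt``
    and ``psi`` come from the ZYZ decomposition of the Rodrigues rotation
    taking +z onto ``v``; ``rot`` is drawn uniformly on [-180, 180) from a
    single generator consumed in record order (byte-reproducible output);
    tilt/psi priors are set equal to tilt/psi for the downstream
    restrained rotational search.
    """
    feature_coords = np.asarray(feature_coords, float)
    if feature_coords.shape != (len(table), 6):
        raise ValueError(
            f"need one (object, feature) pair per record: expected "
            f"{(len(table), 6)}, got {feature_coords.shape}"
        )
    rng = np.random.default_rng(seed)
    out = table.copy()
    eulers = np.empty((len(table), 3))
    for i, row in enumerate(feature_coords):
        v = row[3:] - row[:3]
        if np.linalg.norm(v) == 0:
            raise ValueError(f"coincident coordinate pair for particle {i}")
        R = rotation_from_axis_angle(axis_angle_from_vector(v))
        _, tilt, psi = euler_from_matrix(R)
        rot = float(rng.uniform(-180.0, 180.0))
        eulers[i] = (rot, tilt, psi)
    out.set_eulers(eulers, priors=True)
    return out


def load_coordinate_pairs(path) -> np.ndarray:
    """Read a 6-column whitespace text table: x1 y1 z1 x2 y2 z2 per row."""
    pairs = np.atleast_2d(np.loadtxt(path, dtype=float))
    if pairs.shape[1] != 6:
        raise ValueError(f"expected 6 columns in {path}, got {pairs.shape[1]}")
    return pairs


def resample_volume_data(
    data: np.ndarray,
    R: np.ndarray,
    T=(0.0, 0.0, 0.0),
    order: int = 1,
    cval: float = 0.0,
) -> np.ndarray:
    """Resample a grid under the map ``x -> R^-1 (x - c) - T + c``.

    Equivalently ``out(y) = data(R @ (y - c + T) + c)`` with ``c`` the box
    center ``floor(N/2)``.  This is the shared kernel behind mask
    placement (R^-1 M - T) and applying a particle's stored alignment to
    its volume.  Trilinear interpolation by default; voxels sampled from
    outside the box read ``cval``.
    """
    from scipy import ndimage

    data = np.asarray(data)
    R = np.asarray(R, float)
    T = np.asarray(T, float).reshape(3)
    c = np.array([s // 2 for s in data.shape], float)
    offset = c + R @ (T - c)
    return ndimage.affine_transform(
        data, R, offset=offset, order=order, mode="constant", cval=cval,
        prefilter=(order > 1),
    )
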