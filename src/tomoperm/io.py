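"""MRC volume and RELION-dialect STAR table I/O.

This module fixes the geometric and metadata conventions that the rest of
the package relies on:

* Volumes are cubic ``N x N x N`` float grids addressed ``data[x, y, z]``
  with the box center at voxel index ``floor(N/2)`` on each axis.
* Pixel size is in Angstrom per voxel and travels with the volume.
* Particle metadata lives in a single ``data_``/``loop_`` STAR block with
  ``_rln``-prefixed labels.  Unknown columns are carried through verbatim
  so tables coming out of external refinement jobs survive a round trip.
* Angles are degrees at every interface; ``rot``/``psi`` are wrapped to
  [-180, 180) on write and ``tilt`` is expected in [0, 180].
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterator, Optional, Sequence

import gemmi
import numpy as np
import pandas as pd

__all__ = [
    "VoxelVolume",
    "ParticleRecord",
    "ParticleTable",
    "read_volume",
    "write_volume",
    "read_star",
    "write_star",
    "normalize_volume",
    "ANGLE_COLUMNS",
]

# STAR labels understood (everything else is passed through untouched)
COORD_COLUMNS = ("rlnCoordinateX", "rlnCoordinateY", "rlnCoordinateZ")
EULER_COLUMNS = ("rlnAngleRot", "rlnAngleTilt", "rlnAnglePsi")
PRIOR_COLUMNS = ("rlnAngleTiltPrior", "rlnAnglePsiPrior")
ORIGIN_COLUMNS = ("rlnOriginX", "rlnOriginY", "rlnOriginZ")
ANGLE_COLUMNS = EULER_COLUMNS + PRIOR_COLUMNS
# angles wrapped to [-180, 180) on write; tilt-like angles are left alone
WRAP_COLUMNS = ("rlnAngleRot", "rlnAnglePsi", "rlnAnglePsiPrior")

_FLOAT_COLUMNS = set(
    COORD_COLUMNS + EULER_COLUMNS + PRIOR_COLUMNS + ORIGIN_COLUMNS + ("rlnCcc",)
)
_INT_COLUMNS = {"rlnClassNumber"}


@dataclass
class VoxelVolume:
    """A cubic real-valued voxel grid with a physical pixel size.

    The universal carrier for subtomograms, masks, class averages and
    missing-wedge weight volumes.  ``data[x, y, z]``; box center at
    ``floor(N/2)`` per axis.
    """

    data: np.ndarray
    pixel_size: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data)
        if self.data.ndim != 3 or len(set(self.data.shape)) != 1:
            raise ValueError(f"volume must be cubic, got shape {self.data.shape}")
        if not self.pixel_size > 0:
            raise ValueError(f"pixel_size must be > 0, got {self.pixel_size}")

    @property
    def box(self) -> int:
        return self.data.shape[0]

    @property
    def center(self) -> np.ndarray:
        """Box center voxel index, floor(N/2) on each axis."""
        return np.full(3, self.box // 2, dtype=float)

    def copy(self) -> "VoxelVolume":
        return VoxelVolume(self.data.copy(), self.pixel_size)


@dataclass
class ParticleRecord:
    """One particle row: coordinates, angles, priors and file references."""

    coord: Optional[np.ndarray] = None
    euler: Optional[tuple[float, float, float]] = None  # (rot, tilt, psi) deg
    priors: Optional[tuple[float, float]] = None  # (tilt_prior, psi_prior) deg
    origin_offset: Optional[np.ndarray] = None
    image_path: Optional[str] = None
    ctf_image_path: Optional[str] = None
    class_id: Optional[int] = None
    ccc: Optional[float] = None


class ParticleTable:
    """Ordered particle records in the RELION STAR dialect.

    Thin wrapper over a :class:`pandas.DataFrame` whose columns are STAR
    labels without the leading underscore (``rlnCoordinateX`` ...).  Row
    order is preserved across read -> write round trips and unknown
    columns are never interpreted.
    """

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other: object) -> bool:
        return isinstance(other, ParticleTable) and self.df.equals(other.df)

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def copy(self) -> "ParticleTable":
        return ParticleTable(self.df.copy())

    def has(self, *cols: str) -> bool:
        return all(c in self.df.columns for c in cols)

    # -- typed accessors -------------------------------------------------
    def coords(self) -> np.ndarray:
        """(n, 3) voxel coordinates in the tomogram frame."""
        return self.df[list(COORD_COLUMNS)].to_numpy(float)

    def eulers(self) -> np.ndarray:
        """(n, 3) array of (rot, tilt, psi) in degrees."""
        if not self.has(*EULER_COLUMNS):
            raise KeyError("table has no Euler angle columns")
        return self.df[list(EULER_COLUMNS)].to_numpy(float)

    def origins(self) -> np.ndarray:
        """(n, 3) origin offsets in voxels; zeros when absent."""
        if self.has(*ORIGIN_COLUMNS):
            return self.df[list(ORIGIN_COLUMNS)].to_numpy(float)
        return np.zeros((len(self), 3))

    def set_eulers(self, eulers: np.ndarray, priors: bool = False) -> None:
        eulers = np.asarray(eulers, float)
        for j, col in enumerate(EULER_COLUMNS):
            self.df[col] = eulers[:, j]
        if priors:
            self.df["rlnAngleTiltPrior"] = eulers[:, 1]
            self.df["rlnAnglePsiPrior"] = eulers[:, 2]

    def record(self, i: int) -> ParticleRecord:
        row = self.df.iloc[i]

        def get(col):
            return row[col] if col in self.df.columns else None

        rec = ParticleRecord()
        if self.has(*COORD_COLUMNS):
            rec.coord = np.array([row[c] for c in COORD_COLUMNS], float)
        if self.has(*EULER_COLUMNS):
            rec.euler = tuple(float(row[c]) for c in EULER_COLUMNS)
        if self.has(*PRIOR_COLUMNS):
            rec.priors = tuple(float(row[c]) for c in PRIOR_COLUMNS)
        if self.has(*ORIGIN_COLUMNS):
            rec.origin_offset = np.array([row[c] for c in ORIGIN_COLUMNS], float)
        rec.image_path = get("rlnImageName")
        rec.ctf_image_path = get("rlnCtfImage")
        cls = get("rlnClassNumber")
        rec.class_id = None if cls is None else int(cls)
        ccc = get("rlnCcc")
        rec.ccc = None if ccc is None else float(ccc)
        return rec

    def records(self) -> Iterator[ParticleRecord]:
        for i in range(len(self)):
            yield self.record(i)

    @classmethod
    def from_records(cls, records: Sequence[ParticleRecord]) -> "ParticleTable":
        cols: dict[str, list] = {}

        def put(name, value):
            cols.setdefault(name, []).append(value)

        for rec in records:
            if rec.coord is not None:
                for c, v in zip(COORD_COLUMNS, rec.coord):
                    put(c, float(v))
            if rec.euler is not None:
                for c, v in zip(EULER_COLUMNS, rec.euler):
                    put(c, float(v))
            if rec.priors is not None:
                for c, v in zip(PRIOR_COLUMNS, rec.priors):
                    put(c, float(v))
            if rec.origin_offset is not None:
                for c, v in zip(ORIGIN_COLUMNS, rec.origin_offset):
                    put(c, float(v))
            if rec.image_path is not None:
                put("rlnImageName", rec.image_path)
            if rec.ctf_image_path is not None:
                put("rlnCtfImage", rec.ctf_image_path)
            if rec.class_id is not None:
                put("rlnClassNumber", int(rec.class_id))
            if rec.ccc is not None:
                put("rlnCcc", float(rec.ccc))
        lengths = {len(v) for v in cols.values()}
        if len(lengths) > 1:
            raise ValueError("records expose inconsistent column sets")
        return cls(pd.DataFrame(cols))


# ---------------------------------------------------------------------------
# MRC volumes (via gemmi's CCP4/MRC2014 reader; mode 2 float32)
# ---------------------------------------------------------------------------

def read_volume(path: str | os.PathLike) -> VoxelVolume:
    """Read an MRC2014 volume into a :class:`VoxelVolume`.

    Rejects non-cubic boxes and non-finite voxels (error names the axis of
    the first offender and the total count).
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    m = gemmi.read_ccp4_map(path)
    data = np.array(m.grid, copy=True).astype(np.float32)
    if data.ndim != 3 or len(set(data.shape)) != 1:
        raise ValueError(f"non-cubic box {data.shape} in {path}")
    bad = ~np.isfinite(data)
    if bad.any():
        x, y, z = (int(i[0]) for i in np.nonzero(bad))
        raise ValueError(
            f"{int(bad.sum())} non-finite voxel(s) in {path}; "
            f"first at x={x}, y={y}, z={z}"
        )
    spacing = m.grid.spacing
    if max(spacing) - min(spacing) > 1e-4:
        raise ValueError(f"anisotropic voxel spacing {spacing} in {path}")
    return VoxelVolume(data, float(spacing[0]))


def write_volume(vol: VoxelVolume, path: str | os.PathLike) -> None:
    """Write ``vol`` as an MRC2014 file (mode 2, float32, cubic cell)."""
    path = os.fspath(path)
    n = vol.box
    grid = gemmi.FloatGrid(n, n, n)
    np.array(grid, copy=False)[:] = vol.data.astype(np.float32)
    a = n * vol.pixel_size
    grid.set_unit_cell(gemmi.UnitCell(a, a, a, 90.0, 90.0, 90.0))
    m = gemmi.Ccp4Map()
    m.grid = grid
    m.update_ccp4_header()
    m.write_ccp4_map(path)


# ---------------------------------------------------------------------------
# STAR tables (gemmi's STAR/CIF parser underneath)
# ---------------------------------------------------------------------------

def _coerce(tag: str, values: list[str]):
    name = tag.lstrip("_")
    if name in _FLOAT_COLUMNS:
        return name, [float(v) for v in values]
    if name in _INT_COLUMNS:
        return name, [int(v) for v in values]
    # unknown columns stay as text, verbatim
    return name, values


def read_star(path: str | os.PathLike) -> ParticleTable:
    """Read the particle loop of a single-block RELION STAR file."""
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    doc = gemmi.cif.read_file(path)
    loop = None
    for block in doc:
        for item in block:
            if item.loop is not None and any(
                t.startswith("_rln") for t in item.loop.tags
            ):
                loop = item.loop
                break
        if loop is not None:
            break
    if loop is None:
        raise ValueError(f"no _rln particle loop found in {path}")
    cols = {}
    width = loop.width()
    flat = list(loop.values)
    for j, tag in enumerate(loop.tags):
        raw = [gemmi.cif.as_string(v) for v in flat[j::width]]
        name, vals = _coerce(tag, raw)
        cols[name] = vals
    return ParticleTable(pd.DataFrame(cols))


def _format_value(name: str, value) -> str:
    if name in _INT_COLUMNS:
        return str(int(value))
    if name in _FLOAT_COLUMNS:
        v = float(value)
        if name in WRAP_COLUMNS:
            v = ((v + 180.0) % 360.0) - 180.0
        return repr(v)
    return gemmi.cif.quote(str(value))


def write_star(table: ParticleTable, path: str | os.PathLike) -> None:
    """Write ``table`` as a ``data_particles`` block with one loop.

    Floats are written with full precision so ``read_star(write_star(t))``
    reproduces the records exactly; ``rot``/``psi`` angles are wrapped to
    [-180, 180) first.
    """
    path = os.fspath(path)
    doc = gemmi.cif.Document()
    block = doc.add_new_block("particles")
    tags = ["_" + c for c in table.columns]
    if not tags:
        raise ValueError("cannot write a table with no columns")
    loop = block.init_loop("", tags)
    for _, row in table.df.iterrows():
        loop.add_row([_format_value(c, row[c]) for c in table.columns])
    doc.write_file(path)


# ---------------------------------------------------------------------------

def normalize_volume(vol: VoxelVolume, invert: bool = False) -> VoxelVolume:
    """Z-score a volume to mean 0 / SD 1.

    ``invert`` flips the contrast (multiplies by -1) after normalization;
    whether extraction inverts contrast before or after normalization is
    pipeline-dependent, so the flag is explicit rather than defaulted.
    """
    data = np.asarray(vol.data, np.float64)
    sd = data.std()
    if sd == 0:
        raise ValueError("zero variance: cannot normalize a constant volume")
    out = (data - data.mean()) / sd
    if invert:
        out = -out
    return VoxelVolume(out, vol.pixel_size)
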