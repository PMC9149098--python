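"""Missing-wedge weights, wedge-aware cross-correlation, Wiener filter.

A single-axis tilt series of range [tilt_min, tilt_max] samples, in the
plane perpendicular to the tilt axis, only the Fourier directions whose
angle from the untilted in-plane direction lies in that range; the rest
is the missing wedge.  The binary wedge volume built here is stored
centered (DC at voxel floor(N/2)) so it can be written as MRC and
referenced from a STAR table as the per-particle CTF image.

Cross-correlation against a class average imposes the wedge on the
average (the subtomogram already carries the experimental wedge) and
computes a Pearson coefficient over a region mask — the constrained
correlation used to prune badly aligned or empty subtomograms.

The Wiener filter is a visualization deconvolution
``W(f) = C(f) / (C(f)^2 + 1/SSNR(f))`` with ``C`` the standard
phase-contrast transfer function and ``SSNR`` an exponentially decaying
spectral signal-to-noise model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .geometry import RigidTransform, matrix_from_euler, resample_volume_data
from .io import ParticleTable, VoxelVolume, read_volume
from .masks import BinaryMask

__all__ = [
    "WedgeSpec",
    "CtfParams",
    "make_wedge_volume",
    "apply_wedge",
    "masked_wedge_ccc",
    "prune_by_ccc",
    "wiener_deconvolve",
]


@dataclass
class WedgeSpec:
    """Tilt axis and angular range (degrees) of a single-axis scheme."""

    tilt_axis: str = "y"
    tilt_min: float = -60.0
    tilt_max: float = 60.0

    def __post_init__(self) -> None:
        if self.tilt_axis not in ("x", "y"):
            raise ValueError(f"tilt_axis must be x or y, got {self.tilt_axis!r}")
        if not (-90.0 <= self.tilt_min < self.tilt_max <= 90.0):
            raise ValueError(
                f"need -90 <= tilt_min < tilt_max <= 90, got "
                f"[{self.tilt_min}, {self.tilt_max}]"
            )


@dataclass
class CtfParams:
    """Microscope parameters for the Wiener visualization filter.

    ``defocus`` is in micrometers and interpreted as underfocus by
    magnitude (so the conventional "-3.0 um" means 3.0 um underfocus);
    ``snr_falloff`` scales the exponential decay of the assumed spectral
    SNR, and ``snr0`` is the SNR at zero frequency.
    """

    defocus: float = -3.0
    voltage: float = 300.0  # kV
    cs: float = 2.7  # mm
    amplitude_contrast: float = 0.07
    pixel_size: float = 2.62  # A
    snr_falloff: float = 1.2
    snr0: float = 10.0

    def __post_init__(self) -> None:
        if self.voltage <= 0 or self.pixel_size <= 0:
            raise ValueError("voltage and pixel_size must be > 0")
        if not 0.0 <= self.amplitude_contrast <= 1.0:
            raise ValueError("amplitude_contrast must be in [0, 1]")


def _centered_freq_angles(
    box: int, tilt_axis: str, rotation: np.ndarray | None = None
) -> np.ndarray:
    """Per-voxel direction angle (deg, in (-90, 90]) in the tilted plane.

    ``rotation`` evaluates the angle on rotated frequency coordinates
    (``g = R f``), giving an exactly inversion-symmetric rotated wedge.
    """
    f = np.arange(box, dtype=float) - box // 2
    fx, fy, fz = np.meshgrid(f, f, f, indexing="ij")
    if rotation is not None:
        R = np.asarray(rotation, float)
        fx, fy, fz = (
            R[0, 0] * fx + R[0, 1] * fy + R[0, 2] * fz,
            R[1, 0] * fx + R[1, 1] * fy + R[1, 2] * fz,
            R[2, 0] * fx + R[2, 1] * fy + R[2, 2] * fz,
        )
    in_plane = fx if tilt_axis == "y" else fy
    ang = np.degrees(np.arctan2(fz, in_plane))
    # directions are lines through the origin: fold to (-90, 90]
    ang = ((ang + 90.0) % 180.0) - 90.0
    ang[(in_plane == 0) & (fz != 0)] = 90.0
    return ang


def make_wedge_volume(
    box: int,
    spec: WedgeSpec,
    pixel_size: float = 1.0,
    rotation: np.ndarray | None = None,
) -> VoxelVolume:
    """Binary single-axis missing-wedge weights, DC at the box center.

    Value 1 where the direction of (in-plane, z) frequency lies within
    [tilt_min, tilt_max]; for a symmetric range +-a this is
    ``|f_z| <= tan(a) * |f_perp|``.  The volume is symmetric under point
    inversion about the center, as required for a real-image filter.
    ``rotation`` produces the wedge of a particle whose alignment maps it
    by ``R`` (the condition is evaluated on rotated frequencies).
    """
    ang = _centered_freq_angles(box, spec.tilt_axis, rotation)
    wedge = (ang >= spec.tilt_min) & (ang <= spec.tilt_max)
    if spec.tilt_max >= 90.0:
        wedge |= ang == -90.0  # +-90 name the same line of directions
    # enforce exact Hermitian (point-inversion) symmetry, including the
    # Nyquist planes of an even box where -k wraps onto +k
    partner = np.roll(wedge[::-1, ::-1, ::-1], 1, axis=(0, 1, 2))
    wedge &= partner
    c = box // 2
    wedge[c, c, c] = True  # DC always passes
    return VoxelVolume(wedge.astype(np.float32), pixel_size)


def apply_wedge(vol: VoxelVolume, wedge: VoxelVolume) -> VoxelVolume:
    """Multiply the volume's Fourier transform by centered weights."""
    if vol.data.shape != wedge.data.shape:
        raise ValueError(
            f"volume {vol.data.shape} and wedge {wedge.data.shape} differ"
        )
    w = np.fft.ifftshift(wedge.data)
    out = np.fft.ifftn(np.fft.fftn(vol.data) * w)
    imag = np.abs(out.imag).max()
    scale = max(np.abs(vol.data).max(), 1.0)
    if imag > 1e-6 * scale:
        raise ValueError(
            f"non-Hermitian wedge: imaginary residue {imag:.3e}"
        )
    return VoxelVolume(out.real, vol.pixel_size)


def masked_wedge_ccc(
    avg: VoxelVolume,
    subtomo: VoxelVolume,
    wedge: VoxelVolume | None,
    region: BinaryMask,
    wedge_both: bool = False,
) -> float:
    """Pearson correlation over a region, wedge imposed on the average.

    The class average is filtered by the subtomogram's missing wedge so
    both sides are compared on the experimentally sampled Fourier
    region; means are taken over the region voxels.
    """
    if not region.data.any():
        raise ValueError("empty correlation region")
    a = avg
    b = subtomo
    if wedge is not None:
        a = apply_wedge(a, wedge)
        if wedge_both:
            b = apply_wedge(b, wedge)
    x = a.data[region.data].astype(np.float64)
    y = b.data[region.data].astype(np.float64)
    x -= x.mean()
    y -= y.mean()
    nx, ny = np.linalg.norm(x), np.linalg.norm(y)
    if nx == 0 or ny == 0:
        raise ValueError("zero variance inside the correlation region")
    return float(np.clip(x @ y / (nx * ny), -1.0, 1.0))


def align_particle_volume(
    vol: VoxelVolume, euler, origin=(0.0, 0.0, 0.0), order: int = 1
) -> VoxelVolume:
    """Resample a particle into the reference frame via its alignment.

    The stored Euler matrix ``A`` maps reference directions into the
    particle frame (feature axis ``v = A ez``), so aligning the volume
    applies ``A^-1`` to its content after undoing the origin offset:
    ``aligned(y) = particle(A (y - c) - origin + c)``.  The inverse of
    the same map places a reference-frame mask on the particle
    (``transform_mask`` with ``(A^T, origin)``), so mask and aligned
    volume always refer to the same physical region.
    """
    R = matrix_from_euler(*euler)
    data = resample_volume_data(
        vol.data, R, -R.T @ np.asarray(origin, float), order=order
    )
    return VoxelVolume(data, vol.pixel_size)


def prune_by_ccc(
    table: ParticleTable,
    avg: VoxelVolume,
    wedge: VoxelVolume | None,
    region: BinaryMask,
    threshold: float,
    volumes: list[VoxelVolume] | None = None,
) -> tuple[ParticleTable, ParticleTable]:
    """Annotate every particle with its CCC and keep ``ccc >= threshold``.

    Each particle volume is brought into the average's frame by its
    stored alignment before correlation, so ``region`` is defined once in
    the reference frame.  Returns ``(annotated, kept)``; pass ``volumes``
    to score in-memory data instead of reading ``rlnImageName`` paths.
    """
    eulers = table.eulers()
    origins = table.origins()
    cccs = np.empty(len(table))
    for i, rec in enumerate(table.records()):
        if volumes is not None:
            vol = volumes[i]
        else:
            if rec.image_path is None:
                raise ValueError(f"record {i} has no rlnImageName")
            vol = read_volume(rec.image_path)
        aligned = align_particle_volume(vol, eulers[i], origins[i])
        cccs[i] = masked_wedge_ccc(avg, aligned, wedge, region)
    annotated = table.copy()
    annotated.df["rlnCcc"] = cccs
    kept = ParticleTable(annotated.df[cccs >= threshold].reset_index(drop=True))
    return annotated, kept


def _electron_wavelength(voltage_kv: float) -> float:
    """Relativistic electron wavelength in Angstrom."""
    v = voltage_kv * 1e3
    return 12.2639 / np.sqrt(v + 0.97845e-6 * v**2)


def ctf_1d(freq: np.ndarray, ctf: CtfParams) -> np.ndarray:
    """Phase-contrast transfer function on spatial frequencies (1/A).

    C(f) = sqrt(1 - A^2) sin(chi) + A cos(chi) with
    chi = pi lambda z f^2 - (pi/2) Cs lambda^3 f^4, z = underfocus (A).
    Positive sign convention: extracted subtomograms here have inverted
    (protein-bright) contrast, so no extra global minus.
    """
    lam = _electron_wavelength(ctf.voltage)
    z = abs(ctf.defocus) * 1e4  # um -> A, underfocus positive
    cs = ctf.cs * 1e7  # mm -> A
    chi = np.pi * lam * z * freq**2 - 0.5 * np.pi * cs * lam**3 * freq**4
    a = ctf.amplitude_contrast
    return np.sqrt(1.0 - a**2) * np.sin(chi) + a * np.cos(chi)


def wiener_deconvolve(vol: VoxelVolume, ctf: CtfParams) -> VoxelVolume:
    """Apply the Wiener filter ``C / (C^2 + 1/SSNR)`` in Fourier space.

    ``SSNR(f) = snr0 * exp(-5 * snr_falloff * f / f_Nyquist)``; at the
    default falloff the top third of the spectrum is strongly damped,
    which is the intended behavior for visualizing noisy subtomograms.
    Deterministic, linear in the input.
    """
    n = vol.box
    f1 = np.fft.fftfreq(n, d=ctf.pixel_size)
    fx, fy, fz = np.meshgrid(f1, f1, f1, indexing="ij")
    freq = np.sqrt(fx**2 + fy**2 + fz**2)
    c = ctf_1d(freq, ctf)
    f_nyq = 0.5 / ctf.pixel_size
    with np.errstate(over="ignore"):
        ssnr = ctf.snr0 * np.exp(-5.0 * ctf.snr_falloff * freq / f_nyq)
    inv_ssnr = np.where(np.isfinite(ssnr) & (ssnr > 0), 1.0 / ssnr, np.inf)
    inv_ssnr = np.where(np.isinf(ssnr), 0.0, inv_ssnr)
    filt = c / (c**2 + inv_ssnr)
    out = np.fft.ifftn(np.fft.fftn(vol.data) * filt).real
    return VoxelVolume(out, vol.pixel_size)
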