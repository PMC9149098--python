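"""QC analytics for membrane-interface class averages.

Covers the standard diagnostics for vesicle-vesicle interface maps:
midsection-slice averaging, center-column intensity traces through the
bilayers, double-peak metrics (half-height width as a bilayer-thickness
proxy and peak magnitude above the local minimum), and the flip-fraction
scatter that exposes pseudo-symmetric misalignment by projecting each
particle's feature direction back through its stored alignment.
Traces are in SD units whenever the map is normalized.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .geometry import matrix_from_euler
from .io import ParticleTable, VoxelVolume

__all__ = [
    "BilayerMetrics",
    "AlignmentScatter",
    "midsection_average",
    "center_trace",
    "bilayer_peak_metrics",
    "alignment_flip_fraction",
]

_AXES = {"x": 0, "y": 1, "z": 2}


@dataclass
class BilayerMetrics:
    """Double-peak descriptors of a bilayer intensity trace."""

    peak_positions: tuple[int, int]
    half_height_widths: tuple[float, float]  # per peak, voxels
    peak_magnitude: float
    baseline: float

    @property
    def half_height_width(self) -> float:
        """Mean width at half height over the two peaks (voxels)."""
        return 0.5 * (self.half_height_widths[0] + self.half_height_widths[1])

    @property
    def peak_separation(self) -> int:
        return abs(self.peak_positions[1] - self.peak_positions[0])


@dataclass
class AlignmentScatter:
    """Per-particle feature directions after undoing the alignment."""

    projected_points: np.ndarray  # (n, 3); z-sign classifies top/bottom
    top_fraction: float
    bottom_fraction: float
    n_ties: int


def midsection_average(
    vol: VoxelVolume, thickness: int = 21, axis: str = "y"
) -> np.ndarray:
    """Mean of the central ``thickness`` planes perpendicular to ``axis``.

    Returns a 2D image whose rows run along the last remaining axis (z
    unless ``axis='z'``), i.e. rows are the vertical direction for the
    usual bilayer-normal-along-z geometry.
    """
    if thickness % 2 == 0:
        raise ValueError(f"thickness must be odd (unambiguous center), got {thickness}")
    n = vol.box
    if thickness > n:
        raise ValueError(f"thickness {thickness} exceeds box {n}")
    if axis not in _AXES:
        raise ValueError(f"axis must be x|y|z, got {axis!r}")
    k = _AXES[axis]
    c = n // 2
    h = thickness // 2
    sl = [slice(None)] * 3
    sl[k] = slice(c - h, c + h + 1)
    img = vol.data[tuple(sl)].mean(axis=k)
    # img axes are the two remaining of (x, y, z) in order; transpose so
    # rows follow the later axis (vertical)
    return img.T


def center_trace(img: np.ndarray, width: int = 21) -> np.ndarray:
    """Per-row mean over the central ``width`` columns of a 2D image."""
    img = np.asarray(img)
    if img.ndim != 2:
        raise ValueError(f"expected a 2D image, got shape {img.shape}")
    if width % 2 == 0:
        raise ValueError(f"width must be odd, got {width}")
    if width > img.shape[1]:
        raise ValueError(f"width {width} exceeds image width {img.shape[1]}")
    c = img.shape[1] // 2
    h = width // 2
    return img[:, c - h : c + h + 1].mean(axis=1)


def _half_height_width(trace, peak, level) -> float:
    """Interpolated width of the peak at ``level`` (linear crossings)."""
    left = None
    for i in range(peak, 0, -1):
        if trace[i - 1] < level <= trace[i]:
            frac = (trace[i] - level) / (trace[i] - trace[i - 1])
            left = i - frac
            break
    right = None
    for i in range(peak, len(trace) - 1):
        if trace[i + 1] < level <= trace[i]:
            frac = (trace[i] - level) / (trace[i] - trace[i + 1])
            right = i + frac
            break
    if left is None or right is None:
        return float("nan")
    return float(right - left)


def bilayer_peak_metrics(
    trace: np.ndarray,
    search_window: tuple[int, int],
    smooth: bool = False,
) -> Optional[BilayerMetrics]:
    """Locate a bilayer double peak in a 1D trace and measure it.

    Finds the two largest local maxima inside ``search_window`` with a
    local minimum between them.  Peak magnitude is the mean of the two
    maxima minus the intervening minimum.  Half-height widths are
    measured per peak at ``baseline + (peak - baseline)/2`` where the
    baseline is the trace mean outside the window.  Returns ``None``
    (no double peak) for flat/monotone traces instead of raising.
    """
    from scipy.signal import find_peaks

    trace = np.asarray(trace, float)
    lo, hi = search_window
    if not (0 <= lo < hi <= len(trace)):
        raise ValueError(f"window {search_window} outside trace of length {len(trace)}")
    if smooth:
        kern = np.ones(3) / 3.0
        trace = np.convolve(trace, kern, mode="same")
    win = trace[lo:hi]
    peaks, _ = find_peaks(win)
    if len(peaks) < 2:
        return None
    top2 = peaks[np.argsort(win[peaks])[-2:]]
    p1, p2 = sorted(int(p) + lo for p in top2)
    valley = p1 + int(np.argmin(trace[p1 : p2 + 1]))
    if valley in (p1, p2):
        return None
    outside = np.concatenate([trace[:lo], trace[hi:]])
    baseline = float(outside.mean()) if outside.size else 0.0
    widths = tuple(
        _half_height_width(trace, p, baseline + 0.5 * (trace[p] - baseline))
        for p in (p1, p2)
    )
    magnitude = float(0.5 * (trace[p1] + trace[p2]) - trace[valley])
    return BilayerMetrics((p1, p2), widths, magnitude, baseline)


def alignment_flip_fraction(
    table: ParticleTable, feature_coords: np.ndarray
) -> AlignmentScatter:
    """Classify particles as correctly oriented (top) vs flipped (bottom).

    For each particle the unit feature vector (feature point minus object
    point) is rotated by the inverse of the stored alignment; a positive
    z-component means the feature maps onto the +z side as intended.
    ``z == 0`` ties count as top (and are reported).  Feature-guided
    initialization yields top_fraction == 1.0 by construction.
    """
    feature_coords = np.asarray(feature_coords, float)
    if feature_coords.shape != (len(table), 6):
        raise ValueError(
            f"expected {(len(table), 6)} coordinate pairs, got {feature_coords.shape}"
        )
    eulers = table.eulers()
    points = np.empty((len(table), 3))
    for i in range(len(table)):
        v = feature_coords[i, 3:] - feature_coords[i, :3]
        nv = np.linalg.norm(v)
        if nv == 0:
            raise ValueError(f"zero-length feature vector for particle {i}")
        R = matrix_from_euler(*eulers[i])
        points[i] = R.T @ (v / nv)
    top = points[:, 2] >= 0.0
    ties = int((points[:, 2] == 0.0).sum())
    frac = float(top.mean()) if len(table) else 0.0
    return AlignmentScatter(points, frac, 1.0 - frac, ties)
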