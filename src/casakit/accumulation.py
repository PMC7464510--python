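"""Sperm-accumulation heat maps with boundary correction and ROI time series.

Given detected cell positions, every pixel receives the number of cell
centroids within a user-defined search radius R (Euclidean distance on
pixel centers). At the image borders the R-circle extends out of bounds, so
raw counts are divided by the in-bounds area fraction of the circle to
restore an unbiased density estimate. Corrected values are linearly rescaled
to 0–255 and rendered through a fixed 256-entry Jet look-up table
(blue → cyan → green → yellow → red: cold = sparse, warm = dense).

Video processing supports two accelerations: a sampling factor f (full maps
computed every f frames, intermediates linearly interpolated per pixel) and
a pixel window W (counts evaluated only at the center of each W×W block,
the block painted with that value).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import fftconvolve

from .imaging import HighDensityWarning, ParticleSet

__all__ = [
    "AccumulationParams",
    "AccumulationMap",
    "RoiSeries",
    "local_counts",
    "boundary_fraction_map",
    "boundary_fraction",
    "correct_counts",
    "scale_to_display",
    "jet_lut",
    "apply_jet_lut",
    "accumulation_map",
    "heatmap_video",
    "roi_timeseries",
    "HighDensityWarning",
]


@dataclass(frozen=True)
class AccumulationParams:
    """Heat-map settings: search radius R (px), sampling factor f, window W."""

    radius_R: float
    sampling_factor_f: int = 1
    window_W: int = 1

    def __post_init__(self) -> None:
        if self.radius_R <= 0:
            raise ValueError("radius_R must be > 0")
        if self.sampling_factor_f < 1:
            raise ValueError("sampling_factor_f must be ≥ 1")
        if self.window_W < 1 or self.window_W % 2 == 0:
            raise ValueError("window_W must be an odd integer ≥ 1")


@dataclass
class AccumulationMap:
    """Per-pixel counts: raw, boundary-corrected, and 0–255 display-scaled."""

    raw_counts: np.ndarray
    corrected: np.ndarray
    scaled: np.ndarray
    frame_index: int = 0


def _disk_offsets(R: float) -> np.ndarray:
    """Integer offsets (dy, dx) with dy² + dx² ≤ R²."""
    k = int(np.floor(R))
    dy, dx = np.mgrid[-k : k + 1, -k : k + 1]
    sel = dy * dy + dx * dx <= R * R
    return np.stack([dy[sel], dx[sel]], axis=1)


def local_counts(particles: ParticleSet, R: float) -> np.ndarray:
    """Count centroids within Euclidean distance ≤ R of every pixel center.

    Entry ``(y, x)`` is the number of particle centroids at distance ≤ R
    from pixel center ``(x, y)``. Implemented by stamping each particle's
    disk of influence; identical to the per-pixel double loop.
    """
    if R <= 0:
        raise ValueError("R must be > 0")
    h, w = particles.height, particles.width
    counts = np.zeros((h, w), dtype=np.int64)
    r2 = R * R
    for cx, cy in particles.centroids:
        x0 = max(int(np.ceil(cx - R)), 0)
        x1 = min(int(np.floor(cx + R)), w - 1)
        y0 = max(int(np.ceil(cy - R)), 0)
        y1 = min(int(np.floor(cy + R)), h - 1)
        if x1 < x0 or y1 < y0:
            continue
        ys = np.arange(y0, y1 + 1)[:, None] - cy
        xs = np.arange(x0, x1 + 1)[None, :] - cx
        counts[y0 : y1 + 1, x0 : x1 + 1] += (ys * ys + xs * xs <= r2)
    return counts


def boundary_fraction_map(shape: tuple[int, int], R: float) -> np.ndarray:
    """In-bounds area fraction of the R-circle centered at every pixel.

    The circle is rasterized on the native pixel grid (integer offsets with
    ``dy² + dx² ≤ R²``) and the in-bounds members counted, so interior
    pixels get exactly 1.0. Computed for the whole raster by convolving an
    all-ones image with the disk kernel (FFT, rounded back to exact integer
    counts).
    """
    h, w = shape
    k = int(np.floor(R))
    dy, dx = np.mgrid[-k : k + 1, -k : k + 1]
    kernel = (dy * dy + dx * dx <= R * R).astype(float)
    total = kernel.sum()
    inside = fftconvolve(np.ones((h, w)), kernel, mode="same")
    inside = np.rint(inside)
    return inside / total


def boundary_fraction(pixel: tuple[int, int], shape: tuple[int, int], R: float) -> float:
    """Fraction in (0, 1] of the R-circle at ``pixel`` = (x, y) lying in-bounds."""
    x, y = pixel
    h, w = shape
    if not (0 <= x < w and 0 <= y < h):
        raise ValueError("pixel must lie inside the image")
    off = _disk_offsets(R)
    yy = y + off[:, 0]
    xx = x + off[:, 1]
    inside = ((yy >= 0) & (yy < h) & (xx >= 0) & (xx < w)).sum()
    return inside / len(off)


def correct_counts(raw: np.ndarray, fractions: np.ndarray) -> np.ndarray:
    """Edge correction: corrected = raw / in-bounds fraction, elementwise."""
    raw = np.asarray(raw, dtype=float)
    fractions = np.asarray(fractions, dtype=float)
    if raw.shape != fractions.shape:
        raise ValueError("raw and fractions must have the same shape")
    assert (fractions > 0).all(), "boundary fractions must be positive"
    return raw / fractions


def scale_to_display(corrected: np.ndarray) -> np.ndarray:
    """Linear rescale of the map to integers in [0, 255].

    ``scaled(x) = (x − x_min)·255/(x_max − x_min)``, rounded half-up. A
    constant map (x_max = x_min, scaling undefined) maps to all zeros.
    """
    corrected = np.asarray(corrected, dtype=float)
    if corrected.size == 0:
        raise ValueError("corrected map must have at least one element")
    lo, hi = corrected.min(), corrected.max()
    if hi == lo:
        return np.zeros(corrected.shape, dtype=np.uint8)
    scaled = (corrected - lo) * 255.0 / (hi - lo)
    return np.floor(scaled + 0.5).astype(np.uint8)  # round half-up


def jet_lut() -> np.ndarray:
    """The 256×3 Jet look-up table (uint8 RGB rows).

    Built from the classic piecewise-linear channel ramps
    (dark blue → blue → cyan → green → yellow → red → dark red) so rendering
    is bit-exact across platforms. Index 0 is the coldest entry, 255 the
    warmest.
    """
    x = np.arange(256) / 255.0
    r = np.clip(np.minimum(4.0 * x - 1.5, -4.0 * x + 4.5), 0.0, 1.0)
    g = np.clip(np.minimum(4.0 * x - 0.5, -4.0 * x + 3.5), 0.0, 1.0)
    b = np.clip(np.minimum(4.0 * x + 0.5, -4.0 * x + 2.5), 0.0, 1.0)
    lut = np.stack([r, g, b], axis=1)
    return np.rint(lut * 255.0).astype(np.uint8)


_JET = jet_lut()


def apply_jet_lut(scaled: np.ndarray) -> np.ndarray:
    """Map a [0, 255] index image through the Jet table → (H, W, 3) RGB."""
    scaled = np.asarray(scaled)
    assert scaled.min() >= 0 and scaled.max() <= 255, "indices must be in [0, 255]"
    return _JET[scaled.astype(np.intp)]


def _window_centers(n: int, W: int) -> np.ndarray:
    """Center indices of consecutive W-wide blocks covering [0, n)."""
    starts = np.arange(0, n, W)
    return np.minimum(starts + W // 2, n - 1)


def accumulation_map(
    particles: ParticleSet,
    params: AccumulationParams,
    fractions: Optional[np.ndarray] = None,
) -> AccumulationMap:
    """Full heat-map computation for one frame.

    With ``window_W > 1`` counts are evaluated only at the center pixel of
    each W×W block and the block is painted with that center's corrected
    value (the raw map is still reported per computed pixel, replicated the
    same way).
    """
    shape = (particles.height, particles.width)
    if fractions is None:
        fractions = boundary_fraction_map(shape, params.radius_R)
    raw = local_counts(particles, params.radius_R)
    W = params.window_W
    if W > 1:
        cy = _window_centers(shape[0], W)
        cx = _window_centers(shape[1], W)
        block_raw = raw[np.ix_(cy, cx)]
        block_corr = block_raw / fractions[np.ix_(cy, cx)]
        raw = np.repeat(np.repeat(block_raw, W, axis=0), W, axis=1)[: shape[0], : shape[1]]
        corrected = np.repeat(np.repeat(block_corr, W, axis=0), W, axis=1)[
            : shape[0], : shape[1]
        ]
    else:
        corrected = correct_counts(raw, fractions)
    return AccumulationMap(
        raw_counts=raw,
        corrected=corrected,
        scaled=scale_to_display(corrected),
        frame_index=particles.frame_index,
    )


def heatmap_video(
    frames: Sequence[ParticleSet],
    params: AccumulationParams,
    global_scale: bool = False,
) -> list[AccumulationMap]:
    """Heat maps for a frame sequence with sampling-factor acceleration.

    Full maps are computed at frames 0, f, 2f, … (and at the final frame);
    intermediate frames are per-pixel linear interpolations of the two
    flanking computed maps. ``global_scale=True`` rescales every frame with
    the video-wide min/max instead of per-frame extremes, for comparable
    colors across time.
    """
    if not frames:
        return []
    f = params.sampling_factor_f
    n = len(frames)
    shape = (frames[0].height, frames[0].width)
    fractions = boundary_fraction_map(shape, params.radius_R)

    computed_idx = sorted(set(range(0, n, f)) | {n - 1})
    computed = {
        i: accumulation_map(frames[i], params, fractions=fractions) for i in computed_idx
    }

    corrected_all: list[np.ndarray] = []
    raw_all: list[np.ndarray] = []
    for i in range(n):
        if i in computed:
            corrected_all.append(computed[i].corrected)
            raw_all.append(computed[i].raw_counts)
        else:
            lo = max(j for j in computed_idx if j < i)
            hi = min(j for j in computed_idx if j > i)
            t = (i - lo) / (hi - lo)
            corrected_all.append(
                (1.0 - t) * computed[lo].corrected + t * computed[hi].corrected
            )
            raw_all.append(computed[lo].raw_counts)  # raw is not interpolated

    if global_scale:
        stack = np.stack(corrected_all)
        lo, hi = stack.min(), stack.max()
        if hi == lo:
            scaled_all = [np.zeros(shape, dtype=np.uint8) for _ in corrected_all]
        else:
            scaled_all = [
                np.floor((c - lo) * 255.0 / (hi - lo) + 0.5).astype(np.uint8)
                for c in corrected_all
            ]
    else:
        scaled_all = [scale_to_display(c) for c in corrected_all]

    return [
        AccumulationMap(raw_counts=r, corrected=c, scaled=s, frame_index=i)
        for i, (r, c, s) in enumerate(zip(raw_all, corrected_all, scaled_all))
    ]


@dataclass
class RoiSeries:
    """Per-frame counts inside concentric circles of radius r, 2r, 3r.

    Relative values are percentages of that frame's total detected
    particles; frames with zero particles report the percentages as NaN
    (missing), not 0.
    """

    center: tuple[float, float]
    radius_px: float
    radius_um: float
    table: pd.DataFrame  # columns: frame, n_r, n_2r, n_3r, N, pct_r, pct_2r, pct_3r

    def to_csv(self, path) -> None:
        self.table.to_csv(path, index=False)


def roi_timeseries(
    frames: Sequence[ParticleSet],
    center: tuple[float, float],
    radius_r: float,
) -> RoiSeries:
    """Count centroids at distance ≤ r, ≤ 2r, ≤ 3r from the ROI center.

    Circle membership uses ``≤`` on the centroid–center distance, so a
    particle exactly on the boundary counts as inside.
    """
    if radius_r <= 0:
        raise ValueError("radius_r must be > 0")
    if not frames:
        raise ValueError("need at least one frame")
    w, h = frames[0].width, frames[0].height
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ValueError("ROI center must lie inside the image")

    rows = []
    for i, ps in enumerate(frames):
        pts = ps.centroids
        if len(pts):
            d = np.hypot(pts[:, 0] - cx, pts[:, 1] - cy)
            n1 = int((d <= radius_r).sum())
            n2 = int((d <= 2 * radius_r).sum())
            n3 = int((d <= 3 * radius_r).sum())
        else:
            n1 = n2 = n3 = 0
        N = len(pts)
        pct = lambda k: 100.0 * k / N if N else np.nan
        rows.append(
            {
                "frame": i,
                "n_r": n1,
                "n_2r": n2,
                "n_3r": n3,
                "N": N,
                "pct_r": pct(n1),
                "pct_2r": pct(n2),
                "pct_3r": pct(n3),
            }
        )
    return RoiSeries(
        center=(float(cx), float(cy)),
        radius_px=float(radius_r),
        radius_um=float(radius_r) * frames[0].scale,
        table=pd.DataFrame(rows),
    )
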