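"""Ground-truthed synthetic microscopy fields and videos.

Stands in for real recordings in tests and demos: every generator plants
cells at known positions (and, for stained fields, known subpopulation
labels), renders them, and returns the truth alongside the image so
detection and classification can be checked against it exactly.

Three generators:

* :func:`make_field` — dark-background intensity field with bright
  elliptical sperm heads at non-overlapping planted positions.
* :func:`make_motion_video` — frame sequence in which cells take random
  steps; with drift strength κ > 0 the step direction is, with probability
  κ, the exact bearing toward an attractant point (κ = 0 is an unbiased
  control). Cells reflect at the field boundary.
* :func:`make_stained_field` — RGB field with cells rendered per the five
  staining patterns (blue/red head, optional green acrosomal cap, green
  head+tail for IFI), hues drawn strictly inside the classifier's bands,
  with optional per-pixel hue jitter.

Plus :func:`agreement_stats`, the Pearson/Spearman + Bland–Altman utility
used to compare two measurement series.

All generators are deterministic given their seed. Cells are filled
ellipses with Gaussian edge softening (σ = 1 px) so Otsu segmentation is
stable; optics (point-spread function, phase-contrast halos) and flagellar
kinematics are not simulated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.ndimage import gaussian_filter
from skimage import color as skcolor
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .functionality import Subtype
from .imaging import DetectionParams, FieldFrame, Particle, ParticleSet

__all__ = [
    "FieldSpec",
    "MotionSpec",
    "StainSpec",
    "make_field",
    "make_motion_video",
    "make_stained_field",
    "truth_particle_set",
    "agreement_stats",
    "SUBTYPE_HUES",
]

# Mid-band hues (0–255 scale) used by the renderer; strictly inside the
# classifier's default bands (red: >200 or <20; green: 50–125; blue: 130–185).
HUE_RED = 235.0
HUE_GREEN = 87.0
HUE_BLUE = 157.0

SUBTYPE_HUES = {
    Subtype.IAIM: (HUE_BLUE, HUE_GREEN),   # head hue, cap hue (None = no cap)
    Subtype.IADM: (HUE_RED, HUE_GREEN),
    Subtype.DAIM: (HUE_BLUE, None),
    Subtype.DADM: (HUE_RED, None),
    Subtype.IFI: (HUE_GREEN, None),        # whole cell green; tail added
}


@dataclass(frozen=True)
class FieldSpec:
    """A still field: geometry, cell shape/brightness, background, seed.

    Defaults emulate bull sperm heads (≈ 9 × 4.5 µm ellipse ≈ 32 µm²) at
    1 µm/px on a dark fluorescence background.
    """

    width: int = 256
    height: int = 256
    scale: float = 1.0
    n_cells: int = 50
    major_um: float = 9.0            # full major axis
    minor_um: float = 4.5            # full minor axis
    intensity: int = 220
    background: int = 10
    noise_sd: float = 0.0
    seed: int = 0

    def axes_px(self) -> tuple[float, float]:
        return self.major_um / 2 / self.scale, self.minor_um / 2 / self.scale

    def recommended_detection(self) -> "DetectionParams":
        """Size filter matched to this spec's rendered cells.

        Gaussian edge softening plus equalization makes a head segment
        larger than its nominal ellipse area (up to ~2.5×), while two
        bridged heads exceed 4×; bounds of 0.5× and 4× nominal keep single
        cells and reject both fragments and merged pairs.
        """
        nominal = math.pi * (self.major_um / 2) * (self.minor_um / 2)
        return DetectionParams(
            min_area_um2=0.5 * nominal, max_area_um2=4.0 * nominal
        )


@dataclass(frozen=True)
class MotionSpec:
    """A motion model: step lengths, attractant point, drift strength κ.

    Step lengths are Rayleigh-distributed (scale ``step_scale`` px/frame).
    With probability κ a cell's step points exactly at the attractant
    (clamped so it never overshoots); otherwise the direction is uniform.
    κ = 0 is the unbiased control.

    Cells are sterically excluded: after every step, centers closer than
    ``min_separation_px`` (default: one head length + 2 px, taken from the
    field spec) are pushed apart, so accumulation produces a dense but
    resolvable cluster instead of a single merged blob.
    """

    n_frames: int = 150
    step_scale: float = 2.5
    attractant: tuple[float, float] = (160.0, 160.0)
    kappa: float = 0.0
    min_separation_px: Optional[float] = None
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.kappa <= 1.0:
            raise ValueError("kappa must lie in [0, 1]")
        if self.n_frames < 1:
            raise ValueError("n_frames must be ≥ 1")


@dataclass(frozen=True)
class StainSpec:
    """A stained field: subtype mix, rendering recipe parameters, jitter.

    ``proportions`` maps the five subtypes to fractions summing to 1.
    ``hue_jitter_sd`` adds zero-mean Gaussian noise (0–255 hue units,
    wrapped) to every cell pixel's hue.
    """

    width: int = 512
    height: int = 512
    scale: float = 1.0
    n_cells: int = 100
    proportions: tuple[float, float, float, float, float] = (0.2, 0.2, 0.2, 0.2, 0.2)
    major_um: float = 9.0
    minor_um: float = 4.5
    tail_len_um: float = 15.0
    cap_fraction: float = 0.25       # head cut: pixels with x' > cap_fraction·a form the cap
    saturation: int = 220
    value: int = 230
    hue_jitter_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.proportions) - 1.0) > 1e-9:
            raise ValueError("subtype proportions must sum to 1")


_SUBTYPE_ORDER = [Subtype.IAIM, Subtype.IADM, Subtype.DAIM, Subtype.DADM, Subtype.IFI]


def _place_centers(
    rng: np.random.Generator,
    width: int,
    height: int,
    n: int,
    margin: float,
    min_dist: float,
    max_tries: int = 20000,
) -> np.ndarray:
    """Rejection-sample n non-overlapping centers fully in-bounds."""
    centers: list[tuple[float, float]] = []
    tries = 0
    while len(centers) < n:
        if tries >= max_tries:
            raise RuntimeError(
                f"could only place {len(centers)}/{n} cells without overlap; "
                "lower the density or enlarge the field"
            )
        tries += 1
        x = rng.uniform(margin, width - 1 - margin)
        y = rng.uniform(margin, height - 1 - margin)
        if all((x - cx) ** 2 + (y - cy) ** 2 >= min_dist**2 for cx, cy in centers):
            centers.append((x, y))
    return np.array(centers) if centers else np.empty((0, 2))


def _stamp_ellipse(canvas: np.ndarray, cx, cy, a, b, theta, value) -> None:
    rr, cc = draw_ellipse(cy, cx, b, a, shape=canvas.shape, rotation=theta)
    canvas[rr, cc] = value


def make_field(spec: FieldSpec) -> tuple[FieldFrame, pd.DataFrame]:
    """Render a still field of bright elliptical heads; return image + truth.

    Truth is a DataFrame with columns (cell_id, x, y, theta) in analysis
    coordinates. Byte-identical output for a fixed seed.
    """
    rng = np.random.default_rng(spec.seed)
    a, b = spec.axes_px()
    margin = max(a, b) + 2.0
    # head length + 4 px: closer pairs can blur-bridge into one component
    min_dist = 2 * max(a, b) + 4.0
    centers = _place_centers(rng, spec.width, spec.height, spec.n_cells, margin, min_dist)
    thetas = rng.uniform(0, math.pi, size=len(centers))

    cells = np.zeros((spec.height, spec.width), dtype=float)
    for (x, y), th in zip(centers, thetas):
        _stamp_ellipse(cells, x, y, a, b, th, float(spec.intensity))
    cells = gaussian_filter(cells, sigma=1.0)

    img = cells + spec.background
    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(np.rint(img), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(len(centers)),
            "x": centers[:, 0] if len(centers) else [],
            "y": centers[:, 1] if len(centers) else [],
            "theta": thetas,
        }
    )
    return FieldFrame(img, spec.scale), truth


def _render_positions(spec: FieldSpec, positions: np.ndarray, thetas, frame_index: int) -> FieldFrame:
    a, b = spec.axes_px()
    cells = np.zeros((spec.height, spec.width), dtype=float)
    for (x, y), th in zip(positions, thetas):
        _stamp_ellipse(cells, x, y, a, b, th, float(spec.intensity))
    cells = gaussian_filter(cells, sigma=1.0)
    img = np.clip(np.rint(cells + spec.background), 0, 255).astype(np.uint8)
    return FieldFrame(img, spec.scale, frame_index)


def _relax_exclusion(
    pos: np.ndarray, d_min: float, rng: np.random.Generator, n_iter: int = 30
) -> np.ndarray:
    """Push apart centers closer than d_min (symmetric pairwise relaxation)."""
    from scipy.spatial import cKDTree

    for _ in range(n_iter):
        pairs = cKDTree(pos).query_pairs(d_min, output_type="ndarray")
        if len(pairs) == 0:
            break
        delta = pos[pairs[:, 1]] - pos[pairs[:, 0]]
        d = np.hypot(delta[:, 0], delta[:, 1])
        zero = d < 1e-9
        if zero.any():
            delta[zero] = rng.normal(size=(int(zero.sum()), 2))
            d[zero] = np.hypot(delta[zero, 0], delta[zero, 1])
        vec = delta * (0.5 * (d_min - np.minimum(d, d_min)) / d)[:, None]
        shift = np.zeros_like(pos)
        np.add.at(shift, pairs[:, 1], vec)
        np.add.at(shift, pairs[:, 0], -vec)
        pos = pos + shift
    return pos


def make_motion_video(
    field: FieldSpec,
    motion: MotionSpec,
    render: bool = True,
) -> tuple[Optional[list[FieldFrame]], list[pd.DataFrame]]:
    """Simulate cell motion with optional drift toward an attractant.

    Returns ``(frames, truth)``: rendered frames (or None with
    ``render=False``) and one truth DataFrame (cell_id, x, y) per frame.
    Initial positions are non-overlapping and in-bounds; cells reflect at
    the boundary margin and respect a minimum pairwise separation.
    """
    rng = np.random.default_rng(motion.seed)
    a, b = field.axes_px()
    margin = max(a, b) + 2.0
    # default separation = one head length + 4 px: below that, Gaussian edge
    # softening can bridge two thresholded heads into one component
    d_min = (
        motion.min_separation_px
        if motion.min_separation_px is not None
        else 2 * max(a, b) + 4.0
    )
    w, h = field.width, field.height
    ax, ay = motion.attractant

    pos = _place_centers(
        rng, w, h, field.n_cells, margin, d_min, max_tries=200 * field.n_cells
    )
    thetas = rng.uniform(0, math.pi, size=field.n_cells)

    frames: Optional[list[FieldFrame]] = [] if render else None
    truth: list[pd.DataFrame] = []
    for t in range(motion.n_frames):
        truth.append(
            pd.DataFrame(
                {"cell_id": np.arange(field.n_cells), "x": pos[:, 0], "y": pos[:, 1]}
            )
        )
        if frames is not None:
            frames.append(_render_positions(field, pos, thetas, t))
        if t == motion.n_frames - 1:
            break
        steps = rng.rayleigh(motion.step_scale, size=field.n_cells)
        biased = rng.random(field.n_cells) < motion.kappa
        angles = rng.uniform(0, 2 * math.pi, size=field.n_cells)
        to_att = np.arctan2(ay - pos[:, 1], ax - pos[:, 0])
        angles[biased] = to_att[biased]
        # a biased step never overshoots the attractant
        dist = np.hypot(ax - pos[:, 0], ay - pos[:, 1])
        steps[biased] = np.minimum(steps[biased], dist[biased])
        pos = pos + np.column_stack([steps * np.cos(angles), steps * np.sin(angles)])
        pos = _relax_exclusion(pos, d_min, rng)
        # reflect at the in-bounds margin box
        for k, lim in ((0, w - 1 - margin), (1, h - 1 - margin)):
            pos[:, k] = np.abs(pos[:, k] - margin) + margin
            over = pos[:, k] > lim
            pos[over, k] = 2 * lim - pos[over, k]
            pos[:, k] = np.clip(pos[:, k], margin, lim)
    return frames, truth


def truth_particle_set(
    truth: pd.DataFrame, width: int, height: int, scale: float, frame_index: int = 0
) -> ParticleSet:
    """Wrap a truth table as a ParticleSet (unit-area particles) for analysis."""
    particles = [
        Particle(float(r.x), float(r.y), scale * scale, 1) for r in truth.itertuples()
    ]
    return ParticleSet(particles, frame_index, width, height, scale)


def make_stained_field(spec: StainSpec) -> tuple[FieldFrame, pd.DataFrame]:
    """Render an RGB stained field; return image + per-cell truth labels.

    Each cell's head is a filled ellipse in its subtype's hue; IAIM/IADM
    additionally get a green acrosomal cap (the head region beyond
    ``cap_fraction`` of the semi-major axis along the cell's axis), and IFI
    cells get a thin green tail. Subtype counts follow ``proportions``
    exactly (largest-remainder rounding). Truth columns: cell_id, x, y,
    subtype.
    """
    rng = np.random.default_rng(spec.seed)
    a = spec.major_um / 2 / spec.scale
    b = spec.minor_um / 2 / spec.scale
    tail_px = spec.tail_len_um / spec.scale
    margin = a + tail_px + 2.0
    min_dist = 2 * (a + tail_px) + 2.0
    centers = _place_centers(rng, spec.width, spec.height, spec.n_cells, margin, min_dist)
    thetas = rng.uniform(0, math.pi, size=len(centers))

    # largest-remainder apportionment of subtype counts
    quota = np.array(spec.proportions) * spec.n_cells
    counts = np.floor(quota).astype(int)
    rem = spec.n_cells - counts.sum()
    order = np.argsort(-(quota - counts))
    counts[order[:rem]] += 1
    labels = np.repeat(np.arange(5), counts)
    rng.shuffle(labels)

    hue = np.zeros((spec.height, spec.width), dtype=float)
    on = np.zeros((spec.height, spec.width), dtype=bool)
    for (x, y), th, lab in zip(centers, thetas, labels):
        subtype = _SUBTYPE_ORDER[lab]
        head_hue, cap_hue = SUBTYPE_HUES[subtype]
        rr, cc = draw_ellipse(y, x, b, a, shape=hue.shape, rotation=th)
        hue[rr, cc] = head_hue
        on[rr, cc] = True
        if cap_hue is not None:
            # axial coordinate of each head pixel; skimage's ellipse rotation
            # puts the c-radius (major) axis along (dx, dy) = (cos θ, −sin θ)
            xs = (cc - x) * math.cos(th) - (rr - y) * math.sin(th)
            cap = xs > spec.cap_fraction * a
            hue[rr[cap], cc[cap]] = cap_hue
        if subtype is Subtype.IFI:
            # start just inside the head so head and tail stay one component
            x0 = x - (a - 1.0) * math.cos(th)
            y0 = y + (a - 1.0) * math.sin(th)
            x1 = x - (a + tail_px) * math.cos(th)
            y1 = y + (a + tail_px) * math.sin(th)
            lr, lc = draw_line(int(round(y0)), int(round(x0)), int(round(y1)), int(round(x1)))
            keep = (lr >= 0) & (lr < spec.height) & (lc >= 0) & (lc < spec.width)
            hue[lr[keep], lc[keep]] = HUE_GREEN
            on[lr[keep], lc[keep]] = True

    if spec.hue_jitter_sd > 0:
        jitter = rng.normal(0.0, spec.hue_jitter_sd, size=hue.shape)
        hue = np.mod(hue + jitter, 256.0)

    hsv = np.zeros((spec.height, spec.width, 3), dtype=float)
    hsv[..., 0] = (hue % 256.0) / 255.0
    hsv[..., 1] = np.where(on, spec.saturation / 255.0, 0.0)
    hsv[..., 2] = np.where(on, spec.value / 255.0, 0.0)
    rgb = np.clip(np.rint(skcolor.hsv2rgb(hsv) * 255.0), 0, 255).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "cell_id": np.arange(len(centers)),
            "x": centers[:, 0] if len(centers) else [],
            "y": centers[:, 1] if len(centers) else [],
            "subtype": [_SUBTYPE_ORDER[l].value for l in labels],
        }
    )
    return FieldFrame(rgb, spec.scale), truth


def agreement_stats(
    x: Sequence[float],
    y: Sequence[float],
    method: Literal["pearson", "spearman"] = "pearson",
) -> tuple[float, float]:
    """Correlation between two measurement series plus Bland–Altman bias.

    Returns ``(r, bias)`` with ``bias = mean(x − y)``. A constant series
    makes the correlation undefined → NaN.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or len(x) < 3:
        raise ValueError("x and y must be equal-length 1-D series of length ≥ 3")
    bias = float(np.mean(x - y))
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), bias
    if method == "pearson":
        r = stats.pearsonr(x, y).statistic
    elif method == "spearman":
        r = stats.spearmanr(x, y).statistic
    else:
        raise ValueError("method must be 'pearson' or 'spearman'")
    return float(r), bias
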