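"""Shared image preprocessing and particle detection.

This module re-implements the "Analyze Particles" stage that every analysis
pipeline depends on: grayscale conversion, global histogram equalization,
Otsu (or fixed-level) binarization, and connected-component extraction with
physical-size filtering in µm².

Conventions
-----------
* Rasters are ``numpy`` arrays indexed ``[row, col]`` == ``[y, x]``.
* Coordinates are 0-based with the pixel-center convention; centroids are
  continuous (arithmetic mean of member pixel coordinates).
* Intensity images are 8-bit (values in 0–255); RGB images have shape
  ``(H, W, 3)``.
* Size filtering always happens in µm² (``pixels × scale²``) so parameter
  files transfer between magnifications.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Literal, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import measure

__all__ = [
    "FieldFrame",
    "DetectionParams",
    "Particle",
    "ParticleSet",
    "to_grayscale",
    "equalize_histogram",
    "otsu_level",
    "binarize",
    "detect_particles",
    "ConstantImageWarning",
    "HighDensityWarning",
]

# ITU-R BT.601 luminance weights (the convention of common particle-analysis
# software for RGB→8-bit conversion).
LUMA_WEIGHTS = (0.299, 0.587, 0.114)


class ConstantImageWarning(UserWarning):
    """Raised when binarization receives a constant image (empty foreground)."""


class HighDensityWarning(UserWarning):
    """>5% of foreground area discarded by the max-size filter.

    At very high cell densities colliding cells segment as one aggregate
    larger than the size limit and are dropped, which silently depresses
    counts; this warning surfaces that failure mode.
    """


@dataclass(frozen=True)
class FieldFrame:
    """One raster (intensity or RGB) with its physical scale.

    Parameters
    ----------
    pixels : ndarray
        ``(H, W)`` intensity or ``(H, W, 3)`` RGB, values in 0–255.
    scale : float
        µm per pixel, > 0.
    frame_index : int
        Ordinal within a video; 0 for stills.
    """

    pixels: np.ndarray
    scale: float
    frame_index: int = 0

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim not in (2, 3) or (px.ndim == 3 and px.shape[2] != 3):
            raise ValueError("pixels must be (H, W) or (H, W, 3)")
        if px.shape[0] < 1 or px.shape[1] < 1:
            raise ValueError("image must be at least 1×1")
        if self.scale <= 0:
            raise ValueError("scale (µm/pixel) must be > 0")
        if px.size and (px.min() < 0 or px.max() > 255):
            raise ValueError("channel values must lie in [0, 255]")
        object.__setattr__(self, "pixels", px)

    @property
    def is_rgb(self) -> bool:
        return self.pixels.ndim == 3

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape[0], self.pixels.shape[1]


@dataclass(frozen=True)
class DetectionParams:
    """Particle-detection settings.

    ``min_area_um2``/``max_area_um2`` bound the accepted particle area in µm²
    (species-dependent sperm-head size). ``threshold_method`` is ``"otsu"``
    (default) or ``"fixed"`` with ``fixed_level``. ``bright_cells`` selects the
    foreground polarity: True for fluorescence (bright-on-dark), False for
    negative phase contrast (dark-on-bright).
    """

    min_area_um2: float = 10.0
    max_area_um2: float = 80.0
    threshold_method: Literal["otsu", "fixed"] = "otsu"
    fixed_level: int = 128
    connectivity: Literal[4, 8] = 8
    bright_cells: bool = True
    equalize: bool = True

    def __post_init__(self) -> None:
        if not 0 < self.min_area_um2 < self.max_area_um2:
            raise ValueError("require 0 < min_area_um2 < max_area_um2")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.threshold_method not in ("otsu", "fixed"):
            raise ValueError("threshold_method must be 'otsu' or 'fixed'")


@dataclass(frozen=True)
class Particle:
    """One detected particle: continuous centroid (px) and area (µm²)."""

    centroid_x: float
    centroid_y: float
    area_um2: float
    pixel_count: int


@dataclass
class ParticleSet:
    """Detected particles for one frame, with source geometry."""

    particles: list[Particle]
    frame_index: int
    width: int
    height: int
    scale: float

    def __len__(self) -> int:
        return len(self.particles)

    def __iter__(self):
        return iter(self.particles)

    @property
    def centroids(self) -> np.ndarray:
        """``(n, 2)`` array of (x, y) centroids; empty → shape (0, 2)."""
        if not self.particles:
            return np.empty((0, 2), dtype=float)
        return np.array([(p.centroid_x, p.centroid_y) for p in self.particles])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "frame_index": self.frame_index,
                "x_px": [p.centroid_x for p in self.particles],
                "y_px": [p.centroid_y for p in self.particles],
                "area_um2": [p.area_um2 for p in self.particles],
            }
        )


def to_grayscale(frame: FieldFrame) -> FieldFrame:
    """Convert RGB to 8-bit intensity via BT.601 luminance weights.

    Already-grayscale input passes through unchanged.
    """
    if not frame.is_rgb:
        return frame
    w = np.asarray(LUMA_WEIGHTS)
    gray = np.tensordot(frame.pixels.astype(float), w, axes=([2], [0]))
    gray = np.clip(np.rint(gray), 0, 255).astype(np.uint8)
    return FieldFrame(gray, frame.scale, frame.frame_index)


def equalize_histogram(frame: FieldFrame) -> FieldFrame:
    """Global 256-bin histogram equalization on an 8-bit intensity image.

    Uses the classic CDF remapping ``round((cdf − cdf_min)/(N − cdf_min)·255)``.
    A constant image is returned unchanged (degenerate histogram).
    """
    if frame.is_rgb:
        raise ValueError("equalize_histogram expects a single-channel frame")
    px = frame.pixels.astype(np.uint8)
    hist = np.bincount(px.ravel(), minlength=256)
    cdf = np.cumsum(hist)
    nonzero = cdf[hist > 0]
    cdf_min = nonzero[0]
    n = px.size
    if n == cdf_min:  # constant image
        return frame
    lut = np.rint((cdf - cdf_min) / (n - cdf_min) * 255.0)
    lut = np.clip(lut, 0, 255).astype(np.uint8)
    return FieldFrame(lut[px], frame.scale, frame.frame_index)


def otsu_level(image: np.ndarray) -> int:
    """Otsu threshold by exhaustive between-class-variance maximization.

    All 256 candidate levels are scanned; a pixel is foreground when its
    value is strictly greater than the returned level. Among equal-variance
    maxima the lowest level wins.
    """
    image = np.asarray(image)
    hist = np.bincount(image.astype(np.uint8).ravel(), minlength=256).astype(float)
    n = hist.sum()
    p = hist / n
    omega = np.cumsum(p)                      # class-0 probability at level t
    mu = np.cumsum(p * np.arange(256))        # class-0 mean mass
    mu_t = mu[-1]
    with np.errstate(divide="ignore", invalid="ignore"):
        sigma_b = (mu_t * omega - mu) ** 2 / (omega * (1.0 - omega))
    sigma_b = np.nan_to_num(sigma_b, nan=0.0, posinf=0.0)
    return int(np.argmax(sigma_b))            # argmax takes the lowest maximizer


def binarize(
    frame: FieldFrame,
    method: Literal["otsu", "fixed"] = "otsu",
    fixed_level: int = 128,
    bright_cells: bool = True,
) -> np.ndarray:
    """Threshold an intensity frame into a boolean foreground mask.

    Foreground = cells. ``bright_cells=False`` inverts polarity for
    dark-on-bright (negative phase contrast) imagery. A constant image
    yields an empty mask and a :class:`ConstantImageWarning`.
    """
    if frame.is_rgb:
        raise ValueError("binarize expects a single-channel frame")
    px = frame.pixels.astype(np.uint8)
    if px.min() == px.max():
        warnings.warn("constant image: empty foreground", ConstantImageWarning)
        return np.zeros(px.shape, dtype=bool)
    level = otsu_level(px) if method == "otsu" else int(fixed_level)
    return px > level if bright_cells else px <= level


def detect_particles(
    mask: np.ndarray,
    scale: float,
    params: DetectionParams,
    frame_index: int = 0,
) -> ParticleSet:
    """Label connected components and keep those inside the µm² size bounds.

    Centroids are arithmetic means of member pixel coordinates (x = column,
    y = row, pixel-center convention). ``area_um2 = pixel_count × scale²``
    exactly. Empty mask → empty ParticleSet.
    """
    if scale <= 0:
        raise ValueError("scale must be > 0")
    mask = np.asarray(mask, dtype=bool)
    conn = 1 if params.connectivity == 4 else 2
    labels = measure.label(mask, connectivity=conn)
    particles: list[Particle] = []
    foreground_px = 0
    oversize_px = 0
    for region in measure.regionprops(labels):
        foreground_px += region.area
        area = region.area * scale * scale
        if params.min_area_um2 <= area <= params.max_area_um2:
            cy, cx = region.centroid
            particles.append(Particle(float(cx), float(cy), float(area), int(region.area)))
        elif area > params.max_area_um2:
            oversize_px += region.area
    if foreground_px and oversize_px > 0.05 * foreground_px:
        warnings.warn(
            f"{100 * oversize_px / foreground_px:.0f}% of foreground area exceeds "
            "max_area_um2 and was discarded; counts in dense regions are unreliable",
            HighDensityWarning,
        )
    return ParticleSet(
        particles=particles,
        frame_index=frame_index,
        width=mask.shape[1],
        height=mask.shape[0],
        scale=scale,
    )


def preprocess_and_detect(frame: FieldFrame, params: DetectionParams) -> ParticleSet:
    """Full chain: grayscale → (optional) equalize → binarize → detect."""
    gray = to_grayscale(frame)
    if params.equalize:
        gray = equalize_histogram(gray)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConstantImageWarning)
        mask = binarize(
            gray,
            method=params.threshold_method,
            fixed_level=params.fixed_level,
            bright_cells=params.bright_cells,
        )
    return detect_particles(mask, frame.scale, params, frame.frame_index)
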