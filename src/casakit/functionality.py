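"""Fluorescence-based sperm functionality classification.

Triple-stained sperm (a membrane-impermeant red nuclear stain, a
membrane-permeant blue nuclear stain, and a green esterase substrate
reporting acrosome/cytoplasm activity) show five patterns that map to
plasma-membrane × acrosome status:

* IAIM — intact acrosome, intact membrane: blue head with green acrosomal cap
* IADM — intact acrosome, damaged membrane: red head with green acrosomal cap
* DAIM — damaged acrosome, intact membrane: blue head
* DADM — damaged acrosome, damaged membrane: red head
* IFI  — increased fluorescence intensity: whole cell (head and tail) green

Each segmented cell's pixels are classified into red/green/blue hue bands
(HSV hue on a 0–255 scale: red iff H > 200 or H < 20, green iff
50 < H < 125, blue iff 130 < H < 185 — empirically determined bands), the
per-cell color ratios are formed with the cell's total pixel count as
denominator, and a small decision tree assigns the subtype.

Cell segmentation runs on the HSV value (brightness) channel; hue
classification uses the original RGB, and histogram equalization is
disabled by default here because it would distort hue.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from enum import Enum
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from skimage import color as skcolor

from .imaging import DetectionParams, FieldFrame, ParticleSet, binarize, detect_particles
from skimage import measure

__all__ = [
    "Subtype",
    "HueBands",
    "TreeParams",
    "CellRecord",
    "FunctionalitySummary",
    "hue_image",
    "pixel_hue",
    "classify_pixel",
    "color_ratios",
    "classify_cell",
    "summarize",
    "classify_field",
]


class Subtype(str, Enum):
    IAIM = "IAIM"
    IADM = "IADM"
    DAIM = "DAIM"
    DADM = "DADM"
    IFI = "IFI"
    UNCLASSIFIED = "UNCLASSIFIED"


@dataclass(frozen=True)
class HueBands:
    """Hue bands on the 0–255 hue scale; strict inequalities as printed.

    red iff H > red_high or H < red_low; green iff green_low < H < green_high;
    blue iff blue_low < H < blue_high. The complement (and undefined hue) is
    "unclassified".
    """

    red_low: float = 20.0
    red_high: float = 200.0
    green_low: float = 50.0
    green_high: float = 125.0
    blue_low: float = 130.0
    blue_high: float = 185.0


@dataclass(frozen=True)
class TreeParams:
    """Decision-tree thresholds.

    tau_ifi : green ratio at or above which the whole cell is considered
        uniformly green (IFI). Default 0.75.
    tau_acr : green ratio at or above which a green acrosomal cap is present
        (acrosome intact). Default 0.10.
    min_value, min_saturation : 0–255 gates below which a pixel's hue is
        ignored (dark / achromatic pixels carry hue noise).
    """

    tau_ifi: float = 0.75
    tau_acr: float = 0.10
    min_value: float = 30.0
    min_saturation: float = 30.0


@dataclass
class CellRecord:
    """One cell's color composition and assigned subpopulation."""

    cell_id: int
    centroid_x: float
    centroid_y: float
    area_um2: float
    pixel_count: int
    red_ratio: float
    green_ratio: float
    blue_ratio: float
    subtype: Subtype


@dataclass
class FunctionalitySummary:
    """Per-image totals: counts/percentages per subtype plus integrity rates."""

    total: int
    counts: dict[Subtype, int]
    percentages: dict[Subtype, float]
    pct_acrosome_intact: float
    pct_membrane_intact: float

    def to_dict(self) -> dict:
        return {
            "total": self.total,
            "counts": {k.value: v for k, v in self.counts.items()},
            "percentages": {k.value: v for k, v in self.percentages.items()},
            "pct_acrosome_intact": self.pct_acrosome_intact,
            "pct_membrane_intact": self.pct_membrane_intact,
        }


def hue_image(rgb: np.ndarray, tree: TreeParams = TreeParams()) -> np.ndarray:
    """Per-pixel HSV hue on the 0–255 scale; NaN where hue is unreliable.

    Hue is undefined for achromatic pixels and noisy for dark or
    low-saturation ones; those report NaN and end up unclassified.
    """
    rgb = np.asarray(rgb)
    hsv = skcolor.rgb2hsv(rgb.astype(np.uint8))
    h = hsv[..., 0] * 255.0
    s = hsv[..., 1] * 255.0
    v = hsv[..., 2] * 255.0
    h = h.copy()
    h[(s < tree.min_saturation) | (v < tree.min_value)] = np.nan
    return h


def pixel_hue(r: int, g: int, b: int) -> float:
    """Hue of one 8-bit RGB pixel on [0, 256); NaN if achromatic (s = 0)."""
    px = np.array([[[r, g, b]]], dtype=np.uint8)
    hsv = skcolor.rgb2hsv(px)[0, 0]
    if hsv[1] == 0:
        return float("nan")
    return float(hsv[0] * 255.0)


def classify_pixel(h: float, bands: HueBands = HueBands()) -> str:
    """Band membership of a hue value: 'red' | 'green' | 'blue' | 'none'."""
    if h is None or np.isnan(h):
        return "none"
    if h > bands.red_high or h < bands.red_low:
        return "red"
    if bands.green_low < h < bands.green_high:
        return "green"
    if bands.blue_low < h < bands.blue_high:
        return "blue"
    return "none"


def color_ratios(
    hues: np.ndarray, bands: HueBands = HueBands()
) -> tuple[float, float, float]:
    """Red/green/blue pixel ratios of one cell.

    The denominator is the cell's total pixel count, including unclassified
    pixels, so the three ratios sum to at most 1.
    """
    hues = np.asarray(hues, dtype=float).ravel()
    total = hues.size
    if total == 0:
        raise ValueError("zero-pixel cell: invalid segmentation")
    valid = ~np.isnan(hues)
    h = hues[valid]
    red = ((h > bands.red_high) | (h < bands.red_low)).sum()
    green = ((h > bands.green_low) & (h < bands.green_high)).sum()
    blue = ((h > bands.blue_low) & (h < bands.blue_high)).sum()
    return red / total, green / total, blue / total


def classify_cell(
    ratios: tuple[float, float, float], tree: TreeParams = TreeParams()
) -> Subtype:
    """Assign a subpopulation from a cell's (red, green, blue) ratios.

    1. green ≥ tau_ifi → IFI (whole cell green).
    2. Otherwise the acrosome is intact iff green ≥ tau_acr (a green cap is
       present).
    3. Membrane status by majority of nuclear stain: damaged iff
       red > blue, intact iff blue > red.
    4. An exact red == blue tie (including the all-zero case) leaves the
       membrane status undetermined → UNCLASSIFIED.
    """
    red, green, blue = ratios
    if green >= tree.tau_ifi:
        return Subtype.IFI
    acrosome_intact = green >= tree.tau_acr
    if red > blue:
        return Subtype.IADM if acrosome_intact else Subtype.DADM
    if blue > red:
        return Subtype.IAIM if acrosome_intact else Subtype.DAIM
    return Subtype.UNCLASSIFIED


def summarize(
    cells: Iterable[CellRecord], ifi_membrane_intact: bool = True
) -> FunctionalitySummary:
    """Aggregate per-cell records into image-level counts and percentages.

    Acrosome-intact % = (IAIM + IADM) / total. Membrane-intact % =
    (IAIM + DAIM [+ IFI]) / total; IFI counts as membrane-intact by default
    because those cells retain the esterase substrate.
    """
    cells = list(cells)
    counts = {s: 0 for s in Subtype}
    for c in cells:
        counts[c.subtype] += 1
    total = len(cells)
    if total == 0:
        return FunctionalitySummary(0, counts, {s: 0.0 for s in Subtype}, 0.0, 0.0)
    pct = {s: 100.0 * counts[s] / total for s in Subtype}
    acr = 100.0 * (counts[Subtype.IAIM] + counts[Subtype.IADM]) / total
    mem_n = counts[Subtype.IAIM] + counts[Subtype.DAIM]
    if ifi_membrane_intact:
        mem_n += counts[Subtype.IFI]
    return FunctionalitySummary(total, counts, pct, acr, 100.0 * mem_n / total)


def classify_field(
    frame: FieldFrame,
    detection: Optional[DetectionParams] = None,
    bands: HueBands = HueBands(),
    tree: TreeParams = TreeParams(),
) -> tuple[list[CellRecord], FunctionalitySummary]:
    """Full pipeline: segment a stained RGB field and classify every cell.

    Segmentation runs on the HSV value channel (max of R, G, B) with Otsu
    thresholding and the configured size filter; equalization is off so hue
    is untouched. Classification then reads the original RGB under each
    cell's pixel mask.
    """
    if not frame.is_rgb:
        raise ValueError("classify_field expects an RGB frame")
    detection = detection or DetectionParams(equalize=False)
    if detection.equalize:
        detection = replace(detection, equalize=False)

    value = frame.pixels.max(axis=2).astype(np.uint8)
    mask = binarize(
        FieldFrame(value, frame.scale, frame.frame_index),
        method=detection.threshold_method,
        fixed_level=detection.fixed_level,
        bright_cells=detection.bright_cells,
    )
    conn = 1 if detection.connectivity == 4 else 2
    labels = measure.label(mask, connectivity=conn)
    hues = hue_image(frame.pixels, tree)

    records: list[CellRecord] = []
    for region in measure.regionprops(labels):
        area = region.area * frame.scale**2
        if not (detection.min_area_um2 <= area <= detection.max_area_um2):
            continue
        rr, cc = region.coords[:, 0], region.coords[:, 1]
        ratios = color_ratios(hues[rr, cc], bands)
        cy, cx = region.centroid
        records.append(
            CellRecord(
                cell_id=len(records),
                centroid_x=float(cx),
                centroid_y=float(cy),
                area_um2=float(area),
                pixel_count=int(region.area),
                red_ratio=ratios[0],
                green_ratio=ratios[1],
                blue_ratio=ratios[2],
                subtype=classify_cell(ratios, tree),
            )
        )
    return records, summarize(records)


def cells_to_dataframe(cells: Sequence[CellRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "cell_id": [c.cell_id for c in cells],
            "x": [c.centroid_x for c in cells],
            "y": [c.centroid_y for c in cells],
            "area_um2": [c.area_um2 for c in cells],
            "red_ratio": [c.red_ratio for c in cells],
            "green_ratio": [c.green_ratio for c in cells],
            "blue_ratio": [c.blue_ratio for c in cells],
            "subtype": [c.subtype.value for c in cells],
        }
    )
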