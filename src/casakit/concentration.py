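"""Sperm concentration from particle counts in a known chamber volume.

A fixed-depth counting chamber (e.g. an improved Neubauer hemocytometer,
depth 100 µm, or a disposable 10–20 µm chamber) images a slab of sample of
known volume: imaged field area (image dimensions × µm/px scale, or an
explicit override) × chamber depth. The concentration in millions of cells
per mL is then

    C = n · dilution · 10⁶ / V[µm³]        (1 mL = 10¹² µm³, 1 M = 10⁶ cells)

The dilution factor restores the pre-dilution concentration when the sample
was diluted before loading to avoid overlapping cells. Particles whose
centroid is in-bounds are counted — a deterministic stand-in for manual
two-edge counting rules.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .imaging import DetectionParams, FieldFrame, preprocess_and_detect

__all__ = [
    "ChamberGeometry",
    "ConcentrationResult",
    "count_field",
    "compute_concentration",
    "aggregate_fields",
]

UM3_PER_ML = 1e12
CELLS_PER_MILLION = 1e6


@dataclass(frozen=True)
class ChamberGeometry:
    """Counting volume: imaged field (µm) × chamber depth (µm), with dilution."""

    field_width_um: float
    field_height_um: float
    depth_um: float
    dilution_factor: float = 1.0

    def __post_init__(self) -> None:
        if min(self.field_width_um, self.field_height_um, self.depth_um) <= 0:
            raise ValueError("all chamber dimensions must be > 0")
        if self.dilution_factor < 1:
            raise ValueError("dilution_factor must be ≥ 1")

    @classmethod
    def from_frame(
        cls, frame: FieldFrame, depth_um: float, dilution_factor: float = 1.0
    ) -> "ChamberGeometry":
        h, w = frame.shape
        return cls(w * frame.scale, h * frame.scale, depth_um, dilution_factor)

    @property
    def volume_um3(self) -> float:
        return self.field_width_um * self.field_height_um * self.depth_um


@dataclass(frozen=True)
class ConcentrationResult:
    """Counted cells, sampled volume, and dilution-adjusted concentration."""

    n_counted: int
    volume_um3: float
    dilution_factor: float
    concentration_mcells_per_ml: float


def count_field(frame: FieldFrame, params: DetectionParams) -> int:
    """Number of size-filtered particles in one field (full detection chain)."""
    return len(preprocess_and_detect(frame, params))


def compute_concentration(n: int, geometry: ChamberGeometry) -> ConcentrationResult:
    """Concentration in millions of cells per mL from a count and geometry."""
    if n < 0:
        raise ValueError("count must be ≥ 0")
    v = geometry.volume_um3
    conc = n * geometry.dilution_factor * UM3_PER_ML / v / CELLS_PER_MILLION
    return ConcentrationResult(
        n_counted=int(n),
        volume_um3=v,
        dilution_factor=geometry.dilution_factor,
        concentration_mcells_per_ml=conc,
    )


def aggregate_fields(
    results: Sequence[ConcentrationResult],
) -> tuple[float, float, pd.DataFrame]:
    """Mean ± sample SD of per-field concentrations, plus the per-field table.

    SD uses the n−1 denominator; a single field reports SD 0.
    """
    if len(results) == 0:
        raise ValueError("need at least one field")
    conc = np.array([r.concentration_mcells_per_ml for r in results])
    mean = float(conc.mean())
    sd = float(conc.std(ddof=1)) if len(conc) > 1 else 0.0
    table = pd.DataFrame(
        {
            "n": [r.n_counted for r in results],
            "volume_um3": [r.volume_um3 for r in results],
            "M_per_ml": conc,
        }
    )
    return mean, sd, table
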