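"""Configuration, logging, and image/video I/O shared by all pipelines.

Videos are read either from an AVI container (when an ffmpeg-backed reader
is available) or — the portable path — from a directory of numbered frame
images (PNG/TIFF), sorted by filename. Every pipeline run writes its fully
resolved configuration as JSON next to its outputs, so any analysis is
reproducible from that file alone.

Configuration is layered: built-in defaults < config file < CLI flags.
Unknown keys are rejected rather than ignored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional, Sequence

import imageio.v3 as iio
import numpy as np

from .accumulation import AccumulationParams
from .functionality import HueBands, TreeParams
from .imaging import DetectionParams, FieldFrame

__all__ = [
    "RunConfig",
    "read_image",
    "write_image",
    "read_video",
    "write_frames",
    "setup_logging",
]

log = logging.getLogger("casakit")

FRAME_EXTENSIONS = (".png", ".tif", ".tiff")


def setup_logging(out_dir: Optional[Path] = None, verbosity: int = 1) -> None:
    """Log to stderr and, if an output directory is given, to run.log there."""
    level = logging.WARNING if verbosity <= 0 else logging.INFO if verbosity == 1 else logging.DEBUG
    handlers: list[logging.Handler] = [logging.StreamHandler(sys.stderr)]
    if out_dir is not None:
        out_dir.mkdir(parents=True, exist_ok=True)
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(
        level=level,
        format="%(asctime)s %(levelname)s %(message)s",
        handlers=handlers,
        force=True,
    )


def _build(cls, data: dict, context: str):
    """Construct a dataclass from a dict, rejecting unknown keys."""
    known = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown {context} keys: {sorted(unknown)}")
    return cls(**data)


@dataclass
class RunConfig:
    """Resolved settings for one pipeline run.

    ``pipeline`` ∈ {accumulate, classify, concentration, synth}. Parameter
    blocks use the owning module's dataclasses; blocks irrelevant to the
    chosen pipeline may stay at their defaults.
    """

    pipeline: str
    inputs: list[str] = field(default_factory=list)
    out_dir: str = "."
    scale: float = 1.0
    seed: int = 0
    verbosity: int = 1
    detection: DetectionParams = field(default_factory=DetectionParams)
    accumulation: Optional[AccumulationParams] = None
    roi: Optional[tuple[float, float, float]] = None   # (x, y, r) px
    bands: HueBands = field(default_factory=HueBands)
    tree: TreeParams = field(default_factory=TreeParams)
    depth_um: float = 100.0
    dilution_factor: float = 1.0

    _TOP_KEYS = {
        "pipeline", "inputs", "out_dir", "scale", "seed", "verbosity",
        "detection", "accumulation", "roi", "bands", "tree",
        "depth_um", "dilution_factor",
    }

    @classmethod
    def from_layers(cls, *layers: dict) -> "RunConfig":
        """Merge config dicts (later layers win) and validate all keys."""
        merged: dict[str, Any] = {}
        for layer in layers:
            for k, v in layer.items():
                if v is None:
                    continue
                if isinstance(v, dict) and isinstance(merged.get(k), dict):
                    merged[k] = {**merged[k], **v}
                else:
                    merged[k] = v
        unknown = set(merged) - cls._TOP_KEYS
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if isinstance(merged.get("detection"), dict):
            merged["detection"] = _build(DetectionParams, merged["detection"], "detection")
        if isinstance(merged.get("accumulation"), dict):
            merged["accumulation"] = _build(
                AccumulationParams, merged["accumulation"], "accumulation"
            )
        if isinstance(merged.get("bands"), dict):
            merged["bands"] = _build(HueBands, merged["bands"], "bands")
        if isinstance(merged.get("tree"), dict):
            merged["tree"] = _build(TreeParams, merged["tree"], "tree")
        if merged.get("roi") is not None:
            merged["roi"] = tuple(float(v) for v in merged["roi"])
        return cls(**merged)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    def write_resolved(self, out_dir: Path) -> Path:
        """Write the resolved config next to the run's outputs."""
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "resolved_config.json"
        path.write_text(json.dumps(self.to_dict(), indent=2, default=str))
        return path


def read_image(path: str | Path, scale: float, frame_index: int = 0) -> FieldFrame:
    """Read a TIFF/PNG still into a FieldFrame (RGBA is reduced to RGB)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"input image not found: {path}")
    px = np.asarray(iio.imread(path))
    if px.ndim == 3 and px.shape[2] == 4:
        px = px[:, :, :3]
    return FieldFrame(px, scale, frame_index)


def write_image(path: str | Path, pixels: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    iio.imwrite(path, np.asarray(pixels).astype(np.uint8))


def read_video(path: str | Path, scale: float) -> list[FieldFrame]:
    """Read a video as FieldFrames, in order.

    A directory is treated as a numbered frame sequence (PNG/TIFF, sorted
    by filename). An AVI file is attempted through imageio; without an
    ffmpeg backend this raises an error advising the frame-directory
    fallback.
    """
    path = Path(path)
    if path.is_dir():
        files = sorted(
            p for p in path.iterdir() if p.suffix.lower() in FRAME_EXTENSIONS
        )
        if not files:
            raise FileNotFoundError(f"no frame images (PNG/TIFF) in directory: {path}")
        return [read_image(p, scale, i) for i, p in enumerate(files)]
    if not path.exists():
        raise FileNotFoundError(f"input video not found: {path}")
    try:
        frames = iio.imread(path, index=None)
    except Exception as exc:  # codec/backend missing
        raise RuntimeError(
            f"cannot decode {path} (no ffmpeg backend available?); "
            "export the video as a directory of numbered PNG frames and pass "
            "that directory instead"
        ) from exc
    out = []
    for i, fr in enumerate(np.asarray(frames)):
        fr = np.asarray(fr)
        if fr.ndim == 3 and fr.shape[2] == 4:
            fr = fr[:, :, :3]
        out.append(FieldFrame(fr, scale, i))
    return out


def write_frames(out_dir: str | Path, frames: Sequence[np.ndarray], stem: str = "frame") -> list[Path]:
    """Write a frame sequence as numbered PNGs; returns the paths."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, fr in enumerate(frames):
        p = out_dir / f"{stem}_{i:05d}.png"
        write_image(p, fr)
        paths.append(p)
    return paths
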