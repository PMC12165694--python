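"""File I/O: TIFF stacks, trace/metric CSVs, and run manifests."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .behavior import PercentTrace
from .video import AreaTrace, FrameStack, MobilityTrace

__all__ = [
    "read_stack",
    "write_stack",
    "write_trace_csv",
    "read_trace_csv",
    "write_manifest",
]


def read_stack(path, frame_interval: float, origin: str = "") -> FrameStack:
    """Read a multi-page TIFF, or a directory of image files in sorted order."""
    path = Path(path)
    if path.is_dir():
        files = sorted(p for p in path.iterdir()
                       if p.suffix.lower() in {".tif", ".tiff", ".png", ".jpg", ".jpeg"})
        if not files:
            raise FileNotFoundError(f"no image files in {path}")
        frames = np.stack([tifffile.imread(f) if f.suffix.lower() in {".tif", ".tiff"}
                           else _read_plain(f) for f in files])
    else:
        frames = tifffile.imread(path)
        if frames.ndim == 2:
            frames = frames[None]
    return FrameStack(frames=frames, frame_interval=frame_interval,
                      origin=origin or str(path))


def _read_plain(path):
    from imageio import v3 as iio  # optional path; only hit for PNG/JPEG input

    img = iio.imread(path)
    if img.ndim == 3:
        img = img.mean(axis=2)
    return img


def write_stack(path, stack_or_array, dtype=None) -> None:
    frames = getattr(stack_or_array, "frames", stack_or_array)
    frames = np.asarray(frames)
    if dtype is not None:
        frames = frames.astype(dtype)
    tifffile.imwrite(path, frames)


def write_trace_csv(path, trace) -> None:
    """Tidy trace CSV: frame, t_s, value, valid."""
    if isinstance(trace, AreaTrace):
        value = trace.area
    elif isinstance(trace, MobilityTrace):
        value = trace.raw_mobility
    elif isinstance(trace, PercentTrace):
        value = trace.pct
    else:
        raise TypeError(f"cannot serialise {type(trace).__name__}")
    pd.DataFrame({
        "frame": np.arange(len(trace.t)),
        "t_s": trace.t,
        "value": value,
        "valid": trace.valid.astype(bool),
    }).to_csv(path, index=False)


def read_trace_csv(path, kind: str = "area"):
    df = pd.read_csv(path)
    t = df["t_s"].to_numpy(float)
    v = df["value"].to_numpy(float)
    valid = df["valid"].to_numpy(bool)
    if kind == "area":
        return AreaTrace(t=t, area=v, valid=valid)
    if kind == "mobility":
        return MobilityTrace(t=t, raw_mobility=v, valid=valid)
    if kind == "percent":
        return PercentTrace(t=t, pct=v, valid=valid)
    raise ValueError("kind must be 'area', 'mobility' or 'percent'")


def write_manifest(path, config, extra: dict | None = None) -> None:
    """Run manifest: config hash + full config + free-form extras."""
    doc = {"config_hash": config.config_hash(), "config": config.model_dump()}
    if extra:
        doc.update(extra)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True, default=str))
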