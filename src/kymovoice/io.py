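"""Readers and writers for the pipeline's file formats.

Conventions: CSV is comma-separated UTF-8 with a mandatory header row and
dot decimals; floats are written with fixed precision so reruns are
byte-identical. Frame stacks are multi-page grayscale TIFF; kymograms
single-page TIFF or PNG.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .kymography import FrameStack, GWWSignal, KymogramImage

FLOAT_FMT = "%.6f"


def write_gww_csv(gww: GWWSignal, path) -> None:
    df = pd.DataFrame({
        "frame_index": np.arange(gww.width.size),
        "time_ms": gww.time_ms,
        "width_px": gww.width,
    })
    df.to_csv(path, index=False, float_format=FLOAT_FMT)


def read_gww_csv(path, fps: float | None = None, section_position: float = 0.5) -> GWWSignal:
    df = pd.read_csv(path)
    if fps is None:
        dt = np.diff(df["time_ms"].to_numpy())
        if dt.size == 0 or not np.all(dt > 0):
            raise ValueError("cannot infer fps from the time column")
        fps = 1000.0 / float(np.mean(dt))
    return GWWSignal(width=df["width_px"].to_numpy(float), fps=fps,
                     section_position=section_position)


def write_frame_stack(stack: FrameStack, path) -> None:
    data = np.clip(np.round(stack.frames), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, metadata={"fps": stack.fps})


def read_frame_stack(path, fps: float | None = None) -> FrameStack:
    with tifffile.TiffFile(path) as tf:
        data = tf.asarray()
        if fps is None:
            meta = tf.shaped_metadata or tf.imagej_metadata or {}
            if isinstance(meta, (list, tuple)):
                meta = meta[0] if meta else {}
            fps = float(meta.get("fps", 0)) or None
    if fps is None:
        raise ValueError("fps not stored in the TIFF; pass it explicitly")
    return FrameStack(frames=data.astype(float), fps=fps)


def write_kymogram(kymogram: KymogramImage, path) -> None:
    data = np.clip(np.round(kymogram.matrix), 0, 255).astype(np.uint8)
    tifffile.imwrite(path, data, metadata={
        "fps": kymogram.fps, "section_position": kymogram.section_position,
    })


def read_kymogram(path, fps: float, section_position: float = 0.5) -> KymogramImage:
    return KymogramImage(matrix=tifffile.imread(path).astype(float),
                         fps=fps, section_position=section_position)


def write_features_csv(features: pd.DataFrame, path) -> None:
    features.to_csv(path, index=False, float_format=FLOAT_FMT)


def config_hash(config: dict) -> str:
    """Stable short hash of a configuration mapping."""
    canon = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_manifest(path: Path, config: dict, extra: dict | None = None) -> dict:
    from . import __version__

    manifest = {
        "config": config,
        "config_hash": config_hash(config),
        "version": __version__,
    }
    if extra:
        manifest.update(extra)
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
    return manifest
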