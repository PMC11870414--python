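"""Reading and writing of images, masks, configs and result tables.

Images travel as single- or multi-page TIFF (one page per channel or
frame) with the pixel size stored in the ImageDescription tag as JSON;
label masks are written as 16-bit TIFF.  Configs are YAML (JSON accepted);
tables are CSV with fixed float formatting so reruns are byte-identical.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile
import yaml

from .core import Image2D, LabelMask, ParameterError

FLOAT_FORMAT = "%.6g"


def save_channels_tiff(path, channels: dict) -> None:
    """Write channels as a multi-page TIFF with a JSON description."""
    names = sorted(channels)
    stack = np.stack([channels[n].pixels for n in names]).astype(np.float32)
    meta = {"channels": names, "pixel_size_um": channels[names[0]].pixel_size}
    tifffile.imwrite(str(path), stack, photometric="minisblack", description=json.dumps(meta))


def load_channels_tiff(path) -> dict:
    """Inverse of :func:`save_channels_tiff`."""
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    meta = json.loads(desc)
    names = meta["channels"]
    px = float(meta["pixel_size_um"])
    if stack.ndim == 2:
        stack = stack[None]
    if len(names) != stack.shape[0]:
        raise ParameterError(f"TIFF has {stack.shape[0]} pages but {len(names)} channel names")
    return {
        n: Image2D(stack[i].astype(np.float64), pixel_size=px, channel=n)
        for i, n in enumerate(names)
    }


def save_frames_tiff(path, frames) -> None:
    stack = np.stack([f.pixels for f in frames]).astype(np.float32)
    meta = {"n_frames": len(frames), "pixel_size_um": frames[0].pixel_size}
    tifffile.imwrite(str(path), stack, photometric="minisblack", description=json.dumps(meta))


def load_frames_tiff(path, channel: str = "") -> list:
    with tifffile.TiffFile(str(path)) as tf:
        stack = tf.asarray()
        desc = tf.pages[0].description
    px = float(json.loads(desc)["pixel_size_um"])
    if stack.ndim == 2:
        stack = stack[None]
    return [Image2D(fr.astype(np.float64), pixel_size=px, channel=channel) for fr in stack]


def save_label_tiff(path, mask: LabelMask) -> None:
    if mask.labels.max() > np.iinfo(np.uint16).max:
        raise ParameterError("more than 65535 labels; cannot store as 16-bit TIFF")
    tifffile.imwrite(
        str(path),
        mask.labels.astype(np.uint16),
        description=json.dumps({"pixel_size_um": mask.pixel_size}),
    )


def load_config(path) -> dict:
    """Load a YAML (or JSON — YAML is a superset) config file to a dict."""
    text = Path(path).read_text()
    cfg = yaml.safe_load(text)
    if not isinstance(cfg, dict):
        raise ParameterError(f"config {path} must be a mapping")
    return cfg


def dump_json(path, obj) -> None:
    """Write JSON with dataclass / numpy support, deterministically ordered."""

    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=default) + "\n")


def write_table(path, df) -> None:
    df.to_csv(path, index=False, float_format=FLOAT_FORMAT)
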