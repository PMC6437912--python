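"""Readers/writers: images, 16-bit label rasters, models, configs.

Label rasters are 16-bit grayscale PNG with value 0 reserved for
boundaries/background.  Models are single versioned binary files (pickle
with a magic header); mismatched versions are refused.
"""

from __future__ import annotations

import hashlib
import pickle
from pathlib import Path

import numpy as np
import tifffile
import yaml
from PIL import Image

from .pipeline import PipelineConfig

MODEL_MAGIC = "myoseg-model"
MODEL_FORMAT_VERSION = 1

_TIFF_SUFFIXES = {".tif", ".tiff"}


def read_image(path) -> np.ndarray:
    """Read an RGB image (PNG or TIFF) as uint8 H x W x 3."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image file not found: {path}")
    if path.suffix.lower() in _TIFF_SUFFIXES:
        arr = tifffile.imread(str(path))
    else:
        arr = np.asarray(Image.open(path))
    if arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[..., :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        raise ValueError(f"{path}: unsupported bit depth {arr.dtype}, expected uint8")
    return arr


def write_image(path, image: np.ndarray) -> None:
    path = Path(path)
    image = np.asarray(image, dtype=np.uint8)
    if path.suffix.lower() in _TIFF_SUFFIXES:
        tifffile.imwrite(str(path), image)
    else:
        Image.fromarray(image, mode="RGB").save(path)


def read_labels(path) -> np.ndarray:
    """Read a 16-bit PNG label raster as int32."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"label file not found: {path}")
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: label raster must be single-channel")
    return arr.astype(np.int32)


def write_labels(path, labels: np.ndarray) -> None:
    labels = np.asarray(labels)
    if labels.min() < 0:
        raise ValueError("label values must be nonnegative")
    if labels.max() > 65535:
        raise ValueError(
            f"label raster has {int(labels.max())} ids; 16-bit PNG supports at most 65535"
        )
    Image.fromarray(labels.astype(np.uint16)).save(Path(path))


def save_model(path, obj, kind: str) -> None:
    """Serialize a model to a single versioned binary file."""
    payload = {
        "magic": MODEL_MAGIC,
        "format_version": MODEL_FORMAT_VERSION,
        "kind": kind,
        "payload": obj,
    }
    with open(path, "wb") as fh:
        pickle.dump(payload, fh, protocol=4)


def load_model(path, kind: str = None):
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"model file not found: {path}")
    try:
        with open(path, "rb") as fh:
            payload = pickle.load(fh)
    except Exception as exc:
        raise ValueError(f"{path}: corrupt or truncated model file ({exc})") from exc
    if not isinstance(payload, dict) or payload.get("magic") != MODEL_MAGIC:
        raise ValueError(f"{path}: not a myoseg model file")
    if payload.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(
            f"{path}: unsupported model format version "
            f"{payload.get('format_version')} (expected {MODEL_FORMAT_VERSION})"
        )
    if kind is not None and payload.get("kind") != kind:
        raise ValueError(
            f"{path}: expected a '{kind}' model, found '{payload.get('kind')}'"
        )
    return payload["payload"]


def file_sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(path, config: PipelineConfig) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
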