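"""Image and manifest I/O.

All float images (phase, gradients, targets, fluorescence) are stored as
single-channel 32-bit float TIFF; binary masks as 8-bit TIFF (0/255);
holograms as float TIFF unless the optical config requests integer
quantization.  Manifests are JSON with an embedded generation-config
snapshot.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

SCHEMA_VERSION = 1


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    arr = np.asarray(image)
    if arr.dtype == bool:
        arr = (arr.astype(np.uint8)) * 255
    elif arr.dtype.kind == "f":
        arr = arr.astype(np.float32)
    tifffile.imwrite(str(path), arr, photometric="minisblack")


def read_image(path: str | Path) -> np.ndarray:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    return tifffile.imread(str(path))


def read_mask(path: str | Path) -> np.ndarray:
    return read_image(path) > 0


def write_json(path: str | Path, obj: dict) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


def read_json(path: str | Path) -> dict:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"JSON file not found: {path}")
    return json.loads(path.read_text())
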