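"""TIFF reading/writing with sidecar metadata.

Images are single-plane, single-channel grayscale TIFFs (8- or 16-bit
photon counts, promoted losslessly on read). Masks are 8-bit 0/255 TIFFs.
Each written image gets a JSON sidecar (``<name>.json``) recording pixel
size, modality, marker and any extra provenance (seed, simulation spec).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .types import ImageChannel, JunctionMask, StrandMask


def read_image(path: str | Path, pixel_size_nm: float, modality: str,
               marker: str = "") -> ImageChannel:
    """Read a single-plane grayscale TIFF as an :class:`ImageChannel`.

    8-bit images are promoted to 16-bit losslessly. Multi-channel/RGB or
    floating-point files are rejected.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = tifffile.imread(path)
    if arr.ndim != 2:
        raise ValueError(
            f"{path.name}: expected a single-plane grayscale image, got shape {arr.shape}"
        )
    if not np.issubdtype(arr.dtype, np.integer):
        raise ValueError(f"{path.name}: expected integer photon counts, got dtype {arr.dtype}")
    if arr.dtype == np.uint8:
        arr = arr.astype(np.uint16)
    return ImageChannel(pixels=arr, pixel_size_nm=pixel_size_nm,
                        modality=modality, marker=marker)


def write_image(channel: ImageChannel, path: str | Path,
                extra_meta: dict | None = None) -> Path:
    """Write photon counts as 16-bit TIFF plus a JSON metadata sidecar."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    counts = np.asarray(channel.raw_counts)
    if counts.max(initial=0) > np.iinfo(np.uint16).max:
        raise ValueError("photon counts exceed the 16-bit range")
    tifffile.imwrite(path, counts.astype(np.uint16))
    meta = {
        "pixel_size_nm": channel.pixel_size_nm,
        "modality": channel.modality,
        "marker": channel.marker,
    }
    if extra_meta:
        meta.update(extra_meta)
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(meta, indent=1))
    return path


def read_image_with_sidecar(path: str | Path) -> ImageChannel:
    """Read an image whose metadata sidecar was written by :func:`write_image`."""
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    return read_image(path, meta["pixel_size_nm"], meta["modality"],
                      meta.get("marker", ""))


def write_mask(mask: np.ndarray | JunctionMask | StrandMask, path: str | Path) -> Path:
    """Write a binary mask as an 8-bit 0/255 TIFF."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pixels = mask if isinstance(mask, np.ndarray) else mask.pixels
    tifffile.imwrite(path, np.where(np.asarray(pixels, bool), 255, 0).astype(np.uint8))
    return path


def read_mask(path: str | Path, pixel_size_nm: float,
              provenance: str = "manual") -> JunctionMask:
    """Read an 8-bit mask TIFF (any nonzero value counts as foreground)."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{Path(path).name}: mask must be single-plane, got shape {arr.shape}")
    return JunctionMask(arr > 0, pixel_size_nm, provenance=provenance)


def read_labels(path: str | Path) -> np.ndarray:
    """Read a sparse annotation TIFF (0 = unlabeled, 1 = background, 2 = strand)."""
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2 or arr.max(initial=0) > 2:
        raise ValueError(f"{Path(path).name}: labels must be 2-D with values in {{0, 1, 2}}")
    return arr.astype(np.uint8)


def write_labels(labels: np.ndarray, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, np.asarray(labels, np.uint8))
    return path
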