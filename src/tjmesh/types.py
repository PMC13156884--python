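"""Core containers shared across the pipeline.

All images are single-plane, single-channel 2-D arrays. Photon-counting
detectors yield non-negative integer counts; preprocessed images may hold
floats in [0, 1], in which case the raw counts are carried along so that
intensity statistics can always be computed on unscaled photon numbers.

Coordinate convention: 0-based, row-major (row, col), pixel-center.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

CONFOCAL = "confocal"
STED = "sted"

#: default sampling of the two modalities, nm per pixel
DEFAULT_PIXEL_SIZE_NM = {CONFOCAL: 100.0, STED: 20.0}


@dataclass
class ImageChannel:
    """One acquired (or simulated) image channel.

    Parameters
    ----------
    pixels : ndarray
        2-D array. Integer photon counts for raw images; floats in [0, 1]
        after normalization (``raw`` then holds the original counts).
    pixel_size_nm : float
        Physical pixel pitch in nanometres.
    modality : str
        ``"confocal"`` or ``"sted"``.
    marker : str
        Free-text label of the stained protein (e.g. ``"Cldn5"``).
    raw : ndarray, optional
        Original photon counts, preserved by preprocessing steps.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    modality: str
    marker: str = ""
    raw: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 2:
            raise ValueError(f"expected a 2-D single-channel image, got shape {self.pixels.shape}")
        if self.modality not in (CONFOCAL, STED):
            raise ValueError(f"modality must be 'confocal' or 'sted', got {self.modality!r}")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")
        if np.issubdtype(self.pixels.dtype, np.integer) and self.pixels.min(initial=0) < 0:
            raise ValueError("photon counts must be non-negative")

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape

    @property
    def raw_counts(self) -> np.ndarray:
        """Unnormalized photon counts (``raw`` if set, else ``pixels``)."""
        return self.pixels if self.raw is None else self.raw


@dataclass
class JunctionMask:
    """Binary junctional region of interest derived from the confocal channel.

    Restricts all STED quantification to cell-cell contact areas.
    """

    pixels: np.ndarray
    pixel_size_nm: float
    provenance: str = "otsu"  # "manual" | "otsu" | "truth"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * (self.pixel_size_nm / 1000.0) ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


@dataclass
class StrandMask:
    """Binary segmentation of tight-junction strand pixels for one channel."""

    pixels: np.ndarray
    pixel_size_nm: float
    prob_threshold: float | None = None
    min_object_px: int | None = None
    marker: str = ""

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels).astype(bool)
        if self.pixels.ndim != 2:
            raise ValueError("mask must be 2-D")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @property
    def area_px(self) -> int:
        return int(self.pixels.sum())

    @property
    def area_um2(self) -> float:
        return self.area_px * (self.pixel_size_nm / 1000.0) ** 2

    @property
    def shape(self) -> tuple[int, int]:
        return self.pixels.shape


def px_to_um2(n_px: int | float, pixel_size_nm: float) -> float:
    """Convert a pixel count to an area in square micrometres."""
    return float(n_px) * (pixel_size_nm / 1000.0) ** 2
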