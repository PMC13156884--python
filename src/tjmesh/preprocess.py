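"""Confocal mask construction and STED preprocessing.

The confocal overview delineates the junctional region; all STED
quantification is restricted to it. The mask is built by Gaussian blur
followed by a two-class Otsu threshold (the alternative order,
threshold-then-blur, is available via ``order``). STED close-ups are
prepared for segmentation by top-hat background subtraction and robust
percentile normalization; raw photon counts are always preserved for
intensity statistics.

All operations here are deterministic (no randomness anywhere).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi
from skimage.filters import threshold_otsu

from .types import CONFOCAL, ImageChannel, JunctionMask


def otsu_integer_threshold(values: np.ndarray) -> int:
    """Two-class Otsu threshold on an integer-valued sample.

    Builds the exact integer histogram and returns the threshold value t
    maximizing between-class variance for the split (<= t) vs (> t).
    Raises ``ValueError`` for a constant sample.
    """
    values = np.asarray(values).ravel()
    if values.min() == values.max():
        raise ValueError("Otsu threshold undefined for a constant image")
    counts = np.bincount(values.astype(np.int64))
    centers = np.arange(len(counts))
    return int(threshold_otsu(hist=(counts, centers)))


def make_confocal_mask(conf: ImageChannel, blur_radius_px: float = 5.0,
                       order: str = "blur_then_otsu") -> JunctionMask:
    """Junctional mask from the confocal overview.

    Default: Gaussian blur (sigma = ``blur_radius_px``), requantize to
    integer counts, then a two-class Otsu threshold on the exact integer
    histogram; foreground = pixels above the threshold. ``order =
    "otsu_then_blur"`` thresholds first and then blurs the binary mask
    (re-binarized at 0.5).
    """
    if conf.modality != CONFOCAL:
        raise ValueError(f"expected a confocal channel, got {conf.modality!r}")
    img = np.asarray(conf.raw_counts)
    if img.min() == img.max():
        raise ValueError("Otsu threshold undefined for a constant image")
    if order == "blur_then_otsu":
        blurred = img.astype(float)
        if blur_radius_px > 0:
            blurred = ndi.gaussian_filter(blurred, blur_radius_px, mode="reflect")
        blurred = np.rint(blurred).astype(np.int64)
        thr = otsu_integer_threshold(blurred)
        mask = blurred > thr
    elif order == "otsu_then_blur":
        thr = otsu_integer_threshold(img)
        mask = (img > thr).astype(float)
        if blur_radius_px > 0:
            mask = ndi.gaussian_filter(mask, blur_radius_px, mode="reflect")
        mask = mask > 0.5
    else:
        raise ValueError(f"unknown order {order!r}")
    return JunctionMask(mask, conf.pixel_size_nm, provenance="otsu")


def resample_mask_to_sted(mask: JunctionMask, sted: ImageChannel,
                          offset_px: tuple[int, int] = (0, 0)) -> JunctionMask:
    """Upsample a confocal-grid mask to the STED grid and crop to its frame.

    Nearest-neighbour upsampling by the (integer) pixel-size ratio; each
    coarse pixel becomes a ratio x ratio block, preserving area. ``offset_px``
    places the STED frame within the upsampled confocal field (STED-grid
    pixels, row/col of the STED origin).
    """
    ratio_f = mask.pixel_size_nm / sted.pixel_size_nm
    ratio = int(round(ratio_f))
    if ratio < 1 or abs(ratio_f - ratio) > 1e-9:
        raise ValueError(
            f"confocal pixel ({mask.pixel_size_nm} nm) must be an integer multiple "
            f"of the STED pixel ({sted.pixel_size_nm} nm)"
        )
    up = np.kron(mask.pixels, np.ones((ratio, ratio), dtype=bool))
    r0, c0 = offset_px
    h, w = sted.shape
    if r0 < 0 or c0 < 0 or r0 + h > up.shape[0] or c0 + w > up.shape[1]:
        raise ValueError(
            f"STED frame {sted.shape} at offset {offset_px} exceeds the "
            f"upsampled confocal field {up.shape}"
        )
    return JunctionMask(up[r0:r0 + h, c0:c0 + w], sted.pixel_size_nm,
                        provenance=mask.provenance)


def preprocess_sted(sted: ImageChannel, background_radius_px: int = 50,
                    norm: str = "percentile") -> ImageChannel:
    """Background subtraction and intensity normalization of a STED image.

    White top-hat with a square structuring element of half-size
    ``background_radius_px`` (separable, so large radii stay cheap) removes
    smooth background; ``norm="percentile"`` then rescales the 0.1-99.9
    percentile range to [0, 1] (clipped). Raw counts are preserved on the
    returned channel for photon-count statistics.
    """
    img = np.asarray(sted.raw_counts).astype(float)
    size = 2 * int(background_radius_px) + 1
    if background_radius_px > 0:
        opened = ndi.maximum_filter(ndi.minimum_filter(img, size=size), size=size)
        out = img - opened
    else:
        out = img.copy()
    if norm == "percentile":
        lo, hi = np.percentile(out, [0.1, 99.9])
        out = np.clip((out - lo) / (hi - lo), 0.0, 1.0) if hi > lo else np.zeros_like(out)
    elif norm != "none":
        raise ValueError(f"unknown norm {norm!r}")
    return ImageChannel(pixels=out, pixel_size_nm=sted.pixel_size_nm,
                        modality=sted.modality, marker=sted.marker,
                        raw=np.asarray(sted.raw_counts))
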