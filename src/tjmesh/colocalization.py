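"""Two-channel colocalization within junctional masks.

Two complementary readouts, both restricted to the junctional region:

* Pearson correlation of raw photon counts between the two STED channels,
  computed over mask pixels only;
* co-occurrence of the two segmented strand masks as Manders overlap
  fractions M1 = |A n B| / |A| and M2 = |A n B| / |B|. The headline
  value is their mean (symmetric in the channels and bounded in [0, 1]);
  intersection-over-union is reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .types import ImageChannel, JunctionMask, StrandMask


class ZeroVarianceError(ValueError):
    """Pearson correlation is undefined: a channel is constant in the mask."""


@dataclass
class ColocResult:
    pearson_r: float | None
    manders_m1: float | None
    manders_m2: float | None
    overlap_mean: float | None
    jaccard: float | None
    n_pixels: int


def pearson_within_mask(a: ImageChannel, b: ImageChannel, mask: JunctionMask) -> float:
    """Sample Pearson correlation of the two channels over mask pixels.

    Computed on raw photon counts. Raises :class:`ZeroVarianceError` when
    either channel is constant within the mask, and ``ValueError`` when
    fewer than two mask pixels are available or the grids disagree.
    """
    if a.shape != b.shape or a.shape != mask.shape:
        raise ValueError(f"grids disagree: {a.shape}, {b.shape}, mask {mask.shape}")
    sel = mask.pixels
    va = np.asarray(a.raw_counts)[sel].astype(float)
    vb = np.asarray(b.raw_counts)[sel].astype(float)
    if va.size < 2:
        raise ValueError("need at least 2 masked pixels for a correlation")
    if va.std() == 0 or vb.std() == 0:
        raise ZeroVarianceError("constant channel within the mask; Pearson undefined")
    return float(sps.pearsonr(va, vb).statistic)


def cooccurrence(mask_a: StrandMask, mask_b: StrandMask) -> ColocResult:
    """Manders overlap of two segmented strand masks.

    M1 = |A n B| / |A|, M2 = |A n B| / |B|; ``overlap_mean`` is their mean
    and ``jaccard`` the intersection over union. Raises on an empty mask,
    naming the offending channel.
    """
    if mask_a.shape != mask_b.shape:
        raise ValueError(f"mask grids disagree: {mask_a.shape} vs {mask_b.shape}")
    a = mask_a.pixels
    b = mask_b.pixels
    na, nb = int(a.sum()), int(b.sum())
    for n, name in ((na, "A"), (nb, "B")):
        if n == 0:
            raise ValueError(f"channel {name} mask is empty; co-occurrence undefined")
    inter = int((a & b).sum())
    union = int((a | b).sum())
    m1, m2 = inter / na, inter / nb
    return ColocResult(pearson_r=None, manders_m1=m1, manders_m2=m2,
                       overlap_mean=0.5 * (m1 + m2), jaccard=inter / union,
                       n_pixels=union)


def coloc_report(pairs: list[tuple], ids: list[str] | None = None) -> pd.DataFrame:
    """Batch colocalization over ROIs.

    Each item is ``(a, b, mask, mask_a, mask_b)``: the two image channels,
    the junctional mask, and the two segmented strand masks. One row per
    ROI; a failing ROI yields a flagged row (``error`` column) instead of
    aborting the batch.
    """
    if not pairs:
        raise ValueError("empty batch")
    if ids is None:
        ids = [f"roi_{i:03d}" for i in range(len(pairs))]
    rows = []
    for roi_id, (a, b, mask, mask_a, mask_b) in zip(ids, pairs):
        row: dict = {"roi": roi_id, "error": ""}
        try:
            row["pearson_r"] = pearson_within_mask(a, b, mask)
            cc = cooccurrence(mask_a, mask_b)
            row.update(manders_m1=cc.manders_m1, manders_m2=cc.manders_m2,
                       overlap_mean=cc.overlap_mean, jaccard=cc.jaccard,
                       n_pixels=cc.n_pixels)
        except (ValueError, ZeroVarianceError) as exc:
            row["error"] = str(exc)
        rows.append(row)
    return pd.DataFrame(rows)
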