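"""Synthetic tight-junction meshwork generator with a forward imaging model.

Flat endothelial cells overlap at their borders, and the claudin strand
meshwork spreads within that junctional overlap zone as a network of thin,
branched strands enclosing polygonal meshes. This module builds such
geometries with known ground truth and renders them into confocal/STED
photon-count image pairs, so that every downstream quantification step can
be validated against the generating parameters.

Geometry model
--------------
Cell layout is a Voronoi tessellation of random seed points. Each Voronoi
border carries a junctional ribbon of configurable width; the two ribbon
edges are the primary strands contributed by the adjacent cells, and the
ribbon is subdivided by transverse rungs and longitudinal separators into
closed meshes whose equivalent-circle diameters are sampled from a
configurable range (log-uniform; the empirical range for brain endothelial
meshworks is roughly 125-1000 nm). Strands are rasterized 1 px wide on a
20 nm grid: real strands are ~10 nm wide by freeze-fracture EM, so one
raster pixel is the closest representation.

Imaging model
-------------
Rendering order is fixed: intensity scaling -> Gaussian PSF convolution ->
block-sum downsampling to the detector grid -> constant background ->
Poisson photon sampling. Confocal and STED differ only in PSF width and
pixel pitch (defaults 250 nm / 100 nm per px and 100 nm / 20 nm per px).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage as ndi
from scipy.spatial import Voronoi
from skimage.draw import line as draw_line
from skimage.measure import label as cc_label
from skimage.morphology import dilation, disk

from .types import CONFOCAL, STED, ImageChannel

__all__ = [
    "MeshworkSpec",
    "OpticsSpec",
    "SyntheticTruth",
    "generate_geometry",
    "insert_gaps",
    "split_channels",
    "render_channel",
    "apparent_strand_mask",
    "simulate_image_pair",
]

FWHM_TO_SIGMA = 1.0 / (2.0 * math.sqrt(2.0 * math.log(2.0)))


@dataclass(frozen=True)
class MeshworkSpec:
    """Parameters of one synthetic ground-truth meshwork.

    ``field_size_px`` is on the truth grid (``pixel_size_nm`` per px, STED
    sampling by default). ``overlap_width_nm`` is the full width of the
    junctional ribbon along each cell border. ``mesh_diameter_range_nm``
    bounds the equivalent-circle diameters of the generated meshes;
    diameters are drawn log-uniformly in that range. ``gap_fraction`` is
    the fraction of strand pixels removed as discontinuities, in runs whose
    lengths are drawn log-uniformly from ``gap_length_nm``.
    ``coloc_fraction`` is the probability that a strand pixel carries both
    markers when the mask is split into two channels.
    """

    field_size_px: tuple[int, int] = (320, 320)
    pixel_size_nm: float = 20.0
    n_cells: int = 4
    overlap_width_nm: float = 500.0
    mesh_diameter_range_nm: tuple[float, float] = (125.0, 1000.0)
    strand_width_px: int = 1
    gap_fraction: float = 0.0
    gap_length_nm: tuple[float, float] = (100.0, 400.0)
    coloc_fraction: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mesh_diameter_range_nm
        if not (0 < lo <= hi):
            raise ValueError("mesh_diameter_range_nm must satisfy 0 < low <= high")
        if not 0.0 <= self.gap_fraction <= 1.0:
            raise ValueError("gap_fraction must lie in [0, 1]")
        if not 0.0 <= self.coloc_fraction <= 1.0:
            raise ValueError("coloc_fraction must lie in [0, 1]")
        if self.n_cells < 2:
            raise ValueError("need at least 2 cells to form a junction")
        if self.pixel_size_nm <= 0 or self.overlap_width_nm <= 0:
            raise ValueError("pixel_size_nm and overlap_width_nm must be positive")
        if self.strand_width_px < 1:
            raise ValueError("strand_width_px must be >= 1")


@dataclass(frozen=True)
class OpticsSpec:
    """Forward imaging model parameters for one rendered channel."""

    psf_fwhm_nm: float = 100.0
    photons_per_strand_px: float = 50.0
    background_photons_per_px: float = 1.0
    pixel_size_nm: float = 20.0
    modality: str = STED
    poisson: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.psf_fwhm_nm < 0:
            raise ValueError("psf_fwhm_nm must be >= 0")
        if self.photons_per_strand_px <= 0:
            raise ValueError("photons_per_strand_px must be positive")
        if self.background_photons_per_px < 0:
            raise ValueError("background_photons_per_px must be >= 0")
        if self.pixel_size_nm <= 0:
            raise ValueError("pixel_size_nm must be positive")

    @staticmethod
    def sted_default(**kw) -> "OpticsSpec":
        return OpticsSpec(psf_fwhm_nm=100.0, pixel_size_nm=20.0, modality=STED, **kw)

    @staticmethod
    def confocal_default(**kw) -> "OpticsSpec":
        return OpticsSpec(psf_fwhm_nm=250.0, pixel_size_nm=100.0, modality=CONFOCAL, **kw)


@dataclass
class SyntheticTruth:
    """Ground-truth strand geometry plus the parameters that generated it.

    ``strand_mask`` is the union meshwork; ``channel_masks`` (set by
    :func:`split_channels`) maps channel names to per-channel truth masks
    whose union equals ``strand_mask``. ``gaps`` records inserted
    discontinuities as ``(row, col, length_nm)``.
    """

    strand_mask: np.ndarray
    junction_band: np.ndarray
    spec: MeshworkSpec
    channel_masks: dict[str, np.ndarray] | None = None
    gaps: list[tuple[int, int, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.strand_mask = np.asarray(self.strand_mask, bool)
        self.junction_band = np.asarray(self.junction_band, bool)
        if self.strand_mask.shape != self.junction_band.shape:
            raise ValueError("strand mask and junction band must share a grid")
        if np.any(self.strand_mask & ~self.junction_band):
            raise ValueError("strand mask must be contained in the junction band")

    @property
    def pixel_size_nm(self) -> float:
        return self.spec.pixel_size_nm

    def truth_metrics(self, min_mesh_px: int = 25):
        """Morphometry of the truth mask itself (no imaging, no noise)."""
        from .morphometry import MorphometryConfig, analyze_roi
        from .types import JunctionMask, StrandMask

        return analyze_roi(
            sted=None,
            conf_mask=JunctionMask(self.junction_band, self.pixel_size_nm, provenance="truth"),
            strand_mask=StrandMask(self.strand_mask, self.pixel_size_nm),
            config=MorphometryConfig(min_mesh_px=min_mesh_px),
        )


def _log_uniform(rng: np.random.Generator, lo: float, hi: float) -> float:
    if hi <= lo:
        return lo
    return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))


def _seed_points(rng: np.random.Generator, shape: tuple[int, int], n: int) -> np.ndarray:
    """Random cell centres with a minimum-spacing rejection rule."""
    h, w = shape
    min_d = 0.45 * math.sqrt(h * w / n)
    pts: list[np.ndarray] = []
    for _ in range(n * 300):
        cand = rng.uniform((0.1 * h, 0.1 * w), (0.9 * h, 0.9 * w))
        if all(np.hypot(*(cand - p)) >= min_d for p in pts):
            pts.append(cand)
            if len(pts) == n:
                break
    while len(pts) < n:  # fall back to unconstrained placement
        pts.append(rng.uniform((0.1 * h, 0.1 * w), (0.9 * h, 0.9 * w)))
    return np.array(pts)


def _clip_segment(p0, p1, shape, margin: float = 1.0):
    """Liang-Barsky clip of segment p0->p1 to the field rectangle."""
    h, w = shape
    lo = np.array([margin, margin])
    hi = np.array([h - 1 - margin, w - 1 - margin])
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for ax in range(2):
        if abs(d[ax]) < 1e-12:
            if p0[ax] < lo[ax] or p0[ax] > hi[ax]:
                return None
            continue
        ta = (lo[ax] - p0[ax]) / d[ax]
        tb = (hi[ax] - p0[ax]) / d[ax]
        ta, tb = min(ta, tb), max(ta, tb)
        t0, t1 = max(t0, ta), min(t1, tb)
        if t0 > t1:
            return None
    return p0 + t0 * d, p0 + t1 * d


def _voronoi_border_segments(points: np.ndarray, shape: tuple[int, int]) -> list[tuple[np.ndarray, np.ndarray]]:
    """Finite Voronoi ridge segments between real cells, clipped to the field.

    Points are mirrored across all four field edges so every ridge between
    two real seeds has finite vertices.
    """
    h, w = shape
    n = len(points)
    mirrors = [points.copy() for _ in range(4)]
    mirrors[0][:, 0] = -points[:, 0]
    mirrors[1][:, 0] = 2 * (h - 1) - points[:, 0]
    mirrors[2][:, 1] = -points[:, 1]
    mirrors[3][:, 1] = 2 * (w - 1) - points[:, 1]
    allpts = np.vstack([points] + mirrors)
    vor = Voronoi(allpts)
    segs = []
    for (i, j), verts in zip(vor.ridge_points, vor.ridge_vertices):
        if i >= n or j >= n or -1 in verts:
            continue
        p0, p1 = vor.vertices[verts[0]], vor.vertices[verts[1]]
        clipped = _clip_segment(p0, p1, shape)
        if clipped is not None and np.hypot(*(clipped[1] - clipped[0])) >= 3.0:
            segs.append(clipped)
    return segs


def _draw(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray) -> None:
    r0, c0 = np.rint(p0).astype(int)
    r1, c1 = np.rint(p1).astype(int)
    h, w = mask.shape
    rr, cc = draw_line(r0, c0, r1, c1)
    keep = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
    mask[rr[keep], cc[keep]] = True


def _ribbon(mask: np.ndarray, p0: np.ndarray, p1: np.ndarray, spec: MeshworkSpec,
            rng: np.random.Generator) -> None:
    """Draw one junctional ribbon: edges, end caps, and mesh subdivisions."""
    px = spec.pixel_size_nm
    hw = 0.5 * spec.overlap_width_nm / px
    w_px = 2.0 * hw
    d = p1 - p0
    length = float(np.hypot(*d))
    t = d / length
    nvec = np.array([-t[1], t[0]])

    def at(s: float, off: float) -> np.ndarray:
        return p0 + s * t + off * nvec

    # ribbon edges (primary strands of the two adjacent cells) and end caps
    _draw(mask, at(0, -hw), at(length, -hw))
    _draw(mask, at(0, hw), at(length, hw))
    _draw(mask, at(0, -hw), at(0, hw))
    _draw(mask, at(length, -hw), at(length, hw))

    # inner sampling margin: raster rounding jitters realized hole dimensions
    # by about one pixel, so diameters are drawn slightly inside the requested
    # bounds to keep every realized mesh within them
    lo_d, hi_d = spec.mesh_diameter_range_nm
    lo_s = min(lo_d * 1.15, 0.5 * (lo_d + hi_d))
    hi_s = max(hi_d * 0.97, lo_s)

    margin = hw  # no subdivisions near the vertices, limits sliver meshes
    s = margin
    first = True
    while s < length - margin:
        d_nm = _log_uniform(rng, lo_s, hi_s)
        area_px = math.pi * (d_nm / 2.0) ** 2 / px**2
        side = math.sqrt(area_px)
        k = max(1, round(w_px / (side + 1.0)))
        rh = w_px / k  # row pitch across the band
        col = area_px / max(rh - 1.0, 1.0) + 1.0  # column pitch along the band
        if s + col > length - margin and not first:
            break
        _draw(mask, at(s, -hw), at(s, hw))  # transverse rung
        end = min(s + col, length - margin)
        for j in range(1, k):  # longitudinal separators of this column
            off = -hw + j * rh
            _draw(mask, at(s, off), at(end, off))
        s += col
        first = False
    if s > margin and s < length - margin:
        _draw(mask, at(s, -hw), at(s, hw))


#: largest sliver hole (px) ever absorbed into the strand; keeps the fill a
#: raster-artifact cleanup and prevents solid filled patches at vertices
_SLIVER_FILL_CAP_PX = 64


def _fill_sliver_holes(strand: np.ndarray, min_area_px: float) -> None:
    """Absorb enclosed background holes below the minimum mesh area.

    Ribbon intersections near Voronoi vertices can rasterize into tiny
    enclosed slivers; these are merged into the strand so that every
    realized mesh respects the requested diameter range. The absorption is
    capped at ``_SLIVER_FILL_CAP_PX`` so that a wide requested range never
    turns whole meshes into solid patches.
    """
    min_area_px = min(min_area_px, _SLIVER_FILL_CAP_PX)
    bg = ~strand
    lbl = cc_label(bg, connectivity=1)
    border = np.unique(np.concatenate([lbl[0], lbl[-1], lbl[:, 0], lbl[:, -1]]))
    counts = np.bincount(lbl.ravel())
    small = np.zeros(len(counts), bool)
    small[1:] = counts[1:] < min_area_px
    small[border] = False
    if small.any():
        strand |= small[lbl]


def generate_geometry(spec: MeshworkSpec) -> SyntheticTruth:
    """Build a ground-truth strand meshwork from a :class:`MeshworkSpec`.

    Deterministic: the same spec (including its seed) always yields
    pixel-identical masks. Raises ``ValueError`` when the field is too
    small to hold the requested band and at least one mesh.
    """
    h, w = spec.field_size_px
    px = spec.pixel_size_nm
    lo_d, _ = spec.mesh_diameter_range_nm
    if min(h, w) * px < 2.0 * (lo_d + spec.overlap_width_nm):
        raise ValueError(
            f"field of {min(h, w) * px:.0f} nm cannot hold a {spec.overlap_width_nm:.0f} nm "
            f"band with meshes of diameter >= {lo_d:.0f} nm"
        )
    rng = np.random.default_rng(spec.seed)
    points = _seed_points(rng, (h, w), spec.n_cells)
    segs = _voronoi_border_segments(points, (h, w))
    if not segs:
        raise ValueError("degenerate cell layout produced no junction borders")

    strand = np.zeros((h, w), bool)
    centers = np.zeros((h, w), bool)
    for p0, p1 in segs:
        _ribbon(strand, p0, p1, spec, rng)
        _draw(centers, p0, p1)

    hw = 0.5 * spec.overlap_width_nm / px
    band = ndi.distance_transform_edt(~centers) <= hw + 1.5
    strand &= band
    _fill_sliver_holes(strand, math.pi * (lo_d / 2.0) ** 2 / px**2)
    if spec.strand_width_px > 1:
        strand = dilation(strand, disk(spec.strand_width_px // 2))
        strand &= band

    truth = SyntheticTruth(strand, band, spec)
    if spec.gap_fraction > 0:
        truth = insert_gaps(truth, spec.gap_fraction, spec.gap_length_nm, seed=spec.seed + 1)
    return truth


def insert_gaps(truth: SyntheticTruth, gap_fraction: float,
                gap_length_nm: tuple[float, float] | None = None, *,
                seed: int = 0) -> SyntheticTruth:
    """Remove runs of strand pixels to create discontinuities.

    Gap centres are drawn uniformly over remaining strand pixels; each gap
    removes a geodesic run of pixels (breadth-first along the strand) whose
    target length is drawn log-uniformly from ``gap_length_nm``. Removal
    stops exactly when ``gap_fraction`` of the original strand pixels have
    been deleted (the final gap is truncated), so the realized removed
    fraction matches the request to within one pixel.
    """
    if not 0.0 <= gap_fraction <= 1.0:
        raise ValueError("gap_fraction must lie in [0, 1]")
    px = truth.pixel_size_nm
    lo, hi = gap_length_nm if gap_length_nm is not None else truth.spec.gap_length_nm
    if lo < px:
        raise ValueError(f"gap length {lo} nm is shorter than one pixel ({px} nm)")
    mask = truth.strand_mask.copy()
    n0 = int(mask.sum())
    gaps = list(truth.gaps)
    if gap_fraction == 0.0 or n0 == 0:
        return replace_masks(truth, mask, gaps)
    if gap_fraction == 1.0:
        return replace_masks(truth, np.zeros_like(mask), gaps)

    rng = np.random.default_rng(seed)
    target = int(round(gap_fraction * n0))
    removed = 0
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    h, w = mask.shape
    while removed < target:
        coords = np.argwhere(mask)
        if len(coords) == 0:
            break
        r0, c0 = coords[rng.integers(len(coords))]
        want = max(1, round(_log_uniform(rng, lo, hi) / px))
        want = min(want, target - removed)
        # breadth-first geodesic ball of `want` pixels along the strand
        taken = [(int(r0), int(c0))]
        seen = {taken[0]}
        qi = 0
        while len(taken) < want and qi < len(taken):
            r, c = taken[qi]
            qi += 1
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and (rr, cc) not in seen and mask[rr, cc]:
                    seen.add((rr, cc))
                    taken.append((rr, cc))
                    if len(taken) == want:
                        break
        for r, c in taken:
            mask[r, c] = False
        removed += len(taken)
        gaps.append((int(r0), int(c0), len(taken) * px))
    return replace_masks(truth, mask, gaps)


def replace_masks(truth: SyntheticTruth, new_strand: np.ndarray,
                  gaps: list[tuple[int, int, float]] | None = None) -> SyntheticTruth:
    """Copy a truth object with an updated strand mask; channel masks are
    intersected with the new strand set."""
    channels = None
    if truth.channel_masks is not None:
        channels = {k: v & new_strand for k, v in truth.channel_masks.items()}
    return SyntheticTruth(
        strand_mask=new_strand,
        junction_band=truth.junction_band.copy(),
        spec=truth.spec,
        channel_masks=channels,
        gaps=list(truth.gaps) if gaps is None else gaps,
    )


def _geodesic_blocks(mask: np.ndarray, block_px: int,
                     rng: np.random.Generator) -> list[np.ndarray]:
    """Partition strand pixels into contiguous runs of ~``block_px`` pixels
    by breadth-first growth along the mask, starting at random seeds."""
    h, w = mask.shape
    unassigned = mask.copy()
    offsets = [(-1, -1), (-1, 0), (-1, 1), (0, -1), (0, 1), (1, -1), (1, 0), (1, 1)]
    blocks = []
    while unassigned.any():
        coords = np.argwhere(unassigned)
        r0, c0 = coords[rng.integers(len(coords))]
        taken = [(int(r0), int(c0))]
        unassigned[r0, c0] = False
        qi = 0
        while len(taken) < block_px and qi < len(taken):
            r, c = taken[qi]
            qi += 1
            for dr, dc in offsets:
                rr, cc = r + dr, c + dc
                if 0 <= rr < h and 0 <= cc < w and unassigned[rr, cc]:
                    unassigned[rr, cc] = False
                    taken.append((rr, cc))
                    if len(taken) == block_px:
                        break
        blocks.append(np.array(taken))
    return blocks


def split_channels(truth: SyntheticTruth, coloc_fraction: float, *,
                   seed: int = 0, names: tuple[str, str] = ("A", "B"),
                   segment_length_nm: float | None = 160.0) -> SyntheticTruth:
    """Assign strand pixels to two marker channels.

    Each strand pixel carries both markers with probability
    ``coloc_fraction``; otherwise it belongs to one channel only, with
    equal probability. Assignment is made in contiguous strand segments of
    roughly ``segment_length_nm`` (proteins segregate in stretches of
    strand, not pixel by pixel, and sub-pixel salt-and-pepper mixing would
    be unresolvable once blurred by the PSF); ``segment_length_nm=None``
    assigns independently per pixel. The union of the two channel masks
    always equals the input strand mask.
    """
    if not 0.0 <= coloc_fraction <= 1.0:
        raise ValueError("coloc_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    shape = truth.strand_mask.shape
    mask_a = np.zeros(shape, bool)
    mask_b = np.zeros(shape, bool)

    if segment_length_nm is None:
        units = [idx for idx in np.argwhere(truth.strand_mask)[:, None]]
    else:
        block_px = max(1, round(segment_length_nm / truth.pixel_size_nm))
        units = _geodesic_blocks(truth.strand_mask, block_px, rng)
    u = rng.random(len(units))
    for unit, x in zip(units, u):
        rows, cols = unit[:, 0], unit[:, 1]
        if x < coloc_fraction:
            mask_a[rows, cols] = True
            mask_b[rows, cols] = True
        elif x < coloc_fraction + (1.0 - coloc_fraction) / 2.0:
            mask_a[rows, cols] = True
        else:
            mask_b[rows, cols] = True
    out = replace_masks(truth, truth.strand_mask.copy())
    out.channel_masks = {names[0]: mask_a, names[1]: mask_b}
    return out


def render_channel(truth_mask: np.ndarray, optics: OpticsSpec, *,
                   truth_pixel_size_nm: float = 20.0, marker: str = "") -> ImageChannel:
    """Render a binary truth mask into a photon-count image.

    Fixed order: scale to ``photons_per_strand_px`` -> Gaussian PSF blur ->
    block-sum downsampling to the detector pixel pitch -> add background ->
    Poisson sampling (skipped when ``optics.poisson`` is false, in which
    case the expectation image is rounded). Output counts are non-negative
    integers; same inputs and seed give identical images.
    """
    truth_mask = np.asarray(truth_mask)
    ratio_f = optics.pixel_size_nm / truth_pixel_size_nm
    ratio = int(round(ratio_f))
    if ratio < 1 or abs(ratio_f - ratio) > 1e-9:
        raise ValueError(
            f"detector pixel ({optics.pixel_size_nm} nm) must be an integer multiple "
            f"of the truth grid ({truth_pixel_size_nm} nm)"
        )
    h, w = truth_mask.shape
    if h % ratio or w % ratio:
        raise ValueError(f"field {truth_mask.shape} not divisible by resampling ratio {ratio}")
    img = truth_mask.astype(float) * optics.photons_per_strand_px
    if optics.psf_fwhm_nm > 0:
        sigma = optics.psf_fwhm_nm * FWHM_TO_SIGMA / truth_pixel_size_nm
        img = ndi.gaussian_filter(img, sigma, mode="constant", truncate=6.0)
    if ratio > 1:
        img = img.reshape(h // ratio, ratio, w // ratio, ratio).sum(axis=(1, 3))
    img = img + optics.background_photons_per_px
    if optics.poisson:
        img = np.random.default_rng(optics.seed).poisson(img)
    else:
        img = np.rint(img)
    return ImageChannel(
        pixels=np.maximum(img, 0).astype(np.int64),
        pixel_size_nm=optics.pixel_size_nm,
        modality=optics.modality,
        marker=marker,
    )


def apparent_strand_mask(truth_mask: np.ndarray, optics: OpticsSpec, *,
                         truth_pixel_size_nm: float = 20.0) -> np.ndarray:
    """PSF-matched dilation of the 1-px truth to the apparent strand width.

    The optical image of a thin strand is a ridge of FWHM
    sqrt(psf_fwhm^2 + width^2); a faithful segmentation recovers pixels of
    that apparent ridge, not the sub-resolution fluorophore line. This is
    the reference mask for segmentation-quality scoring.
    """
    apparent = math.hypot(optics.psf_fwhm_nm, truth_pixel_size_nm)
    radius = max(1, round(0.5 * apparent / truth_pixel_size_nm - 0.5))
    return dilation(np.asarray(truth_mask, bool), disk(radius))


def simulate_image_pair(spec: MeshworkSpec,
                        sted_optics: OpticsSpec | None = None,
                        confocal_optics: OpticsSpec | None = None,
                        ) -> tuple[SyntheticTruth, ImageChannel, ImageChannel]:
    """Generate geometry and render the matching confocal/STED image pair."""
    truth = generate_geometry(spec)
    if sted_optics is None:
        sted_optics = OpticsSpec.sted_default(seed=spec.seed + 101)
    if confocal_optics is None:
        confocal_optics = OpticsSpec.confocal_default(seed=spec.seed + 102)
    sted = render_channel(truth.strand_mask, sted_optics,
                          truth_pixel_size_nm=spec.pixel_size_nm)
    conf = render_channel(truth.strand_mask, confocal_optics,
                          truth_pixel_size_nm=spec.pixel_size_nm)
    return truth, conf, sted
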