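# Methods

`tjmesh` quantifies the nanoscale organisation of tight-junction (TJ)
strand meshworks from paired confocal/STED images and validates every
stage against a synthetic ground-truth simulator. This note records the
models, the parameters that matter, the numerical choices, and what the
synthetic validation does and does not establish.

## The measurement problem

Claudin strands are ~10 nm wide polymers forming branched, polygonal
meshworks in the plane of the junctional membrane overlap between flat
endothelial cells. Confocal microscopy (~250 nm lateral resolution,
100 nm/px here) resolves the junction as a band; STED (~50–100 nm,
20 nm/px) resolves individual strands and meshes. Quantification is
always restricted to the junctional region defined by the confocal
channel, because outside it the STED channel contains only background
and non-junctional signal.

## Pipeline

1. **Confocal mask** — Gaussian blur (sigma = 5 px by default) then a
   two-class Otsu threshold. The threshold is computed on the exact
   integer histogram of the (requantized) blurred image, so it is
   invariant under integer intensity rescaling and reproducible to the
   bin. The alternative order (threshold, then blur the binary mask) is
   available via `order="otsu_then_blur"`; we default to blur-first
   because thresholding a smoothed image yields a connected junction
   band rather than speckle. Whether the historical "radius of 5 pixels"
   maps to a Gaussian sigma or a kernel radius is ambiguous; we expose
   it as sigma.
2. **Mask transfer** — nearest-neighbour upsampling by the (integer)
   confocal/STED pixel ratio (default 5), preserving area exactly.
3. **STED preprocessing** — white top-hat background subtraction with a
   separable square structuring element (half-size 50 px ≈ 1 µm at
   20 nm/px; separability keeps large radii cheap), then robust
   rescaling of the 0.1–99.9 percentile range to [0, 1]. Raw photon
   counts are carried on the image object; intensity statistics always
   use them, never normalized values.
4. **Segmentation** — two-class random-forest pixel classification
   (100 trees, unlimited depth, fixed seed). Features per pixel: at each
   sigma in {0.3, 0.7, 1.0, 1.6, 3.5} px, Gaussian-smoothed intensity,
   gradient magnitude, Laplacian-of-Gaussian, the larger
   structure-tensor eigenvalue and both Hessian eigenvalues (30
   features). Probability maps are thresholded at 0.5 and objects
   smaller than 4 px removed. A classifier-free Otsu fallback
   (`threshold_segment`) serves for bootstrapping annotations and for
   fast deterministic studies.
5. **Colocalization** — Pearson correlation of raw counts over the
   junction mask, and Manders overlap fractions M1 = |A∩B|/|A|,
   M2 = |A∩B|/|B| of the two segmented strand masks. The headline value
   is their mean (symmetric, bounded); intersection-over-union is
   reported alongside because the two answer slightly different
   questions (per-channel co-occupancy vs. shared fraction).
6. **Morphometry** — see below.
7. **Statistics** — normality-driven test selection with Holm
   correction, and blank-corrected TEER (Ω·cm², membrane area
   0.336 cm²).

## Morphometric descriptors

* **Fragmentation / continuity.** Connected components of the strand
  mask (8-connectivity). Fragmentation = object count / total strand
  area (µm²); continuity = its exact reciprocal, the mean object size.
  Both µm² and px² are reported.
* **Meshes.** Background holes of the strand network: 4-connected
  background components (the dual of 8-connected foreground) that do not
  touch the frame border, are at least 25 px (0.01 µm² at 20 nm/px), and
  lie at least 50% inside the junction region — the last rule excludes
  enclosed cell interiors, which are holes of the border network but not
  meshes of it. Circularity is 4πA/P² with a Crofton perimeter estimate:
  chain-length perimeters understate small digitized shapes enough to
  push circularity to ~1.2, while Crofton keeps all shapes ≤ ~1.
  `mesh_measure_on="skeleton"` measures hole areas on the skeletonized
  mask instead; for PSF-broadened segmentations this removes the
  apparent-wall-width bias (about −20% on 400-nm meshes at a 100-nm PSF)
  and matches quantification on skeletonized images.
* **Skeleton.** Topology-preserving thinning; skeleton pixels with ≥ 3
  neighbours are junction pixels, 8-adjacent junction pixels merge into
  one junction node (unmerged clusters would inflate counts), pixels
  with one neighbour are endpoints. Branches are node-to-node paths;
  diagonal steps count √2 px; branches shorter than 3 px are pruned from
  the reported lists. Tortuosity = geodesic length / Euclidean endpoint
  distance (≥ 1); cycles and branches returning to the same junction are
  excluded from tortuosity. The traversal is verified against an
  independent adjacency-graph oracle.
* **Gaps / discontinuity.** Along the medial axis of the junction band,
  a position is uncovered when no strand pixel lies within the local
  half band width; maximal uncovered runs, corrected for that coverage
  radius, are gap lengths. Gaps longer than 100 nm (more than five
  20-nm pixels) count as discontinuities; a meshwork with more than
  0.5 such gaps per µm of junction path (our operationalization of
  "frequent", configurable) is classified discontinuous. Note the
  coverage rule ties detectability to band width: on a 500-nm band only
  gaps clearing both band edges are visible.
* **Strand width.** At every 10th skeleton pixel, a bilinear profile is
  sampled perpendicular to the local skeleton direction (PCA of a 5×5
  skeleton neighbourhood), ±10 px in 0.5-px steps. FWHM is interpolated
  at half of (peak − background), background = median of the outer
  profile samples; profiles that never cross half-maximum on both sides
  are discarded. Mean, SD and 25th percentile are reported in nm.
* **Intensity.** Sum of raw photon counts in the confocal mask divided
  by the mask area (photons/µm²) — photon-counting detectors make raw
  sums meaningful, and normalizing removes the dependence on mask size.
* **Area ratio.** |strand ∩ junction| / |junction|.

## Synthetic ground truth

The generator emulates the geometry the pipeline is built for, with
every parameter known:

* **Cell layout**: Voronoi tessellation of minimum-spacing random seeds
  (default 4 cells on a 320×320 px field at 20 nm/px, i.e. 6.4 µm).
  Borders are clipped to the field (Liang–Barsky).
* **Junctional ribbon**: 500 nm wide along each border (a plausible
  overlap-zone width for flat endothelial cells). Ribbon edges are the
  strand pair contributed by the adjacent cells; transverse rungs and
  longitudinal separators subdivide the ribbon into closed meshes.
* **Mesh sizes**: equivalent-circle diameters drawn log-uniformly from
  125–1000 nm by default (the empirically observed range; no empirical
  distribution within that range is established, so log-uniform is our
  choice, flagged as such).
  Hole dimensions are designed so the *realized* (post-raster) diameters
  stay inside the requested range: diameters are sampled with an inner
  margin compensating ±1 px rounding, and residual sub-minimum sliver
  holes at ribbon intersections (≤ 64 px) are absorbed into the strand.
* **Strand width**: 1 px (20 nm) — the closest raster to the ~10 nm
  physical strand.
* **Gaps**: runs removed along the strand graph at uniformly random
  positions, lengths log-uniform in 100–400 nm by default; removal stops
  exactly at the requested pixel fraction, so the realized gap fraction
  is exact to one pixel.
* **Two channels**: strand pixels carry both markers with probability
  `coloc_fraction`, otherwise one marker, assigned in contiguous
  ~160 nm geodesic segments. Proteins segregate in stretches of strand;
  independent per-pixel assignment (available via
  `segment_length_nm=None`) produces sub-resolution salt-and-pepper that
  no optical measurement could distinguish from full colocalization.
* **Imaging**: scale to photons/strand px → isotropic Gaussian PSF
  (FWHM 250 nm confocal / 100 nm STED, chosen to bracket measurable
  strand widths) → block-sum downsampling to the detector pitch
  (100/20 nm) → constant background → Poisson sampling. The order is
  fixed so tests are stable; disabling Poisson yields the rounded
  expectation image. Photons are conserved to < 0.5% (border truncation
  and integer rounding).

**Segmentation ground truth.** The 1-px fluorophore line is not the
object a 100-nm-PSF image presents; a faithful segmentation recovers the
apparent ridge of width √(PSF² + w²). IoU scoring and training labels
therefore use the PSF-matched dilation of the truth
(`apparent_strand_mask`). Mesh/skeleton truth metrics use the 1-px truth
directly.

**What passing does and does not show.** The simulator produces
polygonal meshworks with ideal Poisson statistics, flat background, a
single isotropic PSF and no labelling artifacts. Passing recovery tests
shows the estimators are unbiased and monotone under the forward model
at realistic photon budgets (5–200 photons per strand pixel); it does
not certify performance under antibody labelling noise, uneven
illumination, detector afterpulsing, or strand geometries outside the
ribbon model (e.g. internalized claudin patches).

## Statistical decision tree

Shapiro–Wilk per group (alpha 0.05) gates the path: all-normal two-group
data go to Levene, then Student's or Welch's t; all-normal multi-group
data to pairwise t/Welch with Holm; non-normal two-group data to
Mann–Whitney (log-transformed first when raw values fail Shapiro–Wilk
but their logs pass — the transform does not change the U statistic but
is recorded); paired non-normal data to Wilcoxon signed-rank; non-normal
multi-group data to Kruskal–Wallis with Dunn's rank z-tests
(tie-corrected, implemented here and unit-tested against the direct
formula) and Holm correction. Single comparisons are reported
uncorrected. Every intermediate decision is recorded on the result.
Under a seeded two-group normal null the whole tree rejects at
0.04–0.06 over 1000 replicates.

## Problem sizes and numerical choices

Validation studies use 320×320 px STED fields (6.4 µm), 2 training +
10 test images for segmentation quality, 5 seeds per condition for
recovery and degradation studies, and 1000 replicates for the type-I
calibration; these sizes give stable medians while keeping the full
suite in a few minutes on one core. Other notable choices: forests run
single-threaded with a fixed seed; `medial_axis` tie-breaking is pinned
(it is randomized by default, which broke bit-reproducible replay);
Otsu on float images falls back to skimage's binned estimator; empty or
constant inputs raise explicit errors rather than returning NaNs.

## Known limitations

* The ribbon generator does not produce curved strands within a border
  (tortuosity of truth branches is near 1), so tortuosity is validated
  only for correctness (≥ 1, exact on constructions), not for recovery.
* Gap classification depends on band width through the coverage rule;
  cross-condition comparisons should hold the junction-band definition
  fixed.
* The Otsu fallback under-segments at low photon budgets (walls break
  and meshes leak); the forest is the supported segmenter below ~100
  photons per strand pixel.
* `run_pipeline` orchestrates simulation-driven experiments; acquired
  images are analyzed with the per-stage CLI commands or the library.
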