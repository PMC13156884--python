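# tjmesh

Quantification of tight-junction (TJ) strand meshworks in paired
confocal/STED fluorescence images, with a synthetic ground-truth
simulator for validation.

Claudin strands — the polymers forming the paracellular barrier between
endothelial and epithelial cells — are ~10 nm wide and organize into
branched, polygonal meshworks within the cell–cell overlap zone. STED
microscopy (20 nm/px) resolves individual strands and meshes; confocal
imaging (100 nm/px) resolves only the junctional band. `tjmesh`
implements the analysis chain for such image pairs:

* junctional masking from the confocal channel (Gaussian blur +
  two-class Otsu), transferred to the STED grid;
* STED preprocessing (top-hat background subtraction, robust
  percentile normalization, raw photon counts preserved);
* strand segmentation by a two-class random-forest pixel classifier on
  multi-scale features (smoothed intensity, gradient magnitude,
  Laplacian, structure-tensor and Hessian eigenvalues at sigmas
  0.3–3.5 px), with an Otsu fallback;
* colocalization: Pearson *R* of raw counts within the junction mask and
  Manders co-occurrence M1 = |A∩B|/|A|, M2 = |A∩B|/|B| of the segmented
  channel masks;
* meshwork morphometry: fragmentation = objects / area and its
  reciprocal, continuity (mean object size); counts, areas, circularity
  4πA/P² and equivalent diameters of enclosed meshes; skeleton branches,
  junctions, branch lengths and tortuosity (geodesic/Euclidean);
  discontinuity gaps (> 100 nm) along the junction path; strand width as
  cross-profile FWHM; photon count per µm² of junction;
* statistics: blank-corrected TEER, TEER = (R − R̄_blank) · 0.336 Ω·cm²,
  and a normality-driven comparison tree (Shapiro–Wilk → t/Welch,
  Mann–Whitney/Wilcoxon, or Kruskal–Wallis + Dunn, with Holm step-down
  correction).

Because no public image data accompany this kind of experiment, the
package ships a first-class simulator: Voronoi cell layouts with
junctional ribbons subdivided into meshes of controlled equivalent
diameter (default 125–1000 nm), controllable gap insertion and
two-channel colocalization, rendered through a Gaussian-PSF + Poisson
photon model at confocal and STED resolution. Every downstream stage is
validated against these known truths.

## Worked example

```python
from tjmesh import (MeshworkSpec, OpticsSpec, generate_geometry, render_channel,
                    make_confocal_mask, resample_mask_to_sted, preprocess_sted,
                    threshold_segment, analyze_roi)

# simulate a junctional region with 10% strand discontinuity ...
spec = MeshworkSpec(seed=7, gap_fraction=0.1)
truth = generate_geometry(spec)
conf = render_channel(truth.strand_mask, OpticsSpec.confocal_default(seed=8))
sted = render_channel(truth.strand_mask, OpticsSpec.sted_default(
    photons_per_strand_px=150, seed=9))

# ... and analyze it exactly like an acquired image pair
jmask = resample_mask_to_sted(make_confocal_mask(conf), sted)
pre = preprocess_sted(sted)
strands = threshold_segment(pre, jmask)
m = analyze_roi(pre, jmask, strands)

print(f"objects: {m.object_stats.n_objects}, "
      f"continuity: {m.object_stats.continuity:.3f} um^2")
print(f"meshes: {m.mesh_stats.mesh_count} "
      f"({m.mesh_stats.mesh_count_per_conf_area:.2f} per um^2 of junction)")
print(f"branches: {m.skeleton_stats.branch_count}, "
      f"junctions: {m.skeleton_stats.junction_count}")
print(f"strand FWHM: {m.width_stats.fwhm_mean_nm:.0f} "
      f"+/- {m.width_stats.fwhm_sd_nm:.0f} nm")
```

prints

```
objects: 8, continuity: 0.512 um^2
meshes: 21 (1.25 per um^2 of junction)
branches: 347, junctions: 165
strand FWHM: 94 +/- 34 nm
```

The continuity value (mean object size) is the headline integrity
readout: an intact meshwork is one large object (continuity = its total
area), while fragmentation by junction-disrupting treatments multiplies
objects and drives continuity toward single-strand fragments. The
measured FWHM reflects the apparent (PSF-broadened) strand width, not
the 20-nm simulated strand — exactly as in real STED data.

A command-line interface mirrors the stages
(`tjmesh simulate | mask | preprocess | segment-train | segment-apply |
coloc | morpho | teer | stats | pipeline`); `tjmesh pipeline --config
run.yaml --out results/` executes a configured simulate-and-analyze
experiment and writes per-ROI CSVs, group statistics and a manifest that
replays bit-identically.

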