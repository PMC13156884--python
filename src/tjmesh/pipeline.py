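"""End-to-end orchestration: simulate (or load) -> mask -> preprocess ->
segment -> colocalize -> morphometry -> statistics.

A run is described by one config mapping (usually loaded from YAML). All
randomness derives from the single top-level ``seed``, so a run can be
reproduced bit-identically from its manifest. Outputs are CSV tables, a
JSON manifest (config, config hash, library versions) and a log file.

Minimal simulation config::

    seed: 1
    simulate:
      n_rois: 5
      conditions:
        - {name: control, gap_fraction: 0.0}
        - {name: treated, gap_fraction: 0.3}
      optics: {photons_per_strand_px: 50}
    stats: {metric: continuity_um2}
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .colocalization import cooccurrence, pearson_within_mask
from .morphometry import MorphometryConfig, analyze_roi, metrics_to_row
from .preprocess import make_confocal_mask, preprocess_sted, resample_mask_to_sted
from .segmentation import threshold_segment
from .stats import select_and_run_test
from .synthetic import (MeshworkSpec, OpticsSpec, apparent_strand_mask,
                        generate_geometry, render_channel, split_channels)
from .types import JunctionMask, StrandMask

log = logging.getLogger("tjmesh")


def _config_hash(config: dict) -> str:
    blob = json.dumps(config, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _setup_logging(out_dir: Path | None) -> None:
    handlers: list[logging.Handler] = [logging.StreamHandler()]
    if out_dir is not None:
        handlers.append(logging.FileHandler(out_dir / "run.log"))
    logging.basicConfig(level=logging.INFO, handlers=handlers, force=True,
                        format="%(asctime)s %(levelname)s %(message)s")


def _iou(a: np.ndarray, b: np.ndarray) -> float:
    union = int((a | b).sum())
    return int((a & b).sum()) / union if union else 0.0


def analyze_simulated_roi(spec: MeshworkSpec, optics: OpticsSpec,
                          confocal_optics: OpticsSpec | None = None,
                          morpho: MorphometryConfig | None = None,
                          coloc_fraction: float | None = None) -> dict:
    """Simulate one ROI and push it through the full analysis pipeline.

    Returns the flattened metrics row, plus truth-comparison entries
    (segmentation IoU against the PSF-matched apparent truth, truth
    continuity and mesh stats) and, when ``coloc_fraction`` is given,
    two-channel colocalization measurements.
    """
    truth = generate_geometry(spec)
    if confocal_optics is None:
        confocal_optics = OpticsSpec.confocal_default(
            photons_per_strand_px=optics.photons_per_strand_px,
            background_photons_per_px=optics.background_photons_per_px,
            seed=spec.seed + 7)
    conf = render_channel(truth.strand_mask, confocal_optics,
                          truth_pixel_size_nm=spec.pixel_size_nm)
    conf_mask_c = make_confocal_mask(conf)

    sted = render_channel(truth.strand_mask, optics,
                          truth_pixel_size_nm=spec.pixel_size_nm)
    jmask = resample_mask_to_sted(conf_mask_c, sted)
    pre = preprocess_sted(sted)
    strand = threshold_segment(pre, jmask)
    metrics = analyze_roi(pre, jmask, strand, config=morpho)
    row = metrics_to_row(metrics)
    row["iou_vs_apparent_truth"] = _iou(
        strand.pixels, apparent_strand_mask(truth.strand_mask, optics,
                                            truth_pixel_size_nm=spec.pixel_size_nm))
    tm = truth.truth_metrics()
    row["truth_continuity_um2"] = tm.object_stats.continuity
    row["truth_mesh_count"] = tm.mesh_stats.mesh_count
    row["truth_mean_mesh_equiv_diameter_nm"] = (
        float(np.mean(tm.mesh_stats.mesh_equiv_diameter_nm))
        if tm.mesh_stats.mesh_equiv_diameter_nm else 0.0)

    if coloc_fraction is not None:
        split = split_channels(truth, coloc_fraction, seed=spec.seed + 13)
        masks = {}
        images = {}
        for shift, (name, chan_mask) in enumerate(split.channel_masks.items()):
            o = OpticsSpec(**{**asdict(optics), "seed": optics.seed + 17 + shift})
            img = render_channel(chan_mask, o, truth_pixel_size_nm=spec.pixel_size_nm,
                                 marker=name)
            images[name] = img
            masks[name] = threshold_segment(preprocess_sted(img), jmask)
        (na, a), (nb, b) = images.items()
        row["pearson_r"] = pearson_within_mask(a, b, jmask)
        cc = cooccurrence(masks[na], masks[nb])
        row.update(manders_m1=cc.manders_m1, manders_m2=cc.manders_m2,
                   overlap_mean=cc.overlap_mean, jaccard=cc.jaccard,
                   truth_coloc_fraction=coloc_fraction)
    return row


def run_pipeline(config: dict, out_dir: str | Path | None = None) -> dict:
    """Execute a configured run; see the module docstring for the schema.

    Returns a bundle with the per-ROI metrics table, the group-comparison
    result (when at least two conditions are configured) and the manifest.
    Any stage failure aborts with the condition/ROI named; rows computed
    so far are still written.
    """
    out = Path(out_dir) if out_dir is not None else None
    if out is not None:
        out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    seed = int(config.get("seed", 0))
    manifest = {
        "config": config,
        "config_hash": _config_hash(config),
        "seed": seed,
        "tjmesh_version": __version__,
    }
    sim = config.get("simulate")
    if sim is None:
        raise ValueError("only simulation-driven configs are supported by run_pipeline; "
                         "analyze acquired images via the library functions or the CLI")

    base = {k: v for k, v in sim.items()
            if k in MeshworkSpec.__dataclass_fields__ and k != "seed"}
    for key in ("field_size_px", "mesh_diameter_range_nm", "gap_length_nm"):
        if key in base:
            base[key] = tuple(base[key])
    optics_kw = dict(sim.get("optics", {}))
    coloc_fraction = sim.get("coloc_fraction")
    n_rois = int(sim.get("n_rois", 5))
    conditions = sim.get("conditions", [{"name": "default", "gap_fraction": 0.0}])
    morpho = MorphometryConfig(**config.get("morphometry", {}))

    rows = []
    for ci, cond in enumerate(conditions):
        for ri in range(n_rois):
            roi_seed = seed + 1009 * (ci * n_rois + ri)
            spec = MeshworkSpec(**{**base,
                                   "gap_fraction": float(cond.get("gap_fraction", 0.0)),
                                   "seed": roi_seed})
            optics = OpticsSpec(**{**optics_kw, "seed": roi_seed + 3})
            log.info("condition %s roi %d (seed %d)", cond.get("name", ci), ri, roi_seed)
            try:
                row = analyze_simulated_roi(
                    spec, optics, morpho=morpho,
                    coloc_fraction=cond.get("coloc_fraction", coloc_fraction))
            except Exception as exc:
                raise RuntimeError(
                    f"pipeline failed at condition {cond.get('name', ci)!r}, "
                    f"roi {ri}: {exc}") from exc
            row["roi"] = f"{cond.get('name', ci)}_{ri:03d}"
            row["condition"] = cond.get("name", str(ci))
            rows.append(row)
    metrics = pd.DataFrame(rows)

    stat_result = None
    stats_cfg = config.get("stats", {})
    metric = stats_cfg.get("metric", "continuity_um2")
    if len(conditions) >= 2 and n_rois >= 3:
        groups = {c["name"]: metrics.loc[metrics.condition == c["name"], metric].to_numpy()
                  for c in conditions}
        stat_result = select_and_run_test(groups, alpha=float(stats_cfg.get("alpha", 0.05)))
        log.info("%s on %s: raw p %s, adjusted %s", stat_result.test_used, metric,
                 stat_result.raw_p, stat_result.adjusted_p)

    if out is not None:
        metrics.to_csv(out / "metrics.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1, default=str))
        if stat_result is not None:
            (out / "stats.json").write_text(json.dumps(
                {k: v for k, v in asdict(stat_result).items()}, indent=1, default=str))
    return {"metrics": metrics, "stats": stat_result, "manifest": manifest}
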