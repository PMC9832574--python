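"""End-to-end orchestration: simulate -> segment -> measure -> classify ->
phagocytosis -> report, driven by a single JSON config.

The config has one block per stage; every stage logs its parameters and all
outputs are plain CSV so reruns with the same config and seed are
byte-identical.  Minimal example::

    {
      "seed": 1,
      "outdir": "run1",
      "simulate": {
        "image_size_px": [420, 420],
        "noise_sd": 1.0,
        "groups": [
          {"name": "control", "n_fields": 2,
           "classes": ["round", "hypertrophic", "bipolar", "fried_egg"]},
          {"name": "treated", "n_fields": 2,
           "classes": ["inflamed_ameboid", "hypertrophic", "round", "bipolar"]}
        ],
        "n_frames": 4,
        "n_particles": 3,
        "n_engulfed": 1,
        "shrink_rate": 0.2
      },
      "segment": {"min_cell_size_um2": 200},
      "classify": {"annotation_fraction": 1.0},
      "report": {"reference_group": "control"}
    }
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import classification, morphometry, phagocytosis, reporting, segmentation
from . import synthetic
from .types import DEFAULT_PIXEL_SIZE_UM

logger = logging.getLogger("microglia_morph")

__all__ = ["run_pipeline", "demo_config", "demo_field_spec", "match_to_truth"]


def demo_field_spec(classes, image_size_px=(420, 420), pixel_size_um=DEFAULT_PIXEL_SIZE_UM,
                    noise_sd: float = 1.0, seed: int = 0,
                    n_particles: int = 0, n_engulfed: int = 0) -> synthetic.FieldSpec:
    """Lay out one synthetic field: cells on a coarse grid, debris scattered.

    Cells are placed on grid nodes spaced by twice the largest cell reach so
    that they never overlap; engulfed particles sit at their host's soma
    centre, free particles fall on background between grid nodes.
    """
    rng = np.random.default_rng(seed)
    nr, nc = image_size_px
    specs = [synthetic.sample_shape_spec(c, rng) for c in classes]
    reach_px = [
        int(np.ceil((s.soma_radius_um * 1.4 + s.process_length_um
                     + s.process_width_um) / pixel_size_um)) + 2
        for s in specs
    ]
    margin = max(reach_px) + 2
    step = 2 * margin
    nodes = [(r, c)
             for r in range(margin, nr - margin + 1, step)
             for c in range(margin, nc - margin + 1, step)]
    if len(nodes) < len(specs):
        raise ValueError(
            f"image {image_size_px} fits only {len(nodes)} cells of this "
            f"size; requested {len(specs)}"
        )
    cells = tuple(
        (spec, (float(rr), float(cc)))
        for spec, (rr, cc) in zip(specs, nodes)
    )
    particles = []
    for k in range(n_engulfed):
        host = 1 + k % len(cells)
        particles.append(synthetic.ParticleSpec(
            radius_um=2.0, position=None, engulfed_by=host))
    for k in range(n_particles - n_engulfed):
        # background positions: offset from grid nodes by one margin
        base = nodes[k % len(nodes)]
        pos = (float(min(base[0] + margin, nr - 6)),
               float(min(base[1] + margin, nc - 6)))
        particles.append(synthetic.ParticleSpec(
            radius_um=2.5, position=pos, engulfed_by=None))
    return synthetic.FieldSpec(
        image_size_px=tuple(image_size_px),
        cells=cells,
        particles=tuple(particles),
        pixel_size_um=pixel_size_um,
        noise_sd=noise_sd,
        seed=int(rng.integers(0, 2 ** 31)),
    )


def match_to_truth(mask: np.ndarray, truth_mask: np.ndarray) -> dict[int, int]:
    """Map each segmented label to the truth label it overlaps most (0 if none)."""
    out = {}
    for lab in np.unique(mask):
        if lab == 0:
            continue
        under = truth_mask[mask == lab]
        vals, cnts = np.unique(under[under > 0], return_counts=True)
        out[int(lab)] = int(vals[np.argmax(cnts)]) if len(vals) else 0
    return out


def demo_config(outdir="pipeline_run", seed: int = 1) -> dict:
    """A small but complete config exercising every stage."""
    return {
        "seed": seed,
        "outdir": str(outdir),
        "pixel_size_um": DEFAULT_PIXEL_SIZE_UM,
        "simulate": {
            "image_size_px": [420, 420],
            "noise_sd": 1.0,
            "groups": [
                {"name": "control", "n_fields": 2,
                 "classes": ["round", "hypertrophic", "bipolar",
                             "fried_egg", "round", "hypertrophic",
                             "bipolar", "fried_egg"]},
                {"name": "treated", "n_fields": 2,
                 "classes": ["inflamed_ameboid", "hypertrophic",
                             "inflamed_ameboid", "round", "hypertrophic",
                             "inflamed_ameboid", "round", "bipolar"]},
            ],
            "n_frames": 4,
            "n_particles": 3,
            "n_engulfed": 1,
            "shrink_rate": 0.2,
            "motion_px_per_frame": [1.0, 0.0],
        },
        "segment": {},
        "classify": {"annotation_fraction": 1.0, "min_cluster_size": 4,
                     "n_neighbors": 8},
        "phago": {"min_shrink": 0.1, "co_move_tol_px": 3.0},
        "report": {"reference_group": "control"},
    }


def run_pipeline(config: dict | str | Path) -> dict:
    """Run every configured stage; returns the in-memory results.

    Writes ``features.csv``, ``assignments.csv``, ``composition_counts.csv``,
    ``composition_pct.csv``, ``phago_report.csv``, ``particles.csv`` and
    ``comparisons.csv`` (when two or more groups are present) under
    ``config['outdir']``.  Reruns with the same config are byte-identical.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    if "pixel_size_um" not in config:
        raise ValueError("config must state pixel_size_um before any computation")
    seed = int(config.get("seed", 0))
    px = float(config["pixel_size_um"])
    outdir = Path(config.get("outdir", "pipeline_run"))
    outdir.mkdir(parents=True, exist_ok=True)
    logger.info("pipeline start: seed=%d outdir=%s", seed, outdir)

    sim = config.get("simulate")
    if sim is None:
        raise ValueError("this runner drives the synthetic workflow; "
                         "a 'simulate' block is required")
    seg_cfg = segmentation.SegmentationConfig(
        pixel_size_um=px, **config.get("segment", {}))

    try:
        feature_rows, phago_rows, particle_rows = _simulate_and_measure(
            sim, seg_cfg, px, seed, config.get("phago", {}))
    except Exception as exc:  # noqa: BLE001 - re-raise with stage name
        raise RuntimeError(f"stage simulate/segment/measure failed: {exc}") from exc

    features = pd.concat(feature_rows, ignore_index=True)
    features["cell_uid"] = np.arange(1, len(features) + 1)
    features.to_csv(outdir / "features.csv", index=False)

    cls_cfg = dict(config.get("classify", {}))
    ann_fraction = float(cls_cfg.pop("annotation_fraction", 1.0))
    rng = np.random.default_rng(seed + 1)
    annotated = rng.random(len(features)) < ann_fraction
    annotations = features["true_class"].where(annotated)
    try:
        feat_cls = (features.drop(columns=["cell_id"])
                    .rename(columns={"cell_uid": "cell_id"}))
        assignments = classification.classify_cells(
            feat_cls, annotations, seed=seed, **cls_cfg)
    except Exception as exc:
        raise RuntimeError(f"stage classify failed: {exc}") from exc
    assignments["group"] = features["group"].to_numpy()
    assignments["true_class"] = features["true_class"].to_numpy()
    assignments.to_csv(outdir / "assignments.csv", index=False)

    try:
        counts, pct = reporting.compose(assignments)
    except Exception as exc:
        raise RuntimeError(f"stage report failed: {exc}") from exc
    counts.to_csv(outdir / "composition_counts.csv")
    pct.to_csv(outdir / "composition_pct.csv")
    comparisons = None
    ref = config.get("report", {}).get("reference_group")
    if ref is not None and len(counts) > 1:
        comparisons = reporting.compare_all_groups(counts, ref)
        comparisons.to_csv(outdir / "comparisons.csv", index=False)

    phago_df = pd.DataFrame(phago_rows)
    phago_df.to_csv(outdir / "phago_report.csv", index=False)
    particles_df = (pd.concat(particle_rows, ignore_index=True)
                    if particle_rows else pd.DataFrame())
    particles_df.to_csv(outdir / "particles.csv", index=False)
    logger.info("pipeline done: %d cells, %d groups", len(features), len(counts))
    return dict(features=features, assignments=assignments, counts=counts,
                percentages=pct, comparisons=comparisons, phago=phago_df,
                particles=particles_df)


def _simulate_and_measure(sim: dict, seg_cfg, px: float, seed: int,
                          phago_cfg: dict):
    """Render every configured field, segment, measure, run phagocytosis."""
    n_frames = int(sim.get("n_frames", 1))
    shrink = float(sim.get("shrink_rate", 0.0))
    motion_step = tuple(sim.get("motion_px_per_frame", (0.0, 0.0)))
    feature_rows, phago_rows, particle_rows = [], [], []
    field_counter = 0
    for g_idx, group in enumerate(sim["groups"]):
        for f_idx in range(int(group.get("n_fields", 1))):
            field_counter += 1
            fseed = (seed * 10007 + g_idx * 101 + f_idx) % (2 ** 31)
            spec = demo_field_spec(
                group["classes"],
                image_size_px=tuple(sim.get("image_size_px", (420, 420))),
                pixel_size_um=px,
                noise_sd=float(sim.get("noise_sd", 1.0)),
                seed=fseed,
                n_particles=int(sim.get("n_particles", 0)),
                n_engulfed=int(sim.get("n_engulfed", 0)),
            )
            if n_frames > 1:
                motion = {1: motion_step}  # cell 1 carries the moving demo
                frames = synthetic.render_timelapse(
                    spec, n_frames, motion=motion, shrink_rate=shrink)
            else:
                frames = [synthetic.render_field(spec)]

            # segmentation + tracking on the red channel
            masks = [segmentation.segment_frame(fr.field.red, seg_cfg)
                     for fr in frames]
            masks = segmentation.track(masks)

            # morphometry on the last frame (the analysis frame)
            last = frames[-1]
            feats = morphometry.measure_base(masks[-1], last.field.red, px,
                                             frame_index=n_frames - 1)
            feats = morphometry.derive_table(feats)
            feats = morphometry.filter_incomplete(feats)
            truth_of = match_to_truth(masks[-1], last.truth_mask)
            class_of = dict(zip(last.cells["cell_id"], last.cells["class_name"]))
            feats["true_class"] = [
                class_of.get(truth_of.get(int(cid), 0)) for cid in feats["cell_id"]
            ]
            feats["group"] = group["name"]
            feats["field"] = field_counter
            feature_rows.append(feats)

            # phagocytosis bookkeeping on the green channel
            if len(spec.particles):
                pmasks = [phagocytosis.auto_threshold(fr.field.green, "isodata")
                          for fr in frames]
                tracked, conf, reports = phagocytosis.analyse_timelapse(
                    masks, pmasks, px, **phago_cfg)
                tracked["group"] = group["name"]
                tracked["field"] = field_counter
                particle_rows.append(tracked)
                rep = reports[-1]
                phago_rows.append(dict(
                    group=group["name"], field=field_counter,
                    frame_index=rep.frame_index,
                    sytox_area_inside=rep.sytox_area_inside,
                    sytox_area_total=rep.sytox_area_total,
                    n_microglia=rep.n_microglia,
                    phago_index=rep.phago_index,
                    n_phagocytosing=rep.n_phagocytosing,
                    phagocytosing_pct=rep.phagocytosing_pct,
                    delta_sytox=phagocytosis.delta_sytox(
                        reports[-1].sytox_area_total,
                        reports[0].sytox_area_total),
                ))
    return feature_rows, phago_rows, particle_rows
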