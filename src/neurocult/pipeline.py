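"""End-to-end runs: simulate/mask/graph/stats and proteomics chains.

``run_connectivity`` executes enhance → segment → detect → mask → trace
→ graph → metrics over a batch of frames (simulated here, or supplied as
images) and writes per-frame metrics plus a ground-truth comparison;
``run_proteomics`` executes the filtering/imputation/normalization/DE
chain with per-step row counts.  Both are deterministic given the config
and global seed: the global seed fans out to per-stage seeds through
``numpy.random.SeedSequence([seed, stage_index])``, so any stage can be
rerun in isolation.

Every tabular output embeds a hash of the configuration and the seed;
two runs with the same config are byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import graphs, io, masking, proteomics, simulate
from .errors import ValidationError

__all__ = ["RunConfig", "RunReport", "run_connectivity", "run_proteomics",
           "analyze_frame", "stage_seed", "config_hash"]


@dataclass(frozen=True)
class RunConfig:
    """Configuration of an end-to-end run."""

    seed: int = 0
    n_frames: int = 5
    frame: simulate.FrameSimParams = field(
        default_factory=simulate.FrameSimParams)
    enhance: masking.EnhanceParams = field(
        default_factory=masking.EnhanceParams)
    masking: Optional[masking.MaskingConfig] = None
    node_mode: str = "connection"
    protein: simulate.ProteinSimParams = field(
        default_factory=simulate.ProteinSimParams)
    normalization: str = "median"
    imputation: str = "downshift"
    save_images: bool = False

    def masking_config(self) -> masking.MaskingConfig:
        if self.masking is not None:
            return self.masking
        return masking.MaskingConfig(pixel_size_um=self.frame.pixel_size_um)


@dataclass
class RunReport:
    """Machine-readable record of a run: counts, parameters, timings."""

    config_hash: str
    seed: int
    stage_counts: dict = field(default_factory=dict)
    wall_clock_s: dict = field(default_factory=dict)
    parameters: dict = field(default_factory=dict)

    def write(self, path) -> None:
        doc = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "stage_counts": self.stage_counts,
            "wall_clock_s": self.wall_clock_s,
            "parameters": self.parameters,
        }
        Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def _to_jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _to_jsonable(v)
                for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _to_jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_to_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def config_hash(config) -> str:
    """Stable short hash of a config dataclass."""
    doc = json.dumps(_to_jsonable(config), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()[:16]


def stage_seed(seed: int, stage: int) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(seed), int(stage)])
    return int(ss.generate_state(1, dtype=np.uint32)[0] & 0x7FFFFFFF)


def analyze_frame(image: np.ndarray, config: RunConfig):
    """Run the masking chain on one image; returns (detections, traces,
    metrics)."""
    mcfg = config.masking_config()
    enhanced = masking.enhance(image, config.enhance)
    fg = masking.segment_foreground(enhanced, mcfg)
    detections = masking.detect_cell_bodies(fg, enhanced, mcfg)
    dmask = masking.mask_dendrites(fg, detections, mcfg)
    traces = masking.trace_dendrites(dmask, detections, mcfg)
    metrics = graphs.metrics_from_detections(detections, traces,
                                             config.node_mode)
    return detections, traces, metrics


def run_connectivity(config: RunConfig, outdir) -> RunReport:
    """Simulate-and-analyze a batch of frames; write metrics and report.

    Writes ``frame_metrics.csv`` (measured vs ground-truth counts per
    frame), per-frame truth JSON, optionally the rendered images, and
    ``run_report.json``.  Asserts at the end that the cross-stage counts
    reconcile (graph cell count = detection count) on every frame.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    report = RunReport(config_hash=chash, seed=config.seed,
                       parameters=_to_jsonable(config))
    rows = []
    t0 = time.perf_counter()
    for i in range(config.n_frames):
        params = dataclasses.replace(config.frame,
                                     seed=stage_seed(config.seed, i))
        scene = simulate.generate_frame(params)
        truth = graphs.metrics_from_scene(scene, config.node_mode)
        detections, traces, measured = analyze_frame(scene.image, config)
        if config.save_images:
            io.write_image(scene.image, outdir / f"frame_{i:03d}.tif")
        io.write_truth(scene, outdir / f"frame_{i:03d}_truth.json")
        if sum(d.estimated_cell_count for d in detections) != \
                measured.total_cells:
            raise ValidationError("cross-stage cell counts do not reconcile")
        rows.append({
            "frame": i,
            "seed": params.seed,
            "true_cells": truth.total_cells,
            "cells": measured.total_cells,
            "true_synapses": truth.synapse_events,
            "synapses": measured.synapse_events,
            "true_networks": truth.network_count,
            "networks": measured.network_count,
            "true_nodes": truth.total_nodes,
            "nodes": measured.total_nodes,
            "synapse_frequency": measured.synapse_frequency,
            "network_frequency": measured.network_frequency,
        })
    df = pd.DataFrame(rows)
    io.write_csv(df, outdir / "frame_metrics.csv", chash, config.seed)
    report.stage_counts = {
        "frames": config.n_frames,
        "true_cells": int(df["true_cells"].sum()) if len(df) else 0,
        "detected_cells": int(df["cells"].sum()) if len(df) else 0,
        "synapse_events": int(df["synapses"].sum()) if len(df) else 0,
        "networks": int(df["networks"].sum()) if len(df) else 0,
    }
    report.wall_clock_s = {
        "connectivity": round(time.perf_counter() - t0, 3)}
    report.write(outdir / "run_report.json")
    return report


def run_proteomics(config: RunConfig, outdir,
                   table: Optional[proteomics.ProteinTable] = None
                   ) -> RunReport:
    """Run the proteomics chain; write DE/PCA/volcano tables and report.

    With no ``table`` supplied, a matrix is simulated from
    ``config.protein`` (seeded from the global seed) and the planted
    truth is written alongside.  Step row counts are logged and checked
    to be monotone under filtering.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    chash = config_hash(config)
    report = RunReport(config_hash=chash, seed=config.seed,
                       parameters=_to_jsonable(config))
    t0 = time.perf_counter()

    truth = None
    if table is None:
        params = dataclasses.replace(config.protein,
                                     seed=stage_seed(config.seed, 1000))
        table, truth = simulate.generate_protein_matrix(params)
        pd.DataFrame({
            "protein_id": list(truth.true_log2fc),
            "true_log2fc": list(truth.true_log2fc.values()),
        }).pipe(io.write_csv, outdir / "planted_truth.csv", chash, config.seed)

    counts = {"raw": len(table.protein_ids)}
    table = proteomics.filter_contaminants(table)
    counts["post_contaminant"] = len(table.protein_ids)
    table = proteomics.filter_valid(table)
    counts["post_validity"] = len(table.protein_ids)
    if not counts["raw"] >= counts["post_contaminant"] >= \
            counts["post_validity"]:
        raise ValidationError("filtering must be monotone")
    table = proteomics.impute_missing(table, method=config.imputation,
                                      seed=stage_seed(config.seed, 1001))
    table = proteomics.log2_and_normalize(table, method=config.normalization)

    groups = table.groups
    ga, gb = groups[-1], groups[0]  # treatment vs reference
    de = proteomics.differential_expression(table, ga, gb)
    counts["de_called"] = int(de["is_de"].sum())
    de_out = de.reset_index()
    io.write_csv(de_out, outdir / "de_results.csv", chash, config.seed)
    io.write_csv(proteomics.volcano_data(de).reset_index(),
                 outdir / "volcano.csv", chash, config.seed)
    scores, var_frac = proteomics.pca_scores(table)
    io.write_csv(scores.reset_index(), outdir / "pca_scores.csv",
                 chash, config.seed)
    io.write_csv(pd.DataFrame({"component": range(1, len(var_frac) + 1),
                               "variance_fraction": var_frac}),
                 outdir / "pca_variance.csv", chash, config.seed)

    report.stage_counts = counts
    report.parameters["comparison"] = f"{ga}_vs_{gb}"
    if truth is not None and not truth.spiked_ids:
        report.parameters["null_run"] = True
    report.wall_clock_s = {"proteomics": round(time.perf_counter() - t0, 3)}
    report.write(outdir / "run_report.json")
    return report
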