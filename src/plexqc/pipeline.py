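"""Pipeline orchestration: run the QC modules in order with checkpointing.

Canonical module order: selectROIs -> artifactDetect -> dnaIntensity ->
areaFilter -> cycleCorrelation -> pruneOutliers -> metaQC -> clustering ->
setContrast -> curateThumbnails. Any subset may be enabled. Each module
consumes only currently retained cells; a checkpoint is written after every
module so a run can resume at any later module; the final outputs are the
cleaned table, the redaction log and per-module reports.

Reproducibility: one global seed fans out to per-module sub-seeds by stable
hashing of the module name, so a resumed run draws exactly the randomness an
uninterrupted run would.
"""

from __future__ import annotations

import logging
import sys
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import gates
from .clustering import ClusterResult, cluster_profile, meta_cluster, run_clustering
from .config import CANONICAL_ORDER, QCConfig
from .detect import DetectionParams, detect_channel, redact_by_mask
from .errors import ConfigError, QCError
from .gallery import compute_contrast, curate_gallery
from .gates import GateInterval, PercentileCutoffs
from .metaqc import run_metaqc
from .model import (
    ArrayImageHandle,
    PipelineState,
    RedactionLog,
    SpatialFeatureTable,
    aggregate_samples,
    load_checkpoint,
    load_sample,
    save_checkpoint,
)
from .roi import apply_rois, load_rois

logger = logging.getLogger("plexqc")

__all__ = ["PipelineRun", "run_pipeline", "resume", "redaction_summary"]


@dataclass
class PipelineRun:
    """Results of a pipeline execution."""

    table: SpatialFeatureTable
    log: RedactionLog
    state: PipelineState
    cluster_result: ClusterResult | None = None
    reports: dict = field(default_factory=dict)
    outdir: Path | None = None


def _setup_logging(outdir: Path) -> None:
    logger.setLevel(logging.INFO)
    logger.handlers = [logging.StreamHandler(sys.stderr)]
    fh = logging.FileHandler(outdir / "pipeline.log", mode="a")
    logger.addHandler(fh)
    for h in logger.handlers:
        h.setFormatter(logging.Formatter("%(asctime)s %(message)s"))


def _load_all(config: QCConfig):
    tables, masks, handles, outlines = [], {}, {}, {}
    for rec in config.samples:
        table, mask, handle = load_sample(rec, config.markers)
        tables.append(table)
        masks[rec.sample_id] = mask
        handles[rec.sample_id] = handle
        if rec.outline_path is not None:
            outlines[rec.sample_id] = np.asarray(tifffile.imread(rec.outline_path))
    return aggregate_samples(tables), masks, handles, outlines


def redaction_summary(log: RedactionLog) -> pd.DataFrame:
    """Per-category redaction accounting over the original cell count.

    Categories: one row per redacting module (gross counts, including cells
    later rescued), metaQC rescues as a negative contribution, and the
    artifact-free remainder. The fractions sum to 1 exactly.
    """
    total = log.n_cells
    rows = []
    gross = log.gross_redactions_by_module()
    for module in list(CANONICAL_ORDER) + sorted(set(gross) - set(CANONICAL_ORDER)):
        if module in gross:
            rows.append({"category": module, "cells": gross[module]})
    n_rescued = log.n_rescued()
    if n_rescued:
        rows.append({"category": "metaQC rescues", "cells": -n_rescued})
    rows.append({"category": "artifact-free", "cells": len(log.retained_keys())})
    df = pd.DataFrame(rows, columns=["category", "cells"])
    df["fraction"] = df["cells"] / total if total else 0.0
    return df


def run_pipeline(config: QCConfig, outdir: Path | str) -> PipelineRun:
    """Execute the configured modules from the start."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    table, masks, handles, outlines = _load_all(config)
    log = RedactionLog.for_table(table)
    state = PipelineState(table=table, log=log, seed=config.seed)
    return _execute(config, state, masks, handles, outlines, outdir,
                    start_index=0)


def resume(config: QCConfig, outdir: Path | str, start_module: str) -> PipelineRun:
    """Resume from the checkpoint, starting at ``start_module``.

    The checkpoint must record every earlier enabled module as completed, and
    the executed modules' parameters must be unchanged.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    _setup_logging(outdir)
    if start_module not in config.modules:
        raise ConfigError(f"start module '{start_module}' not in configured modules")
    start_index = config.modules.index(start_module)
    if start_index == 0:
        return run_pipeline(config, outdir)
    needed = config.modules[:start_index]
    ckpt = outdir / "checkpoints" / f"after_{needed[-1]}.zip"
    if not ckpt.exists():
        raise ConfigError(
            f"cannot resume at '{start_module}': no checkpoint for completed "
            f"module '{needed[-1]}'"
        )
    state = load_checkpoint(ckpt, config.module_hashes())
    missing = [m for m in needed if m not in state.completed]
    if missing:
        raise ConfigError(
            f"cannot resume at '{start_module}': modules {missing} not completed "
            "in the checkpoint"
        )
    # discard completion of start_module and later (they will re-run)
    state.completed = [m for m in state.completed if m in needed]
    state.module_hashes = {m: h for m, h in state.module_hashes.items() if m in needed}
    _, masks, handles, outlines = _load_all(config)
    state.table = state.table  # table travels in the checkpoint
    return _execute(config, state, masks, handles, outlines, outdir, start_index)


def _execute(
    config: QCConfig,
    state: PipelineState,
    masks: dict,
    handles: dict,
    outlines: dict,
    outdir: Path,
    start_index: int,
) -> PipelineRun:
    table, log = state.table, state.log
    run = PipelineRun(table=table, log=log, state=state, outdir=outdir)
    rescaled_written = False
    for module in config.modules[start_index:]:
        t0 = time.time()
        n_before = len(log.retained_keys())
        p = config.module_params(module)
        mseed = config.module_seed(module)
        try:
            if module == "selectROIs":
                rois = load_rois(p["roi_file"]) if p.get("roi_file") else []
                apply_rois(table, log, rois, mode=p.get("mode", "negative"))
            elif module == "artifactDetect":
                dp = DetectionParams(
                    downsample_factor=int(p.get("downsample_factor", 4)),
                    kernel_diameter=int(p.get("kernel_diameter", 9)),
                    seed_expansion=float(p.get("seed_expansion", 2.0)),
                    tolerance=float(p.get("tolerance", 40.0)),
                    intensity_floor=int(p.get("intensity_floor", 50)),
                )
                channels = p.get("channels") or [
                    m.marker_name for m in config.markers
                ]
                name_to_meta = {m.marker_name: m for m in config.markers}
                for sid, handle in sorted(handles.items()):
                    union = np.zeros(handle.shape, dtype=bool)
                    hit_channels = []
                    for ch_name in channels:
                        meta = name_to_meta[ch_name]
                        am = detect_channel(
                            handle.channel(meta.channel_index), dp, ch_name
                        )
                        if am.area:
                            hit_channels.append(ch_name)
                        union |= am.mask
                    redact_by_mask(
                        table, log, union, sample_id=sid,
                        detail=",".join(hit_channels),
                    )
            elif module == "dnaIntensity":
                dna = table.counterstain_names[0]
                gate = GateInterval(
                    feature=dna,
                    sample_id=p.get("sample_id", "ALL"),
                    lower=float(p.get("lower", -np.inf)),
                    upper=float(p.get("upper", np.inf)),
                )
                gates.apply_interval_gate(
                    table, log, table.data[dna], gate, "dnaIntensity"
                )
            elif module == "areaFilter":
                gate = GateInterval(
                    feature="area",
                    sample_id=p.get("sample_id", "ALL"),
                    lower=float(p.get("lower", -np.inf)),
                    upper=float(p.get("upper", np.inf)),
                )
                gates.apply_interval_gate(
                    table, log, table.data["area"], gate, "areaFilter"
                )
            elif module == "cycleCorrelation":
                gate = GateInterval(
                    feature="log_ratio",
                    sample_id=p.get("sample_id", "ALL"),
                    lower=float(p.get("lower", -np.inf)),
                    upper=float(p.get("upper", np.inf)),
                )
                gates.gate_cycle_ratio(table, log, gate)
            elif module == "pruneOutliers":
                entries = p.get("cutoffs", [])
                cutoffs = [
                    PercentileCutoffs(
                        marker=str(e["marker"]),
                        p_lo=float(e.get("p_lo", 0.0)),
                        p_hi=float(e.get("p_hi", 100.0)),
                        scope=str(e.get("scope", p.get("scope", "batch"))),
                    )
                    for e in entries
                ]
                table = gates.prune_channel_outliers(table, log, cutoffs)
                state.table = table
                run.table = table
                rescaled_written = True
            elif module == "metaQC":
                decision = run_metaqc(
                    table,
                    log,
                    fraction=float(p.get("fraction", 1.0)),
                    threshold=float(p.get("threshold", 0.5)),
                    seed=mseed,
                    method=p.get("method", "umap"),
                    n_neighbors=int(p.get("n_neighbors", 15)),
                    min_cluster_size=int(p.get("min_cluster_size", 20)),
                )
                if decision is not None:
                    decision.cluster_stats.to_csv(
                        outdir / "metaqc_report.csv", index=False
                    )
                    run.reports["metaQC"] = decision
            elif module == "clustering":
                result = run_clustering(
                    table,
                    log,
                    method=p.get("method", "umap"),
                    seed=mseed,
                    n_neighbors=int(p.get("n_neighbors", 15)),
                    perplexity=float(p.get("perplexity", 30.0)),
                    min_cluster_size=int(p.get("min_cluster_size", 20)),
                )
                run.cluster_result = result
                result.to_frame().to_csv(outdir / "clusters.csv", index=False)
                retained = log.retained_mask(table)
                profile = cluster_profile(
                    table.data.loc[retained, table.feature_marker_names].reset_index(
                        drop=True
                    ),
                    result.labels,
                )
                k = int(p.get("meta_clusters", min(4, max(1, result.n_clusters))))
                if result.n_clusters >= 1:
                    profile = meta_cluster(profile, min(k, result.n_clusters))
                run.reports["profile"] = profile
                profile.means.to_csv(outdir / "cluster_profile_means.csv")
                profile.normalized.to_csv(outdir / "cluster_profile_normalized.csv")
            elif module == "setContrast":
                ref = p.get("reference") or config.samples[0].sample_id
                pct = tuple(p.get("percentiles", (0.1, 99.9)))
                contrast = compute_contrast(
                    handles[ref], config.markers, percentiles=pct,
                    overrides=p.get("overrides"), reference_sample=ref,
                )
                run.reports["contrast"] = contrast
                with open(outdir / "contrast.yml", "w") as fh:
                    yaml.safe_dump(
                        {k: list(v) for k, v in contrast.limits.items()}, fh
                    )
            elif module == "curateThumbnails":
                if run.cluster_result is None or "profile" not in run.reports:
                    raise ConfigError("curateThumbnails requires clustering")
                contrast = run.reports.get("contrast")
                if contrast is None:
                    ref = config.samples[0].sample_id
                    contrast = compute_contrast(handles[ref], config.markers,
                                                reference_sample=ref)
                manifest = curate_gallery(
                    handles,
                    table,
                    run.cluster_result,
                    run.reports["profile"],
                    contrast,
                    n_per_cluster=int(p.get("n_per_cluster", 25)),
                    size=int(p.get("size", 30)),
                    seed=mseed,
                    outdir=outdir / "gallery",
                    outlines=outlines or None,
                )
                run.reports["gallery_manifest"] = manifest
            else:  # pragma: no cover - guarded by QCConfig validation
                raise ConfigError(f"unknown module {module}")
        except QCError:
            logger.error("module %s failed; checkpoint of last completed module kept",
                         module)
            raise
        state.completed.append(module)
        state.module_hashes[module] = config.module_hash(module)
        (outdir / "checkpoints").mkdir(exist_ok=True)
        save_checkpoint(state, outdir / "checkpoints" / f"after_{module}.zip")
        save_checkpoint(state, outdir / "checkpoint.zip")
        n_after = len(log.retained_keys())
        logger.info(
            "module %-16s in=%d redacted=%+d elapsed=%.1fs",
            module, n_before, n_before - n_after, time.time() - t0,
        )
    # final outputs
    retained = log.retained_mask(table)
    cleaned = table.with_data(table.data.loc[retained].reset_index(drop=True))
    cleaned.to_csv(outdir / "cleaned.csv")
    log.status_frame().to_csv(outdir / "redaction_status.csv", index=False)
    log.events_frame().to_csv(outdir / "redaction_log.csv", index=False)
    summary = redaction_summary(log)
    summary.to_csv(outdir / "redaction_summary.csv", index=False)
    run.reports["summary"] = summary
    run.reports["rescaled"] = rescaled_written
    return run
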