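"""Histogram/threshold QC filters on the spatial feature table.

Four filters from the standard QC repertoire for cyclic multiplexed imaging:

* ``dnaIntensity`` — interval gate on per-cell mean nuclear counterstain;
  very dim nuclei are typically out of focus, very bright ones sit in tissue
  folds or are poorly segmented.
* ``areaFilter`` — interval gate on segmentation area (pixel counts); flags
  over-segmented fragments (small) and under-segmented doublets (large).
* ``cycleCorrelation`` — gate on log10(DNA_1 / DNA_n), the ratio of nuclear
  stain between the first and last imaging cycles. Cells lost or damaged
  during cyclic imaging form a discrete peak at ratios well above 0.
* ``pruneOutliers`` — per-marker percentile cutoffs; artifacts are often
  (not always) much brighter than biological signal, so trimming the extreme
  quantiles removes e.g. antibody-aggregate cells that are tedious to lasso
  by hand. After pruning, each marker is min-max rescaled to [0, 1].

All gates are supplied via configuration (headless operation); interval
bounds are inclusive — a value equal to a bound is kept. Percentile pruning
is boundary-inclusive in the opposite sense: a value at or beyond the cutoff
is redacted, so a point mass of identical outliers sitting exactly at the
empirical cutoff is removed in full. Percentiles of exactly 0 / 100 are open
ends (no cut), keeping (0, 100) a no-op.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, SchemaError
from .model import RedactionLog, SpatialFeatureTable

__all__ = [
    "GateInterval",
    "PercentileCutoffs",
    "apply_interval_gate",
    "log_cycle_ratio",
    "gate_cycle_ratio",
    "prune_channel_outliers",
    "rescale_unit_interval",
]

LOG_RATIO_EPSILON = 1.0  # AFU; keeps zero-intensity cells finite


@dataclass(frozen=True)
class GateInterval:
    """Inclusive lower/upper bounds on one feature, per sample or batch-wide."""

    feature: str
    sample_id: str = "ALL"
    lower: float = -np.inf
    upper: float = np.inf

    def __post_init__(self):
        if self.lower > self.upper:
            raise ParameterError(
                f"gate on {self.feature}: lower {self.lower} > upper {self.upper}"
            )


@dataclass(frozen=True)
class PercentileCutoffs:
    """Lower/upper percentile cutoffs for one marker."""

    marker: str
    p_lo: float = 0.0
    p_hi: float = 100.0
    scope: str = "batch"  # "batch" (pooled over samples) or "sample"

    def __post_init__(self):
        if not (0 <= self.p_lo < self.p_hi <= 100):
            raise ParameterError(
                f"cutoffs for {self.marker}: need 0 <= p_lo < p_hi <= 100, "
                f"got ({self.p_lo}, {self.p_hi})"
            )
        if self.scope not in ("batch", "sample"):
            raise ParameterError(f"unknown scope: {self.scope}")


def apply_interval_gate(
    table: SpatialFeatureTable,
    log: RedactionLog,
    values: pd.Series,
    gate: GateInterval,
    module_name: str,
) -> int:
    """Redact retained cells whose feature value falls outside [lower, upper].

    ``values`` must be aligned to ``table.data``'s index. Bounds are
    inclusive. Returns the number of newly redacted cells.
    """
    df = table.data
    in_sample = (
        np.ones(len(df), dtype=bool)
        if gate.sample_id == "ALL"
        else (df["sample_id"] == gate.sample_id).to_numpy()
    )
    retained = log.retained_mask(table)
    vals = values.to_numpy(dtype=float)
    scope = in_sample & retained
    if not np.isfinite(vals[scope]).all():
        raise ParameterError(f"{gate.feature}: non-finite values among gated cells")
    out = scope & ((vals < gate.lower) | (vals > gate.upper))
    keys = [
        (s, int(c))
        for s, c in zip(df["sample_id"].to_numpy()[out], df["cell_id"].to_numpy()[out])
    ]
    n = log.redact(
        keys, module_name, f"{gate.feature} outside [{gate.lower}, {gate.upper}]"
    )
    if scope.any() and n == int(scope.sum()):
        warnings.warn(
            f"{module_name}: every gated cell of sample '{gate.sample_id}' was "
            "redacted; sample is now empty",
            stacklevel=2,
        )
    return n


def log_cycle_ratio(table: SpatialFeatureTable) -> pd.Series:
    """Per-cell log10((DNA_1 + eps) / (DNA_n + eps)) with eps = 1 AFU.

    Cells lost during cyclic imaging have near-zero last-cycle counterstain
    and yield values well above 0; stable cells sit near 0.
    """
    cs = table.counterstain_names
    if len(cs) < 2:
        raise SchemaError(
            "cycleCorrelation needs counterstain channels for at least two cycles"
        )
    first, last = cs[0], cs[-1]
    num = table.data[first].to_numpy(dtype=float) + LOG_RATIO_EPSILON
    den = table.data[last].to_numpy(dtype=float) + LOG_RATIO_EPSILON
    return pd.Series(np.log10(num / den), index=table.data.index, name="log_ratio")


def gate_cycle_ratio(
    table: SpatialFeatureTable, log: RedactionLog, gate: GateInterval
) -> int:
    """Interval gate on the first/last-cycle DNA log ratio."""
    return apply_interval_gate(
        table, log, log_cycle_ratio(table), gate, "cycleCorrelation"
    )


def rescale_unit_interval(values: np.ndarray) -> np.ndarray:
    """(v - min) / (max - min); a constant vector maps to all zeros."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ParameterError("cannot rescale an empty vector")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        return np.zeros_like(values)
    return (values - lo) / (hi - lo)


def prune_channel_outliers(
    table: SpatialFeatureTable,
    log: RedactionLog,
    cutoffs: list[PercentileCutoffs],
) -> SpatialFeatureTable:
    """Percentile-prune marker channels, then 0-1 rescale every marker.

    Channels are processed in the given order and cumulatively: percentiles
    for each channel are computed over the cells still retained when that
    channel is reached (pooled over the batch, or per sample when
    ``scope="sample"``). Percentiles use linear interpolation between order
    statistics. A cell at or beyond a cutoff is redacted (module
    ``pruneOutliers``).

    Returns a copy of the table whose marker columns are min-max rescaled
    using the retained cells' extremes (redacted rows are rescaled with the
    same affine map so pooled re-analyses stay comparable). Retained values
    lie in [0, 1] with min exactly 0 and max exactly 1 (non-degenerate case).
    """
    df = table.data
    for co in cutoffs:
        if co.marker not in table.marker_names:
            raise SchemaError(f"pruneOutliers: unknown marker {co.marker}")
        vals = df[co.marker].to_numpy(dtype=float)
        retained = log.retained_mask(table)
        groups: list[np.ndarray] = (
            [retained]
            if co.scope == "batch"
            else [
                retained & (df["sample_id"] == sid).to_numpy()
                for sid in sorted(set(df["sample_id"]))
            ]
        )
        for scope in groups:
            if not scope.any():
                continue
            pool = vals[scope]
            out = np.zeros(len(df), dtype=bool)
            if co.p_lo > 0:
                lo = np.percentile(pool, co.p_lo)
                out |= scope & (vals <= lo)
            if co.p_hi < 100:
                hi = np.percentile(pool, co.p_hi)
                out |= scope & (vals >= hi)
            keys = [
                (s, int(c))
                for s, c in zip(
                    df["sample_id"].to_numpy()[out], df["cell_id"].to_numpy()[out]
                )
            ]
            log.redact(
                keys, "pruneOutliers", f"{co.marker} ({co.p_lo}, {co.p_hi})"
            )
    # final 0-1 rescale per marker, anchored on retained cells
    new = df.copy()
    retained = log.retained_mask(table)
    for name in table.marker_names:
        vals = new[name].to_numpy(dtype=float)
        if retained.any():
            lo, hi = float(vals[retained].min()), float(vals[retained].max())
        else:
            lo, hi = float(vals.min()), float(vals.max())
        if hi == lo:
            new[name] = 0.0
        else:
            new[name] = np.clip((vals - lo) / (hi - lo), 0.0, None)
    return table.with_data(new)


def export_histograms(
    table: SpatialFeatureTable,
    features: list[str],
    path_prefix: str,
    bins: int = 100,
) -> list[str]:
    """Export histogram CSVs (and plots) so a human can pick thresholds.

    Replaces the interactive histogram sliders of a viewer-based workflow.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    written = []
    for feat in features:
        if feat == "log_ratio":
            vals = log_cycle_ratio(table).to_numpy()
        elif feat in table.data.columns:
            vals = table.data[feat].to_numpy(dtype=float)
        else:
            raise SchemaError(f"unknown feature: {feat}")
        counts, edges = np.histogram(vals, bins=bins)
        csv_path = f"{path_prefix}_{feat}.csv"
        pd.DataFrame(
            {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
        ).to_csv(csv_path, index=False)
        fig, ax = plt.subplots(figsize=(4, 3))
        ax.stairs(counts, edges, fill=True)
        ax.set_xlabel(feat)
        ax.set_ylabel("cells")
        fig.tight_layout()
        fig.savefig(f"{path_prefix}_{feat}.png", dpi=100)
        plt.close(fig)
        written.append(csv_path)
    return written
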