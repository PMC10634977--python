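"""Polygon region-of-interest filtering of the spatial feature table.

ROIs are consumed as ordered vertex lists (the hand-drawn lassos of an
annotation front-end, exported as JSON). Membership is decided by the cell
CENTROID — the table row is the unit of redaction — under the even-odd fill
rule with the polygon boundary counting as inside, which stays deterministic
even for self-intersecting freehand outlines.

Two modes exist per sample: *negative* (cells inside any ROI are redacted —
the ROIs trace artifacts) and *positive* (cells outside every ROI are
redacted — the ROIs trace tissue regions devoid of artifacts, for heavily
affected specimens). A sample with no ROIs in positive mode is left untouched
with a warning: an absent annotation must never silently erase a specimen.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import GeometryError, ParameterError
from .model import Key, RedactionLog, SpatialFeatureTable

__all__ = ["PolygonROI", "cells_in_polygons", "apply_rois", "load_rois", "save_rois"]

_EPS = 1e-9


@dataclass(frozen=True)
class PolygonROI:
    """A closed polygon in full-resolution pixel coordinates."""

    sample_id: str
    vertices: tuple[tuple[float, float], ...]  # ordered (x, y); implicitly closed
    label: str = ""

    def __post_init__(self):
        if len(self.vertices) < 3:
            raise GeometryError("polygon needs at least 3 vertices")


def points_in_polygon(
    px: np.ndarray, py: np.ndarray, vertices: Sequence[tuple[float, float]]
) -> np.ndarray:
    """Vectorized even-odd point-in-polygon test, boundary-inclusive."""
    px = np.asarray(px, dtype=float)
    py = np.asarray(py, dtype=float)
    verts = np.asarray(vertices, dtype=float)
    if len(verts) < 3:
        raise GeometryError("polygon needs at least 3 vertices")
    inside = np.zeros(px.shape, dtype=bool)
    on_edge = np.zeros(px.shape, dtype=bool)
    n = len(verts)
    scale = max(1.0, np.abs(verts).max())
    for i in range(n):
        x1, y1 = verts[i]
        x2, y2 = verts[(i + 1) % n]
        # boundary test: zero cross product and inside the segment bbox
        cross = (x2 - x1) * (py - y1) - (y2 - y1) * (px - x1)
        within = (
            (np.minimum(x1, x2) - _EPS <= px)
            & (px <= np.maximum(x1, x2) + _EPS)
            & (np.minimum(y1, y2) - _EPS <= py)
            & (py <= np.maximum(y1, y2) + _EPS)
        )
        on_edge |= (np.abs(cross) <= _EPS * scale * scale) & within
        # even-odd crossing of a horizontal ray to +x (half-open in y)
        crosses = (y1 > py) != (y2 > py)
        if np.any(crosses):
            with np.errstate(divide="ignore", invalid="ignore"):
                xint = x1 + (py - y1) * (x2 - x1) / (y2 - y1)
            inside ^= crosses & (px < xint)
    return inside | on_edge


def cells_in_polygons(
    table: SpatialFeatureTable, rois: Sequence[PolygonROI]
) -> set[Key]:
    """Cells whose centroid lies inside (or on) at least one ROI of its sample."""
    sample_ids = set(table.data["sample_id"])
    for roi in rois:
        if roi.sample_id not in sample_ids:
            raise ParameterError(f"ROI sample_id '{roi.sample_id}' not in table")
    selected: set[Key] = set()
    for roi in rois:
        rows = table.data[table.data["sample_id"] == roi.sample_id]
        if rows.empty:
            continue
        hit = points_in_polygon(
            rows["x"].to_numpy(), rows["y"].to_numpy(), roi.vertices
        )
        selected.update(
            (roi.sample_id, int(c)) for c in rows["cell_id"].to_numpy()[hit]
        )
    return selected


def apply_rois(
    table: SpatialFeatureTable,
    log: RedactionLog,
    rois: Sequence[PolygonROI],
    mode: str | dict[str, str] = "negative",
    module: str = "selectROIs",
) -> int:
    """Apply ROI selection; returns the number of newly redacted cells.

    ``mode`` is exclusive per sample: either one string for all samples or a
    mapping ``sample_id -> mode``.
    """

    def mode_for(sid: str) -> str:
        m = mode.get(sid, "negative") if isinstance(mode, dict) else mode
        if m not in ("negative", "positive"):
            raise ParameterError(f"unknown ROI mode: {m}")
        return m

    selected = cells_in_polygons(table, rois)
    rois_per_sample: dict[str, int] = {}
    for roi in rois:
        rois_per_sample[roi.sample_id] = rois_per_sample.get(roi.sample_id, 0) + 1
    n = 0
    for sid in sorted(set(table.data["sample_id"])):
        keys = [k for k in table.keys() if k[0] == sid]
        if mode_for(sid) == "negative":
            n += log.redact(
                [k for k in keys if k in selected], module, "negative ROI"
            )
        else:
            if rois_per_sample.get(sid, 0) == 0:
                warnings.warn(
                    f"positive ROI mode with no ROIs for sample '{sid}'; "
                    "sample left untouched",
                    stacklevel=2,
                )
                continue
            n += log.redact(
                [k for k in keys if k not in selected], module, "outside positive ROI"
            )
    return n


# -- JSON exchange ----------------------------------------------------------


def save_rois(rois: Iterable[PolygonROI], path: Path | str) -> None:
    payload = [
        {"sample_id": r.sample_id, "label": r.label,
         "vertices": [list(v) for v in r.vertices]}
        for r in rois
    ]
    Path(path).write_text(json.dumps(payload, indent=1))


def load_rois(path: Path | str) -> list[PolygonROI]:
    payload = json.loads(Path(path).read_text())
    return [
        PolygonROI(
            sample_id=item["sample_id"],
            vertices=tuple(tuple(v) for v in item["vertices"]),
            label=item.get("label", ""),
        )
        for item in payload
    ]
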