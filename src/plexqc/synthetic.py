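"""Synthetic multiplexed-imaging samples with planted artifacts and ground truth.

The generator emulates the structure of a cyclic immunofluorescence experiment:
``n_cycles`` imaging rounds, each contributing one nuclear counterstain channel
(``DNA_1 ... DNA_n``) plus ``markers_per_cycle`` protein channels. Cells are
non-overlapping discs so areas and centroids have exact analytic values for
oracle tests. Cell types are defined by orthogonal marker templates: type ``t``
expresses the markers whose index is congruent to ``t`` modulo the number of
types.

Intensity model (AFU):

* background: constant ``background`` plus Gaussian read noise, clipped at 0;
* marker signal: ``template * exp(sigma * Z)`` per cell and channel
  (multiplicative lognormal noise);
* counterstain: a per-cell brightness factor (lognormal, ``noise_sigma``)
  shared across cycles — DNA content is a property of the cell — times a small
  per-cycle lognormal jitter (``counterstain_jitter_sigma``).

Planted artifact classes mirror the recurrent artifacts seen in real
multiplexed images: bright antibody *aggregates*, tissue *folds* that elevate
every channel, autofluorescent *fibers*, cell *detachment* over imaging cycles
and *defocus* tiles. Each artifact records a full-resolution binary mask and
the set of affected cells in the ground truth object, so detector recall and
gate recovery can be scored exactly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import tifffile
from skimage.draw import polygon2mask

from .errors import ParameterError, PlacementError
from .model import MarkerMetadata, SpatialFeatureTable

__all__ = [
    "ArtifactSpec",
    "SynthParams",
    "SyntheticGroundTruth",
    "generate_dataset",
    "compute_feature_table",
    "write_sample",
    "default_artifact_plan",
]


@dataclass(frozen=True)
class ArtifactSpec:
    """One planted artifact: its class and class-specific geometry/params.

    Parameter keys by class:

    * ``aggregate``: center (x, y), radius (px), channel (marker name),
      multiplier (default 5; value = multiplier x 99th percentile of the
      channel's biological signal)
    * ``fold``: vertices [(x, y), ...], factor (optional; else drawn in [2, 3])
    * ``fiber``: start (x, y), length (steps), channels (>= 2 marker names),
      multiplier (default 5)
    * ``detachment``: fraction, after_cycle, delta (default 0.01)
    * ``defocus``: rect (x0, y0, x1, y1), sigma (px)
    """

    kind: str
    params: dict

    def __post_init__(self):
        if self.kind not in ("aggregate", "fold", "fiber", "detachment", "defocus"):
            raise ParameterError(f"unknown artifact class: {self.kind}")


@dataclass(frozen=True)
class SynthParams:
    """Study conditions for one synthetic specimen."""

    shape: tuple[int, int] = (1024, 1024)  # (rows, cols)
    n_cells: int = 500
    n_cell_types: int = 4
    cell_radius: int = 6  # px
    n_cycles: int = 3
    markers_per_cycle: int = 3
    marker_template: float = 80.0  # AFU above background for expressed markers
    counterstain_template: float = 2000.0  # AFU above background
    noise_sigma: float = 0.2  # lognormal sigma, per cell x channel
    counterstain_jitter_sigma: float = 0.05  # per cell x cycle
    background: float = 100.0  # AFU
    read_noise: float = 5.0  # Gaussian sigma, clipped at 0
    doublet_fraction: float = 0.0  # under-segmented doublets (two fused discs)
    artifacts: tuple[ArtifactSpec, ...] = ()
    seed: int = 0

    def __post_init__(self):
        if self.n_cells < 0:
            raise ParameterError("n_cells must be >= 0")
        if self.marker_template < 0 or self.counterstain_template < 0:
            raise ParameterError("templates must be non-negative")


@dataclass
class SyntheticGroundTruth:
    """Planted truth: masks, affected-cell sets, true types, detachment."""

    artifact_masks: dict[str, np.ndarray] = field(default_factory=dict)
    affected_cells: dict[str, set[int]] = field(default_factory=dict)
    cell_types: dict[int, int] = field(default_factory=dict)
    detached_cells: set[int] = field(default_factory=set)
    detachment_delta: float = 0.01
    detachment_after_cycle: int = 1
    doublet_cells: set[int] = field(default_factory=set)
    # counterstain signal amplitude per cell and cycle, before per-cycle
    # jitter; *_base is before detachment scaling
    dna_amp: np.ndarray | None = None
    dna_amp_base: np.ndarray | None = None
    fold_factors: dict[str, float] = field(default_factory=dict)


def default_markers(params: SynthParams) -> list[MarkerMetadata]:
    """Channel layout: per cycle one counterstain followed by the markers."""
    markers: list[MarkerMetadata] = []
    idx = 0
    m = 0
    for cyc in range(1, params.n_cycles + 1):
        markers.append(MarkerMetadata(idx, f"DNA_{cyc}", cyc, True))
        idx += 1
        for _ in range(params.markers_per_cycle):
            markers.append(MarkerMetadata(idx, f"M{m:02d}", cyc, False))
            idx += 1
            m += 1
    return markers


def _place_centers(params: SynthParams, rng: np.random.Generator) -> np.ndarray:
    """Non-overlapping disc centers by rejection sampling."""
    h, w = params.shape
    r = params.cell_radius
    margin = 2 * r + 2  # keep doublet lobes inside the image
    min_d2 = (2 * r + 2) ** 2
    # coarse occupancy grid for O(1) neighbor lookups
    cell = 2 * r + 2
    grid: dict[tuple[int, int], list[tuple[float, float]]] = {}
    centers = []
    attempts = 0
    max_attempts = max(1000, 200 * params.n_cells)
    while len(centers) < params.n_cells:
        if attempts > max_attempts:
            raise PlacementError(
                f"could not place {params.n_cells} non-overlapping cells "
                f"of radius {r} in {params.shape}"
            )
        attempts += 1
        cy = rng.uniform(margin, h - margin)
        cx = rng.uniform(margin, w - margin)
        gy, gx = int(cy // cell), int(cx // cell)
        ok = True
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                for (oy, ox) in grid.get((gy + dy, gx + dx), ()):
                    if (oy - cy) ** 2 + (ox - cx) ** 2 < min_d2:
                        ok = False
                        break
        if ok:
            centers.append((cy, cx))
            grid.setdefault((gy, gx), []).append((cy, cx))
    return np.array(centers)


def _paint_disc(mask: np.ndarray, cy: float, cx: float, r: int, label: int) -> None:
    y0, y1 = int(np.floor(cy - r)), int(np.ceil(cy + r)) + 1
    x0, x1 = int(np.floor(cx - r)), int(np.ceil(cx + r)) + 1
    y0, x0 = max(y0, 0), max(x0, 0)
    y1, x1 = min(y1, mask.shape[0]), min(x1, mask.shape[1])
    yy, xx = np.mgrid[y0:y1, x0:x1]
    mask[y0:y1, x0:x1][(yy - cy) ** 2 + (xx - cx) ** 2 <= r * r] = label


def _random_walk_mask(
    shape: tuple[int, int],
    start: tuple[float, float],
    length: int,
    rng: np.random.Generator,
    width: int = 3,
) -> np.ndarray:
    """A bright lint-fiber-like curve: random walk dilated to ``width`` px."""
    h, w = shape
    y, x = float(start[1]), float(start[0])
    theta = rng.uniform(0, 2 * np.pi)
    mask = np.zeros(shape, dtype=bool)
    for _ in range(length):
        theta += rng.normal(0, 0.25)
        y = np.clip(y + np.sin(theta), 1, h - 2)
        x = np.clip(x + np.cos(theta), 1, w - 2)
        mask[int(round(y)), int(round(x))] = True
    r = width // 2
    return ndi.binary_dilation(mask, structure=_disc_structure(r))


def _disc_structure(r: int) -> np.ndarray:
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy * yy + xx * xx <= r * r


def compute_feature_table(
    images: np.ndarray,
    mask: np.ndarray,
    markers: Sequence[MarkerMetadata],
    sample_id: str = "synthetic",
) -> SpatialFeatureTable:
    """Quantify a (C, H, W) image stack over a label mask.

    Per cell: centroid = mean of member-pixel coordinates, area = member pixel
    count, intensity = mean of each channel over member pixels.
    """
    images = np.asarray(images)
    if images.ndim == 2:
        images = images[None]
    if images.shape[1:] != mask.shape:
        raise ParameterError(
            f"image shape {images.shape[1:]} != mask shape {mask.shape}"
        )
    if len(markers) != images.shape[0]:
        raise ParameterError("one marker per channel required")
    ids = np.unique(mask)
    ids = ids[ids > 0]
    if ids.size == 0:
        cols = list(("sample_id", "cell_id", "x", "y", "area"))
        cols += [m.marker_name for m in markers]
        return SpatialFeatureTable(
            pd.DataFrame({c: [] for c in cols}), list(markers)
        )
    flat = mask.ravel()
    # areas and centroids via bincount over the label image
    counts = np.bincount(flat, minlength=ids.max() + 1)
    yy, xx = np.indices(mask.shape)
    ysum = np.bincount(flat, weights=yy.ravel(), minlength=ids.max() + 1)
    xsum = np.bincount(flat, weights=xx.ravel(), minlength=ids.max() + 1)
    area = counts[ids]
    cy = ysum[ids] / area
    cx = xsum[ids] / area
    data = {
        "sample_id": sample_id,
        "cell_id": ids.astype(int),
        "x": cx,
        "y": cy,
        "area": area.astype(int),
    }
    for c, m in enumerate(markers):
        csum = np.bincount(
            flat, weights=images[c].ravel().astype(float), minlength=ids.max() + 1
        )
        data[m.marker_name] = csum[ids] / area
    return SpatialFeatureTable(pd.DataFrame(data), list(markers))


def generate_dataset(
    params: SynthParams, sample_id: str = "synthetic"
) -> tuple[
    np.ndarray,
    list[MarkerMetadata],
    np.ndarray,
    SpatialFeatureTable,
    SyntheticGroundTruth,
]:
    """Generate one synthetic specimen.

    Returns ``(images, markers, label_mask, table, ground_truth)`` where
    ``images`` is a float32 (C, H, W) stack. Identical params (including the
    seed) produce bit-identical outputs.
    """
    rng = np.random.default_rng(params.seed)
    h, w = params.shape
    markers = default_markers(params)
    n_markers = params.n_cycles * params.markers_per_cycle

    gt = SyntheticGroundTruth()

    # --- geometry ---------------------------------------------------------
    centers = (
        _place_centers(params, rng) if params.n_cells else np.zeros((0, 2))
    )
    types = (
        rng.integers(0, params.n_cell_types, size=params.n_cells)
        if params.n_cells
        else np.zeros(0, dtype=int)
    )
    n_doub = int(round(params.doublet_fraction * params.n_cells))
    doublet_ids = set(range(1, n_doub + 1))  # first labels are doublets
    mask = np.zeros(params.shape, dtype=np.int32)
    r = params.cell_radius
    for i, (cy, cx) in enumerate(centers):
        label = i + 1
        if label in doublet_ids:
            # two fused discs 1.5 r apart -> area ~ 1.9x a single disc
            ang = rng.uniform(0, np.pi)
            dy, dx = 0.75 * r * np.sin(ang), 0.75 * r * np.cos(ang)
            _paint_disc(mask, cy - dy, cx - dx, r, label)
            _paint_disc(mask, cy + dy, cx + dx, r, label)
        else:
            _paint_disc(mask, cy, cx, r, label)
    gt.cell_types = {i + 1: int(t) for i, t in enumerate(types)}
    gt.doublet_cells = doublet_ids

    # --- per-cell signal amplitudes --------------------------------------
    # type t expresses markers m with m % n_types == t
    template = np.zeros((params.n_cell_types, n_markers))
    for m in range(n_markers):
        template[m % params.n_cell_types, m] = params.marker_template
    marker_amp = template[types] * np.exp(
        params.noise_sigma * rng.standard_normal((params.n_cells, n_markers))
    )
    cell_factor = np.exp(params.noise_sigma * rng.standard_normal(params.n_cells))
    jitter = np.exp(
        params.counterstain_jitter_sigma
        * rng.standard_normal((params.n_cells, params.n_cycles))
    )
    dna_amp_base = params.counterstain_template * cell_factor[:, None] * np.ones(
        (1, params.n_cycles)
    )
    dna_amp = dna_amp_base.copy()

    # --- detachment (amplitude-level, before rendering) -------------------
    for spec in params.artifacts:
        if spec.kind != "detachment":
            continue
        frac = float(spec.params["fraction"])
        after = int(spec.params.get("after_cycle", params.n_cycles - 1))
        delta = float(spec.params.get("delta", 0.01))
        n_det = int(round(frac * params.n_cells))
        detached = rng.choice(params.n_cells, size=n_det, replace=False)
        gt.detached_cells = {int(i) + 1 for i in detached}
        gt.detachment_delta = delta
        gt.detachment_after_cycle = after
        dna_amp[detached, after:] *= delta
        for m in range(n_markers):
            cyc = m // params.markers_per_cycle  # 0-based cycle of marker m
            if cyc >= after:
                marker_amp[detached, m] *= delta
    gt.dna_amp = dna_amp
    gt.dna_amp_base = dna_amp_base

    # --- render channels ---------------------------------------------------
    images = np.empty((len(markers), h, w), dtype=np.float32)
    cell_pixels = mask > 0
    idx = mask[cell_pixels] - 1  # 0-based cell index per foreground pixel
    for ch, meta in enumerate(markers):
        bg = params.background + params.read_noise * rng.standard_normal((h, w))
        img = np.clip(bg, 0, None)
        if params.n_cells:
            if meta.is_counterstain:
                amp = dna_amp[:, meta.cycle_number - 1] * jitter[
                    :, meta.cycle_number - 1
                ]
            else:
                m = meta.channel_index - meta.cycle_number  # marker ordinal
                amp = marker_amp[:, m]
            img[cell_pixels] += amp[idx]
        images[ch] = img

    name_to_ch = {m.marker_name: m.channel_index for m in markers}

    # --- image-level artifacts --------------------------------------------
    n_by_kind: dict[str, int] = {}
    for spec in params.artifacts:
        if spec.kind == "detachment":
            continue
        n_by_kind[spec.kind] = n_by_kind.get(spec.kind, 0) + 1
        name = f"{spec.kind}_{n_by_kind[spec.kind]}"
        if spec.kind == "fold":
            verts = np.asarray(spec.params["vertices"], dtype=float)
            if (verts < 0).any() or (verts[:, 0] >= w).any() or (verts[:, 1] >= h).any():
                raise ParameterError(f"{name}: vertices outside image")
            factor = float(spec.params.get("factor") or rng.uniform(2.0, 3.0))
            amask = polygon2mask(params.shape, verts[:, ::-1])  # (row, col)
            images[:, amask] *= factor
            gt.fold_factors[name] = factor
        elif spec.kind == "aggregate":
            cx, cy = spec.params["center"]
            rad = float(spec.params["radius"])
            if not (0 <= cx < w and 0 <= cy < h):
                raise ParameterError(f"{name}: center outside image")
            mult = float(spec.params.get("multiplier", 5.0))
            ch = name_to_ch[spec.params["channel"]]
            value = mult * np.percentile(images[ch], 99)
            amask = np.zeros(params.shape, dtype=bool)
            _paint_disc(amask.view(np.uint8), cy, cx, int(rad), 1)
            images[ch][amask] = value
        elif spec.kind == "fiber":
            chans = [name_to_ch[c] for c in spec.params["channels"]]
            if len(chans) < 2:
                raise ParameterError(f"{name}: fiber needs >= 2 channels")
            amask = _random_walk_mask(
                params.shape,
                spec.params["start"],
                int(spec.params.get("length", 400)),
                rng,
            )
            mult = float(spec.params.get("multiplier", 5.0))
            for ch in chans:
                images[ch][amask] = mult * np.percentile(images[ch], 99)
        elif spec.kind == "defocus":
            x0, y0, x1, y1 = spec.params["rect"]
            if not (0 <= x0 < x1 <= w and 0 <= y0 < y1 <= h):
                raise ParameterError(f"{name}: rect outside image")
            sigma = float(spec.params.get("sigma", 4.0))
            amask = np.zeros(params.shape, dtype=bool)
            amask[y0:y1, x0:x1] = True
            for ch in range(len(markers)):
                blurred = ndi.gaussian_filter(images[ch], sigma)
                images[ch][amask] = blurred[amask]
        gt.artifact_masks[name] = amask
        # affected cells: centroid inside the artifact mask
        affected = set()
        for i, (cyc_, cxc) in enumerate(centers):
            iy, ix = int(round(cyc_)), int(round(cxc))
            if amask[iy, ix]:
                affected.add(i + 1)
        gt.affected_cells[name] = affected

    table = compute_feature_table(images, mask, markers, sample_id=sample_id)
    return images, markers, mask, table, gt


def default_artifact_plan(shape: tuple[int, int] = (1024, 1024)) -> list[ArtifactSpec]:
    """A representative artifact plan: one aggregate, one fold, detachment."""
    h, w = shape
    return [
        ArtifactSpec(
            "aggregate",
            {"center": (int(0.22 * w), int(0.25 * h)), "radius": int(0.078 * w),
             "channel": "M00", "multiplier": 5.0},
        ),
        ArtifactSpec(
            "fold",
            {
                "vertices": [
                    (int(0.42 * w), int(0.40 * h)),
                    (int(0.92 * w), int(0.44 * h)),
                    (int(0.95 * w), int(0.90 * h)),
                    (int(0.47 * w), int(0.93 * h)),
                ]
            },
        ),
        ArtifactSpec("detachment", {"fraction": 0.2, "after_cycle": 2, "delta": 0.01}),
    ]


# ---------------------------------------------------------------------------
# On-disk sample layout (four-file contract + ground-truth JSON)
# ---------------------------------------------------------------------------


def _rle_encode(mask: np.ndarray) -> dict:
    """Row-major run-length encoding of a boolean mask (JSON-friendly)."""
    flat = np.asarray(mask, dtype=bool).ravel()
    n = flat.size
    changes = np.flatnonzero(np.diff(flat.astype(np.int8)))
    bounds = np.concatenate(([0], changes + 1, [n]))
    runs = np.diff(bounds)
    return {
        "shape": list(mask.shape),
        "first": bool(flat[0]) if n else False,
        "runs": runs.tolist(),
    }


def rle_decode(enc: dict) -> np.ndarray:
    flat = np.zeros(int(np.prod(enc["shape"])), dtype=bool)
    pos = 0
    val = enc["first"]
    for run in enc["runs"]:
        if val:
            flat[pos : pos + run] = True
        pos += run
        val = not val
    return flat.reshape(enc["shape"])


def write_sample(
    outdir: Path | str, params: SynthParams, sample_id: str = "synthetic"
) -> dict[str, Path]:
    """Write the standard four-file layout plus ground truth and markers.

    Produces ``image.tif`` (multi-channel float32), ``mask.tif`` (int32 label
    mask), ``outlines.tif`` (binary cell boundaries), ``table.csv`` and
    ``ground_truth.json``, so the pipeline consumes synthetic data exactly as
    it would real data.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    images, markers, mask, table, gt = generate_dataset(params, sample_id)
    paths = {
        "image": outdir / "image.tif",
        "mask": outdir / "mask.tif",
        "outline": outdir / "outlines.tif",
        "table": outdir / "table.csv",
        "ground_truth": outdir / "ground_truth.json",
        "markers": outdir / "markers.csv",
    }
    tifffile.imwrite(paths["image"], images, photometric="minisblack")
    tifffile.imwrite(paths["mask"], mask)
    eroded = ndi.grey_erosion(mask, footprint=_disc_structure(1))
    outlines = ((mask != eroded) & (mask > 0)).astype(np.uint8) * 255
    tifffile.imwrite(paths["outline"], outlines)
    table.to_csv(paths["table"])
    pd.DataFrame(
        [
            {
                "channel_index": m.channel_index,
                "marker_name": m.marker_name,
                "cycle_number": m.cycle_number,
                "is_counterstain": m.is_counterstain,
            }
            for m in markers
        ]
    ).to_csv(paths["markers"], index=False)
    gt_json = {
        "artifact_masks": {k: _rle_encode(v) for k, v in gt.artifact_masks.items()},
        "affected_cells": {k: sorted(v) for k, v in gt.affected_cells.items()},
        "cell_types": {str(k): v for k, v in gt.cell_types.items()},
        "detached_cells": sorted(gt.detached_cells),
        "detachment_delta": gt.detachment_delta,
        "detachment_after_cycle": gt.detachment_after_cycle,
        "doublet_cells": sorted(gt.doublet_cells),
        "fold_factors": gt.fold_factors,
    }
    paths["ground_truth"].write_text(json.dumps(gt_json))
    return paths
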