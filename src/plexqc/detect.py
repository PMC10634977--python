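"""Automated artifact detection by mathematical morphology and flood fill.

The detector flags image regions whose intensity structure is larger than the
cell scale: illumination aberrations, antibody aggregates, tissue folds. It
operates per channel on a downsampled, 8-bit-rescaled copy of the image:

1. block-mean downsample (``downsample_factor``);
2. linear min-max rescale to integer grey levels 0..255;
3. grey-level erosion -> local mean -> grey-level dilation, all with one disk
   kernel whose diameter should span roughly 3-5 cells at the working
   resolution. Erosion removes cell-scale bright spots; the local mean
   smooths residual texture; dilation restores the extent of structures that
   survived, so artifact-scale plateaus remain while single cells vanish;
4. local-maxima seed points searched with the kernel expanded by
   ``seed_expansion``, accepted only strictly above ``intensity_floor``;
5. a tolerance flood fill from each seed; the union of the filled regions,
   resized back to full resolution, is the artifact mask.

Cells whose centroid pixel falls inside the mask are dropped from the spatial
feature table (two-phase: masks can be reviewed before application).

All filters use reflect padding at the image border so edge artifacts are not
eroded by a spurious dark rim.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.ndimage as ndi
from skimage.segmentation import flood

from .errors import ParameterError
from .model import RedactionLog, SpatialFeatureTable, downsample_channel

__all__ = [
    "DetectionParams",
    "ArtifactMask",
    "transform_channel",
    "find_seed_points",
    "flood_fill_region",
    "build_artifact_mask",
    "detect_channel",
    "redact_by_mask",
]


@dataclass(frozen=True)
class DetectionParams:
    """User parameters of the artifact detector.

    ``kernel_diameter`` is in pixels at the working (downsampled) resolution
    and should be on the order of 3-5 cell diameters; structures smaller than
    the kernel are suppressed, larger ones survive. ``tolerance`` is in the
    8-bit grey levels the transform produces. ``intensity_floor`` rejects
    seeds whose transformed value is not clearly above background, so
    cell-scale residue cannot seed a region.
    """

    downsample_factor: int = 4
    kernel_diameter: int = 9
    seed_expansion: float = 2.0
    tolerance: float = 40.0
    intensity_floor: int = 50

    def __post_init__(self):
        if self.downsample_factor < 1:
            raise ParameterError("downsample_factor must be >= 1")
        if self.kernel_diameter < 3:
            raise ParameterError("kernel_diameter must be >= 3")
        if self.seed_expansion < 1:
            raise ParameterError("seed_expansion must be >= 1")
        if self.tolerance < 0:
            raise ParameterError("tolerance must be >= 0")


@dataclass
class ArtifactMask:
    """Full-resolution binary artifact mask for one channel."""

    channel: str
    mask: np.ndarray  # bool, image dims
    seeds: list[tuple[int, int]] = field(default_factory=list)  # (x, y) full res
    region_areas: list[int] = field(default_factory=list)  # full-res px per region

    @property
    def area(self) -> int:
        return int(self.mask.sum())


def disk_footprint(diameter: int) -> np.ndarray:
    """Disk structuring element of (odd) size ``2*(diameter//2) + 1``."""
    r = max(1, diameter // 2)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return yy * yy + xx * xx <= r * r


def rescale_to_uint8(arr: np.ndarray) -> np.ndarray:
    """Linear min-max rescale to integer levels 0..255.

    A constant input maps to all zeros (documented degenerate case). The full
    range is used deliberately: artifacts are assumed to be the brightest
    structures, so percentile clipping could saturate them together with
    signal.
    """
    arr = np.asarray(arr, dtype=float)
    lo, hi = float(arr.min()), float(arr.max())
    if hi == lo:
        return np.zeros(arr.shape, dtype=np.uint8)
    return np.rint((arr - lo) / (hi - lo) * 255.0).astype(np.uint8)


def transform_channel(channel: np.ndarray, params: DetectionParams) -> np.ndarray:
    """Downsample, rescale to uint8 and apply erosion -> local mean -> dilation."""
    channel = np.asarray(channel)
    if channel.size == 0:
        raise ParameterError("channel is empty")
    work = downsample_channel(channel, params.downsample_factor)
    levels = rescale_to_uint8(work)
    fp = disk_footprint(params.kernel_diameter)
    eroded = ndi.grey_erosion(levels, footprint=fp, mode="reflect")
    weights = fp.astype(float) / fp.sum()
    mean = ndi.correlate(eroded.astype(float), weights, mode="reflect")
    mean = np.rint(mean).astype(np.uint8)
    dilated = ndi.grey_dilation(mean, footprint=fp, mode="reflect")
    return dilated


def find_seed_points(
    transformed: np.ndarray, params: DetectionParams
) -> list[tuple[int, int]]:
    """Local-maxima seed points in the transformed image (working resolution).

    Maxima are taken within the kernel expanded by ``seed_expansion``, must be
    strictly above ``intensity_floor`` and are kept at mutual (Euclidean)
    distance of at least the expanded diameter. For plateau maxima the
    lexicographically smallest (y, x) pixel wins; candidates are visited in
    order of decreasing value then (y, x), and greedily accepted.
    """
    expanded = max(3, int(round(params.kernel_diameter * params.seed_expansion)))
    fp = disk_footprint(expanded)
    mx = ndi.maximum_filter(transformed, footprint=fp, mode="reflect")
    cand = (transformed == mx) & (transformed > params.intensity_floor)
    if not cand.any():
        return []
    # adjacent candidates necessarily share their value (else the lower one
    # would not be a local maximum), so each 8-connected candidate component
    # is one plateau; collapse it to its lexicographically smallest pixel
    lab, ncomp = ndi.label(cand, structure=np.ones((3, 3), dtype=int))
    reps: list[tuple[int, int, int]] = []  # (value, y, x)
    for c in range(1, ncomp + 1):
        ys, xs = np.nonzero(lab == c)
        i = np.lexsort((xs, ys))[0]
        reps.append((int(transformed[ys[i], xs[i]]), int(ys[i]), int(xs[i])))
    reps.sort(key=lambda r: (-r[0], r[1], r[2]))
    seeds: list[tuple[int, int]] = []
    min_d2 = float(expanded) ** 2
    for _, y, x in reps:
        if all((y - sy) ** 2 + (x - sx) ** 2 >= min_d2 for sx, sy in seeds):
            seeds.append((x, y))
    return seeds


def flood_fill_region(
    transformed: np.ndarray, seed: tuple[int, int], tolerance: float
) -> np.ndarray:
    """8-connected component of pixels within ``tolerance`` of the seed value."""
    if tolerance < 0:
        raise ParameterError("tolerance must be >= 0")
    x, y = seed
    h, w = transformed.shape
    if not (0 <= x < w and 0 <= y < h):
        raise ParameterError(f"seed {seed} outside grid {transformed.shape}")
    return flood(
        transformed.astype(np.int16), (int(y), int(x)),
        connectivity=2, tolerance=float(tolerance),
    )


def build_artifact_mask(
    regions: Sequence[np.ndarray],
    original_shape: tuple[int, int],
    factor: int,
    channel: str = "",
    seeds: Sequence[tuple[int, int]] = (),
) -> ArtifactMask:
    """Union the flood regions and resize to the original image dimensions.

    Upscaling is nearest-neighbor: each working pixel expands to a
    ``factor x factor`` block (clipped to the original dims); seed
    coordinates are rescaled by the same factor.
    """
    h, w = original_shape
    if regions:
        union = np.zeros(regions[0].shape, dtype=bool)
        areas = []
        for r in regions:
            if r.shape != union.shape:
                raise ParameterError("regions must share working-resolution dims")
            union |= r
            areas.append(int(r.sum()) * factor * factor)
        full = np.repeat(np.repeat(union, factor, axis=0), factor, axis=1)[:h, :w]
    else:
        full = np.zeros(original_shape, dtype=bool)
        areas = []
    scaled_seeds = [(int(x) * factor, int(y) * factor) for x, y in seeds]
    return ArtifactMask(channel=channel, mask=full, seeds=scaled_seeds,
                        region_areas=areas)


def detect_channel(
    channel: np.ndarray, params: DetectionParams, channel_name: str = ""
) -> ArtifactMask:
    """End-to-end detection on one channel: transform, seed, flood, union."""
    transformed = transform_channel(channel, params)
    seeds = find_seed_points(transformed, params)
    regions = [flood_fill_region(transformed, s, params.tolerance) for s in seeds]
    return build_artifact_mask(
        regions, channel.shape, params.downsample_factor,
        channel=channel_name, seeds=seeds,
    )


def redact_by_mask(
    table: SpatialFeatureTable,
    log: RedactionLog,
    mask: ArtifactMask | np.ndarray,
    sample_id: str | None = None,
    module: str = "artifactDetect",
    detail: str | None = None,
) -> int:
    """Redact cells whose rounded centroid pixel lies inside the mask.

    Only currently retained cells change status; cells already redacted by an
    earlier module keep their original provenance. Returns the number of
    newly redacted cells.
    """
    if isinstance(mask, ArtifactMask):
        grid = mask.mask
        detail = detail if detail is not None else mask.channel
    else:
        grid = np.asarray(mask, dtype=bool)
        detail = detail or ""
    df = table.data
    rows = df if sample_id is None else df[df["sample_id"] == sample_id]
    if rows.empty:
        return 0
    h, w = grid.shape
    iy = np.clip(np.rint(rows["y"].to_numpy(float)).astype(int), 0, h - 1)
    ix = np.clip(np.rint(rows["x"].to_numpy(float)).astype(int), 0, w - 1)
    hit = grid[iy, ix]
    keys = list(
        zip(rows["sample_id"].to_numpy()[hit], rows["cell_id"].to_numpy()[hit])
    )
    return log.redact([(s, int(c)) for s, c in keys], module, detail)
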