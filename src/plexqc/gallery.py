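"""Batch-consistent contrast settings and per-cluster thumbnail galleries.

Cluster verification is visual: for each cluster, a grid of fixed-size image
patches of randomly drawn member cells is rendered with the cluster's three
most highly expressed markers (rank 1 green, 2 red, 3 blue) over the nuclear
counterstain in grey. One set of per-channel display limits, computed on a
reference sample, renders every sample in the batch so apparent brightness is
comparable across tissues. A single white pixel at the patch center marks the
reference cell; the optional segmentation-outline image can be overlaid.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import ClusterProfile, ClusterResult
from .errors import ParameterError
from .model import ArrayImageHandle, ImageHandle, MarkerMetadata, SpatialFeatureTable

__all__ = [
    "ContrastSettings",
    "Thumbnail",
    "compute_contrast",
    "top_markers",
    "extract_patch",
    "curate_gallery",
]

# color ranks for the top-3 markers, matching common gallery conventions
_RANK_COLORS = ((0.0, 1.0, 0.0), (1.0, 0.0, 0.0), (0.0, 0.0, 1.0))  # G, R, B
_GREY = (1.0, 1.0, 1.0)


@dataclass
class ContrastSettings:
    """Per-marker display limits (low, high) in AFU, from a reference sample."""

    limits: dict[str, tuple[float, float]]
    reference_sample: str = ""

    def apply(self, values: np.ndarray, marker: str) -> np.ndarray:
        """Map intensities to display levels in [0, 1]; degenerate limits
        (constant channel) render mid-grey."""
        lo, hi = self.limits[marker]
        if hi == lo:
            return np.full(np.shape(values), 0.5)
        return np.clip((np.asarray(values, float) - lo) / (hi - lo), 0.0, 1.0)


@dataclass
class Thumbnail:
    """One S x S patch: raw per-channel crops and the rendered RGB composite."""

    sample_id: str
    cell_id: int
    center: tuple[float, float]  # (x, y) full resolution
    markers: list[str]  # displayed markers, rank order
    rgb: np.ndarray  # (S, S, 3) in [0, 1]
    patches: dict[str, np.ndarray] = field(default_factory=dict)


def compute_contrast(
    handle: ImageHandle | ArrayImageHandle | np.ndarray,
    markers: list[MarkerMetadata],
    percentiles: tuple[float, float] = (0.1, 99.9),
    overrides: dict[str, tuple[float, float]] | None = None,
    reference_sample: str = "",
) -> ContrastSettings:
    """Display limits from pixel percentiles of the reference channels.

    User-supplied overrides win over computed limits; the same settings are
    then applied to every sample in the batch.
    """
    if isinstance(handle, np.ndarray):
        handle = ArrayImageHandle(handle)
    lo_p, hi_p = percentiles
    if not 0 <= lo_p < hi_p <= 100:
        raise ParameterError("percentiles must satisfy 0 <= lo < hi <= 100")
    limits: dict[str, tuple[float, float]] = {}
    for m in markers:
        ch = np.asarray(handle.channel(m.channel_index), dtype=float)
        lo, hi = np.percentile(ch, [lo_p, hi_p])
        limits[m.marker_name] = (float(lo), float(hi))
    if overrides:
        limits.update({k: (float(a), float(b)) for k, (a, b) in overrides.items()})
    return ContrastSettings(limits=limits, reference_sample=reference_sample)


def top_markers(
    profile: ClusterProfile,
    cluster: int,
    k: int = 3,
    exclude: list[str] | None = None,
) -> list[str]:
    """The k most highly expressed markers for one cluster.

    Ranking uses the cluster-normalized profile row, descending; ties break
    toward the earlier channel (column) position. Counterstains should be
    passed via ``exclude``. With fewer than k eligible markers, all are
    returned in rank order.
    """
    row = profile.normalized.loc[cluster]
    if exclude:
        row = row.drop([c for c in exclude if c in row.index])
    vals = row.to_numpy(dtype=float)
    order = np.lexsort((np.arange(len(vals)), -vals))
    return [row.index[i] for i in order[: min(k, len(vals))]]


def extract_patch(
    handle: ImageHandle | ArrayImageHandle | np.ndarray,
    center: tuple[float, float],
    markers: list[MarkerMetadata],
    display_markers: list[str],
    contrast: ContrastSettings,
    size: int = 30,
    counterstain: str | None = None,
    outline: np.ndarray | None = None,
    sample_id: str = "",
    cell_id: int = 0,
) -> Thumbnail:
    """Render one S x S thumbnail centered on a cell.

    The crop is centered at the rounded centroid and zero-padded where it
    leaves the image, so every patch is exactly S x S. Displayed markers map
    to green/red/blue by rank; the counterstain is added in grey. The center
    pixel is set to the display maximum (white reference dot).
    """
    if isinstance(handle, np.ndarray):
        handle = ArrayImageHandle(handle)
    h, w = handle.shape
    cx, cy = center
    if not (0 <= cx < w and 0 <= cy < h):
        raise ParameterError(f"patch center {center} outside image {handle.shape}")
    icx, icy = int(round(cx)), int(round(cy))
    half = size // 2
    y0, x0 = icy - half, icx - half
    name_to_meta = {m.marker_name: m for m in markers}

    def crop(channel_name: str) -> np.ndarray:
        ch = np.asarray(handle.channel(name_to_meta[channel_name].channel_index))
        patch = np.zeros((size, size), dtype=float)
        sy0, sy1 = max(y0, 0), min(y0 + size, h)
        sx0, sx1 = max(x0, 0), min(x0 + size, w)
        patch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = ch[sy0:sy1, sx0:sx1]
        return patch

    rgb = np.zeros((size, size, 3), dtype=float)
    patches: dict[str, np.ndarray] = {}
    shown = list(display_markers[:3])
    for rank, name in enumerate(shown):
        raw = crop(name)
        patches[name] = raw
        lev = contrast.apply(raw, name)
        for c, weight in enumerate(_RANK_COLORS[rank]):
            rgb[:, :, c] = np.maximum(rgb[:, :, c], lev * weight)
    if counterstain is not None:
        raw = crop(counterstain)
        patches[counterstain] = raw
        lev = contrast.apply(raw, counterstain)
        for c, weight in enumerate(_GREY):
            rgb[:, :, c] = np.maximum(rgb[:, :, c], lev * weight * 0.6)
    if outline is not None:
        opatch = np.zeros((size, size), dtype=bool)
        sy0, sy1 = max(y0, 0), min(y0 + size, h)
        sx0, sx1 = max(x0, 0), min(x0 + size, w)
        opatch[sy0 - y0 : sy1 - y0, sx0 - x0 : sx1 - x0] = (
            np.asarray(outline[sy0:sy1, sx0:sx1]) > 0
        )
        rgb[opatch] = np.maximum(rgb[opatch], 0.35)
    rgb[half, half, :] = 1.0  # white reference pixel at display maximum
    return Thumbnail(
        sample_id=sample_id,
        cell_id=cell_id,
        center=(cx, cy),
        markers=shown + ([counterstain] if counterstain else []),
        rgb=rgb,
        patches=patches,
    )


def curate_gallery(
    handles: dict[str, ImageHandle | ArrayImageHandle],
    table: SpatialFeatureTable,
    result: ClusterResult,
    profile: ClusterProfile,
    contrast: ContrastSettings,
    n_per_cluster: int = 25,
    size: int = 30,
    seed: int = 0,
    outdir: Path | str | None = None,
    outlines: dict[str, np.ndarray] | None = None,
) -> pd.DataFrame:
    """Random per-cluster cell galleries for visual cluster verification.

    For each cluster, up to ``n_per_cluster`` member cells are drawn
    uniformly without replacement (all members if the cluster is smaller) and
    rendered with the cluster's top-3 markers plus the first-cycle
    counterstain. Returns the manifest (cluster, cell, displayed markers);
    when ``outdir`` is given, one PNG grid per cluster is written. The
    manifest is reproducible under the seed.
    """
    rng = np.random.default_rng(seed)
    counterstain = table.counterstain_names[0] if table.counterstain_names else None
    cell_rows = table.data.set_index(["sample_id", "cell_id"])
    keys = np.array(result.keys, dtype=object)
    manifest = []
    thumbs_by_cluster: dict[int, list[Thumbnail]] = {}
    for cluster in sorted(set(result.labels[result.labels >= 0])):
        members = np.flatnonzero(result.labels == cluster)
        n = min(n_per_cluster, members.size)
        chosen = rng.choice(members, size=n, replace=False)
        chosen = np.sort(chosen)
        top3 = top_markers(profile, cluster, k=3, exclude=table.counterstain_names)
        thumbs = []
        for i in chosen:
            sid, cid = keys[i]
            row = cell_rows.loc[(sid, cid)]
            thumb = extract_patch(
                handles[sid],
                (float(row["x"]), float(row["y"])),
                table.markers,
                top3,
                contrast,
                size=size,
                counterstain=counterstain,
                outline=(outlines or {}).get(sid),
                sample_id=sid,
                cell_id=int(cid),
            )
            thumbs.append(thumb)
            manifest.append(
                {
                    "cluster": int(cluster),
                    "sample_id": sid,
                    "cell_id": int(cid),
                    "markers": "|".join(top3),
                }
            )
        thumbs_by_cluster[int(cluster)] = thumbs
    manifest_df = pd.DataFrame(
        manifest, columns=["cluster", "sample_id", "cell_id", "markers"]
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        _write_grids(thumbs_by_cluster, outdir)
        manifest_df.to_csv(outdir / "gallery_manifest.csv", index=False)
    return manifest_df


def _write_grids(thumbs_by_cluster: dict[int, list[Thumbnail]], outdir: Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    for cluster, thumbs in thumbs_by_cluster.items():
        if not thumbs:
            continue
        ncol = min(5, len(thumbs))
        nrow = int(np.ceil(len(thumbs) / ncol))
        fig, axes = plt.subplots(
            nrow, ncol, figsize=(1.2 * ncol, 1.2 * nrow), squeeze=False
        )
        for ax in axes.ravel():
            ax.axis("off")
        for ax, t in zip(axes.ravel(), thumbs):
            ax.imshow(t.rgb, interpolation="nearest")
            ax.set_title(f"{t.cell_id}", fontsize=5)
        fig.suptitle(
            f"cluster {cluster}: " + ", ".join(thumbs[0].markers), fontsize=7
        )
        fig.tight_layout()
        fig.savefig(outdir / f"cluster_{cluster:03d}.png", dpi=120)
        plt.close(fig)
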