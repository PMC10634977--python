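"""Core domain types: markers, samples, feature tables, redaction log, checkpoints.

The spatial feature table is the object every QC module acts on: one row per
segmented cell with its centroid (full-resolution pixel coordinates, x = column,
y = row, 0-based), segmentation area in pixels and per-marker mean intensities
in arbitrary fluorescence units (AFU). Cells are never deleted from the table
during QC; their terminal status (retained / redacted) lives in the
:class:`RedactionLog`, which keeps append-only provenance of which module
removed (or rescued) each cell and why.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    ConsistencyError,
    ParameterError,
    SchemaError,
    StaleCheckpointError,
    ValidationError,
)

RESERVED_COLUMNS = ("sample_id", "cell_id", "x", "y", "area")

# Accepted aliases for the reserved columns when reading third-party CSVs
# (MCMICRO-style quantification tables use CellID / X_centroid / ...).
_COLUMN_ALIASES = {
    "cell_id": ("cell_id", "CellID", "ID", "label"),
    "x": ("x", "X_centroid", "X"),
    "y": ("y", "Y_centroid", "Y"),
    "area": ("area", "Area"),
}


@dataclass(frozen=True)
class MarkerMetadata:
    """One image channel: its marker name, cycle and counterstain role."""

    channel_index: int  # 0-based position in the image stack
    marker_name: str
    cycle_number: int  # 1-based imaging cycle
    is_counterstain: bool = False


def validate_markers(markers: Sequence[MarkerMetadata]) -> None:
    """Check the per-batch marker invariants.

    Exactly one counterstain channel per cycle (cyclic methods re-image the
    nuclear stain every round) and globally unique marker names.
    """
    names = [m.marker_name for m in markers]
    if len(set(names)) != len(names):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate marker names: {dupes}")
    cycles = sorted({m.cycle_number for m in markers})
    for c in cycles:
        n_cs = sum(1 for m in markers if m.cycle_number == c and m.is_counterstain)
        if n_cs != 1:
            raise ValidationError(
                f"cycle {c} has {n_cs} counterstain channels (expected exactly 1)"
            )


def counterstain_markers(markers: Sequence[MarkerMetadata]) -> list[MarkerMetadata]:
    """Counterstain channels ordered by cycle (DNA_1 ... DNA_n)."""
    return sorted(
        (m for m in markers if m.is_counterstain), key=lambda m: m.cycle_number
    )


@dataclass(frozen=True)
class SampleRecord:
    """Pointers to the four per-specimen input files."""

    sample_id: str
    image_path: Path
    mask_path: Path
    table_path: Path
    outline_path: Path | None = None
    pixel_size: float = 0.65  # um / pixel

    def __post_init__(self):
        if self.pixel_size <= 0:
            raise ParameterError("pixel_size must be positive")


class ImageHandle:
    """Lazy per-channel access to a multi-channel TIFF/OME-TIFF.

    Channels are stored as pages (or the leading axis) in metadata order.
    """

    def __init__(self, path: Path | str):
        self.path = Path(path)
        with tifffile.TiffFile(self.path) as tf:
            series = tf.series[0]
            shape = series.shape
        if len(shape) == 2:
            self.n_channels = 1
            self.shape = tuple(shape)
        else:
            self.n_channels = int(shape[0])
            self.shape = tuple(shape[-2:])

    def channel(self, index: int) -> np.ndarray:
        """Read one 2-D channel plane."""
        if not 0 <= index < self.n_channels:
            raise ParameterError(f"channel index {index} out of range")
        if self.n_channels == 1:
            return np.asarray(tifffile.imread(self.path))
        arr = np.asarray(tifffile.imread(self.path, key=index))
        if arr.ndim == 3:  # channels stored interleaved in a single page
            arr = arr[index] if arr.shape[0] == self.n_channels else arr[..., index]
        return arr


class ArrayImageHandle:
    """In-memory stand-in for :class:`ImageHandle` wrapping a (C, H, W) array."""

    def __init__(self, stack: np.ndarray):
        stack = np.asarray(stack)
        if stack.ndim == 2:
            stack = stack[None]
        self.stack = stack
        self.n_channels = stack.shape[0]
        self.shape = stack.shape[1:]

    def channel(self, index: int) -> np.ndarray:
        return self.stack[index]


class SpatialFeatureTable:
    """Per-cell records for one or many samples.

    Wraps a pandas DataFrame with the reserved columns ``sample_id, cell_id,
    x, y, area`` followed by one intensity column per marker, and carries the
    batch's marker metadata.
    """

    def __init__(self, data: pd.DataFrame, markers: Sequence[MarkerMetadata]):
        validate_markers(markers)
        self.markers = list(markers)
        missing = [c for c in RESERVED_COLUMNS if c not in data.columns]
        if missing:
            raise SchemaError(f"missing reserved columns: {missing}")
        for m in self.markers:
            if m.marker_name not in data.columns:
                raise SchemaError(f"missing intensity column: {m.marker_name}")
        cols = list(RESERVED_COLUMNS) + [m.marker_name for m in self.markers]
        self.data = data.loc[:, cols].reset_index(drop=True)
        self._validate()

    # -- construction ------------------------------------------------------

    @classmethod
    def from_csv(
        cls,
        path: Path | str,
        sample_id: str,
        markers: Sequence[MarkerMetadata],
    ) -> "SpatialFeatureTable":
        # round_trip parsing: CSV interchange must be bit-exact
        df = pd.read_csv(path, float_precision="round_trip")
        rename = {}
        for canon, aliases in _COLUMN_ALIASES.items():
            found = [a for a in aliases if a in df.columns]
            if not found:
                raise SchemaError(
                    f"{path}: no column for '{canon}' (accepted: {aliases})"
                )
            rename[found[0]] = canon
        df = df.rename(columns=rename)
        for m in markers:
            if m.marker_name not in df.columns:
                raise SchemaError(f"{path}: missing intensity column: {m.marker_name}")
        if "sample_id" in df.columns:
            df["sample_id"] = sample_id
        else:
            df.insert(0, "sample_id", sample_id)
        return cls(df, markers)

    def _validate(self) -> None:
        df = self.data
        if df.empty:
            return
        if df.duplicated(subset=["sample_id", "cell_id"]).any():
            dup = df[df.duplicated(subset=["sample_id", "cell_id"])]
            raise ValidationError(
                f"duplicate (sample_id, cell_id): {dup[['sample_id', 'cell_id']].values[:5]}"
            )
        if (df["cell_id"] <= 0).any():
            raise ValidationError("cell_id must be a positive integer")
        if (df["area"] <= 0).any():
            raise ValidationError("area must be positive")
        inten = df[self.marker_names]
        if not np.isfinite(inten.to_numpy(dtype=float)).all():
            bad = inten.columns[~np.isfinite(inten.to_numpy(dtype=float)).all(axis=0)]
            raise ValidationError(f"non-finite intensities in: {list(bad)}")
        if (inten.to_numpy(dtype=float) < 0).any():
            raise ValidationError("negative intensity values")

    # -- accessors ---------------------------------------------------------

    @property
    def marker_names(self) -> list[str]:
        return [m.marker_name for m in self.markers]

    @property
    def counterstain_names(self) -> list[str]:
        return [m.marker_name for m in counterstain_markers(self.markers)]

    @property
    def feature_marker_names(self) -> list[str]:
        """Markers used as phenotype features (counterstains excluded)."""
        return [m.marker_name for m in self.markers if not m.is_counterstain]

    @property
    def n_cells(self) -> int:
        return len(self.data)

    def keys(self) -> list[tuple[str, int]]:
        return list(
            zip(self.data["sample_id"].tolist(), self.data["cell_id"].tolist())
        )

    def subset(self, keys: Iterable[tuple[str, int]]) -> "SpatialFeatureTable":
        keyset = set(keys)
        mask = [k in keyset for k in self.keys()]
        return SpatialFeatureTable(self.data.loc[mask].copy(), self.markers)

    def with_data(self, data: pd.DataFrame) -> "SpatialFeatureTable":
        return SpatialFeatureTable(data, self.markers)

    def to_csv(self, path: Path | str) -> None:
        self.data.to_csv(path, index=False)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpatialFeatureTable):
            return NotImplemented
        return self.markers == other.markers and self.data.equals(other.data)


# ---------------------------------------------------------------------------
# Loading and aggregation
# ---------------------------------------------------------------------------


def load_sample(
    record: SampleRecord, markers: Sequence[MarkerMetadata]
) -> tuple[SpatialFeatureTable, np.ndarray, ImageHandle]:
    """Load and cross-validate the four per-specimen inputs.

    Returns the validated feature table, the integer label mask and a lazy
    image handle. Raises :class:`SchemaError` / :class:`ConsistencyError` /
    :class:`ValidationError` on contract violations.
    """
    for p in (record.image_path, record.mask_path, record.table_path):
        if not Path(p).exists():
            raise ConsistencyError(f"{record.sample_id}: missing input file {p}")
    if record.outline_path is not None and not Path(record.outline_path).exists():
        raise ConsistencyError(
            f"{record.sample_id}: missing outline file {record.outline_path}"
        )
    handle = ImageHandle(record.image_path)
    if handle.n_channels != len(markers):
        raise ConsistencyError(
            f"{record.sample_id}: image has {handle.n_channels} channels, "
            f"marker metadata lists {len(markers)}"
        )
    mask = np.asarray(tifffile.imread(record.mask_path))
    if mask.ndim != 2:
        raise ValidationError(f"{record.sample_id}: label mask must be 2-D")
    if mask.shape != handle.shape:
        raise ConsistencyError(
            f"{record.sample_id}: mask shape {mask.shape} != image shape {handle.shape}"
        )
    table = SpatialFeatureTable.from_csv(record.table_path, record.sample_id, markers)
    if table.n_cells:
        labels = np.unique(mask)
        labels = set(labels[labels > 0].tolist())
        missing = sorted(set(table.data["cell_id"].tolist()) - labels)
        if missing:
            raise ConsistencyError(
                f"{record.sample_id}: table cell_ids absent from mask: {missing[:20]}"
            )
        h, w = handle.shape
        x, y = table.data["x"], table.data["y"]
        if ((x < 0) | (x >= w) | (y < 0) | (y >= h)).any():
            raise ValidationError(f"{record.sample_id}: centroid outside image bounds")
    return table, mask, handle


def aggregate_samples(tables: Sequence[SpatialFeatureTable]) -> SpatialFeatureTable:
    """Concatenate per-sample tables into one batch table."""
    if not tables:
        raise ParameterError("no tables to aggregate")
    ref = tables[0]
    for t in tables[1:]:
        a, b = set(ref.marker_names), set(t.marker_names)
        if a != b:
            raise SchemaError(f"marker sets differ: {sorted(a ^ b)}")
    data = pd.concat([t.data for t in tables], ignore_index=True)
    return SpatialFeatureTable(data, ref.markers)


def downsample_channel(channel: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean downsampling by an integer factor.

    Output dimensions are ``ceil(input / factor)`` per axis; partial edge
    blocks are averaged over the pixels they actually contain. Block means
    (rather than striding) suppress single-pixel noise before artifact
    detection.
    """
    if factor < 1 or int(factor) != factor:
        raise ParameterError("downsampling factor must be an integer >= 1")
    factor = int(factor)
    arr = np.asarray(channel, dtype=float)
    if arr.ndim != 2:
        raise ParameterError("channel must be 2-D")
    if factor == 1:
        return arr.copy()
    h, w = arr.shape
    ridx = np.arange(0, h, factor)
    cidx = np.arange(0, w, factor)
    sums = np.add.reduceat(np.add.reduceat(arr, ridx, axis=0), cidx, axis=1)
    rcount = np.minimum(ridx + factor, h) - ridx
    ccount = np.minimum(cidx + factor, w) - cidx
    return sums / np.outer(rcount, ccount)


# ---------------------------------------------------------------------------
# Redaction log
# ---------------------------------------------------------------------------

Key = tuple[str, int]


class RedactionLog:
    """Append-only provenance of per-cell QC decisions.

    Every cell registered with the log has exactly one terminal status
    (retained or redacted). A redaction names the single module responsible;
    a metaQC rescue flips the terminal status back to retained and records
    both the original redaction and the rescue in the event history.
    """

    def __init__(self):
        self._events: list[dict] = []
        self._status: dict[Key, dict] = {}
        self._step = 0

    # -- registration ------------------------------------------------------

    def register(self, keys: Iterable[Key]) -> None:
        for k in keys:
            if k not in self._status:
                self._status[k] = {"retained": True, "module": "input", "detail": ""}

    @classmethod
    def for_table(cls, table: SpatialFeatureTable) -> "RedactionLog":
        log = cls()
        log.register(table.keys())
        return log

    # -- state changes -----------------------------------------------------

    def redact(self, keys: Iterable[Key], module: str, detail: str = "") -> int:
        """Redact currently retained cells; already-redacted cells are untouched.

        Returns the number of cells whose status changed.
        """
        self._step += 1
        n = 0
        for k in keys:
            st = self._status.get(k)
            if st is None or not st["retained"]:
                continue
            st.update(retained=False, module=module, detail=detail)
            self._events.append(
                {
                    "sample_id": k[0],
                    "cell_id": k[1],
                    "status": "redacted",
                    "module": module,
                    "step_ordinal": self._step,
                    "detail": detail,
                }
            )
            n += 1
        return n

    def rescue(self, keys: Iterable[Key], module: str = "metaQC", detail: str = "") -> int:
        """Flip redacted cells back to retained (metaQC rescue)."""
        self._step += 1
        n = 0
        for k in keys:
            st = self._status.get(k)
            if st is None or st["retained"]:
                continue
            prior = st["module"]
            st.update(retained=True, module=module, detail=f"rescued from {prior}")
            self._events.append(
                {
                    "sample_id": k[0],
                    "cell_id": k[1],
                    "status": "retained",
                    "module": module,
                    "step_ordinal": self._step,
                    "detail": f"{detail or 'rescue'} (was: {prior})",
                }
            )
            n += 1
        return n

    # -- queries -----------------------------------------------------------

    def is_retained(self, key: Key) -> bool:
        return self._status[key]["retained"]

    def retained_keys(self) -> list[Key]:
        return [k for k, st in self._status.items() if st["retained"]]

    def redacted_keys(self) -> list[Key]:
        return [k for k, st in self._status.items() if not st["retained"]]

    def retained_mask(self, table: SpatialFeatureTable) -> np.ndarray:
        return np.array([self.is_retained(k) for k in table.keys()], dtype=bool)

    @property
    def n_cells(self) -> int:
        return len(self._status)

    def status_frame(self) -> pd.DataFrame:
        """Terminal status per cell, ordered by (sample_id, cell_id)."""
        rows = [
            {
                "sample_id": k[0],
                "cell_id": k[1],
                "status": "retained" if st["retained"] else "redacted",
                "module": st["module"],
                "detail": st["detail"],
            }
            for k, st in sorted(self._status.items())
        ]
        return pd.DataFrame(
            rows, columns=["sample_id", "cell_id", "status", "module", "detail"]
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._events,
            columns=["sample_id", "cell_id", "status", "module", "step_ordinal", "detail"],
        )

    def gross_redactions_by_module(self) -> dict[str, int]:
        """Redaction events per module, including cells later rescued."""
        out: dict[str, int] = {}
        for e in self._events:
            if e["status"] == "redacted":
                out[e["module"]] = out.get(e["module"], 0) + 1
        return out

    def n_rescued(self) -> int:
        return sum(1 for e in self._events if e["status"] == "retained")

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, RedactionLog):
            return NotImplemented
        return self._events == other._events and self._status == other._status


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------


@dataclass
class PipelineState:
    """Everything needed to resume a run: table, log, completed modules."""

    table: SpatialFeatureTable
    log: RedactionLog
    completed: list[str] = field(default_factory=list)
    module_hashes: dict[str, str] = field(default_factory=dict)
    seed: int = 0


def save_checkpoint(state: PipelineState, path: Path | str) -> None:
    """Serialize the pipeline state to a single inspectable zip archive.

    The archive holds the table (CSV), the event log + terminal statuses
    (CSV), and a JSON header with the per-module config hashes of already
    executed modules.
    """
    path = Path(path)
    header = {
        "completed": state.completed,
        "module_hashes": state.module_hashes,
        "seed": state.seed,
        "step": state.log._step,
        "markers": [
            {
                "channel_index": m.channel_index,
                "marker_name": m.marker_name,
                "cycle_number": m.cycle_number,
                "is_counterstain": m.is_counterstain,
            }
            for m in state.table.markers
        ],
    }
    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("header.json", json.dumps(header, indent=1, sort_keys=True))
        buf = io.StringIO()
        state.table.data.to_csv(buf, index=False)
        zf.writestr("table.csv", buf.getvalue())
        buf = io.StringIO()
        state.log.events_frame().to_csv(buf, index=False)
        zf.writestr("events.csv", buf.getvalue())
        buf = io.StringIO()
        state.log.status_frame().to_csv(buf, index=False)
        zf.writestr("status.csv", buf.getvalue())


def load_checkpoint(
    path: Path | str, current_hashes: dict[str, str] | None = None
) -> PipelineState:
    """Load a checkpoint, verifying executed-module config hashes.

    Only modules recorded as completed are checked against ``current_hashes``;
    editing a downstream module's parameters does not invalidate the
    checkpoint.
    """
    path = Path(path)
    try:
        with zipfile.ZipFile(path) as zf:
            header = json.loads(zf.read("header.json"))
            table_df = pd.read_csv(
                io.BytesIO(zf.read("table.csv")), float_precision="round_trip"
            )
            events = pd.read_csv(
                io.BytesIO(zf.read("events.csv")),
                dtype={"detail": str},
                keep_default_na=False,
            )
            status = pd.read_csv(
                io.BytesIO(zf.read("status.csv")),
                dtype={"detail": str},
                keep_default_na=False,
            )
    except (zipfile.BadZipFile, KeyError, OSError) as exc:
        raise IOError(f"corrupt checkpoint: {path}") from exc
    if current_hashes is not None:
        for mod in header["completed"]:
            saved = header["module_hashes"].get(mod)
            if saved != current_hashes.get(mod):
                raise StaleCheckpointError(
                    f"checkpoint is stale: parameters of executed module '{mod}' changed"
                )
    markers = [MarkerMetadata(**m) for m in header["markers"]]
    table = SpatialFeatureTable(table_df, markers)
    log = RedactionLog()
    log.register(table.keys())
    for _, row in events.iterrows():
        key = [(row["sample_id"], int(row["cell_id"]))]
        if row["status"] == "redacted":
            log.redact(key, row["module"], row["detail"])
        else:
            log.rescue(key, row["module"], row["detail"])
    # restore terminal details verbatim (rescue re-derivation may differ in text)
    for _, row in status.iterrows():
        st = log._status[(row["sample_id"], int(row["cell_id"]))]
        st["module"] = row["module"]
        st["detail"] = row["detail"]
        st["retained"] = row["status"] == "retained"
    log._events = [
        {
            "sample_id": r["sample_id"],
            "cell_id": int(r["cell_id"]),
            "status": r["status"],
            "module": r["module"],
            "step_ordinal": int(r["step_ordinal"]),
            "detail": r["detail"],
        }
        for _, r in events.iterrows()
    ]
    log._step = int(header.get("step", events["step_ordinal"].max() if len(events) else 0))
    return PipelineState(
        table=table,
        log=log,
        completed=list(header["completed"]),
        module_hashes=dict(header["module_hashes"]),
        seed=int(header["seed"]),
    )
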