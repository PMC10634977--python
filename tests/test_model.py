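"""Data model: loading, validation, aggregation, downsampling, checkpoints."""

import numpy as np
import pandas as pd
import pytest
import tifffile
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays

from plexqc import (
    MarkerMetadata,
    PipelineState,
    RedactionLog,
    SampleRecord,
    SpatialFeatureTable,
    aggregate_samples,
    downsample_channel,
    load_checkpoint,
    load_sample,
    save_checkpoint,
)
from plexqc.errors import (
    ConsistencyError,
    ParameterError,
    SchemaError,
    StaleCheckpointError,
    ValidationError,
)
from plexqc.model import validate_markers

from conftest import make_table


def _write_sample_files(tmp_path, df, markers, mask=None, n_channels=None):
    n_channels = n_channels or len(markers)
    h = w = 64
    img = np.full((n_channels, h, w), 100, dtype=np.float32)
    if mask is None:
        mask = np.zeros((h, w), dtype=np.int32)
        ids = df["CellID"] if "CellID" in df.columns else df.get("cell_id", [])
        for cid in ids:
            mask[int(cid), int(cid)] = int(cid)
    tifffile.imwrite(tmp_path / "image.tif", img, photometric="minisblack")
    tifffile.imwrite(tmp_path / "mask.tif", mask)
    df.to_csv(tmp_path / "table.csv", index=False)
    return SampleRecord(
        sample_id="s1",
        image_path=tmp_path / "image.tif",
        mask_path=tmp_path / "mask.tif",
        table_path=tmp_path / "table.csv",
    )


class TestMarkerInvariants:
    def test_one_counterstain_per_cycle_enforced(self):
        with pytest.raises(ValidationError, match="cycle 1"):
            validate_markers(
                [MarkerMetadata(0, "A", 1, False), MarkerMetadata(1, "B", 1, False)]
            )
        with pytest.raises(ValidationError, match="counterstain"):
            validate_markers(
                [MarkerMetadata(0, "DNA", 1, True), MarkerMetadata(1, "DNA2", 1, True)]
            )

    def test_duplicate_marker_names_rejected(self):
        with pytest.raises(ValidationError, match="duplicate"):
            validate_markers(
                [MarkerMetadata(0, "X", 1, True), MarkerMetadata(1, "X", 1, False)]
            )


class TestLoadSample:
    def _df(self, cell_ids, markers):
        df = pd.DataFrame(
            {
                "CellID": cell_ids,
                "X_centroid": [float(c) for c in cell_ids],
                "Y_centroid": [float(c) for c in cell_ids],
                "Area": [5] * len(cell_ids),
            }
        )
        for m in markers:
            df[m.marker_name] = 10.0
        return df

    def test_empty_table_loads_without_error(self, tmp_path, simple_markers):
        df = self._df([], simple_markers)
        rec = _write_sample_files(tmp_path, df, simple_markers)
        table, mask, handle = load_sample(rec, simple_markers)
        assert table.n_cells == 0
        assert handle.n_channels == 3

    def test_row_count_preserved(self, tmp_path, simple_markers):
        df = self._df([1, 2, 3], simple_markers)
        rec = _write_sample_files(tmp_path, df, simple_markers)
        table, _, _ = load_sample(rec, simple_markers)
        assert table.n_cells == 3

    def test_missing_intensity_column_names_it(self, tmp_path, simple_markers):
        df = self._df([1, 2], simple_markers).drop(columns=["B"])
        rec = _write_sample_files(tmp_path, df, simple_markers)
        with pytest.raises(SchemaError, match="B"):
            load_sample(rec, simple_markers)

    def test_table_id_absent_from_mask_names_offender(self, tmp_path, simple_markers):
        df = self._df([1, 2, 4], simple_markers)
        mask = np.zeros((64, 64), dtype=np.int32)
        for cid in (1, 2, 3):
            mask[cid, cid] = cid
        rec = _write_sample_files(tmp_path, df, simple_markers, mask=mask)
        with pytest.raises(ConsistencyError, match="4"):
            load_sample(rec, simple_markers)

    def test_nonfinite_intensity_rejected(self, tmp_path, simple_markers):
        df = self._df([1, 2], simple_markers)
        df.loc[0, "A"] = np.nan
        rec = _write_sample_files(tmp_path, df, simple_markers)
        with pytest.raises(ValidationError, match="A"):
            load_sample(rec, simple_markers)

    def test_channel_count_mismatch(self, tmp_path, simple_markers):
        df = self._df([1], simple_markers)
        rec = _write_sample_files(tmp_path, df, simple_markers, n_channels=5)
        with pytest.raises(ConsistencyError, match="channels"):
            load_sample(rec, simple_markers)

    def test_row_order_insensitive(self, tmp_path, simple_markers):
        df = self._df([1, 2, 3], simple_markers)
        rec = _write_sample_files(tmp_path, df, simple_markers)
        t1, _, _ = load_sample(rec, simple_markers)
        df.iloc[::-1].to_csv(tmp_path / "table.csv", index=False)
        t2, _, _ = load_sample(rec, simple_markers)
        a = t1.data.sort_values("cell_id").reset_index(drop=True)
        b = t2.data.sort_values("cell_id").reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)

    def test_csv_round_trip_identical(self, tmp_path, simple_markers):
        rng = np.random.default_rng(0)
        table = make_table(
            {"DNA_1": rng.uniform(0, 5000, 20), "A": rng.lognormal(5, 1, 20),
             "B": rng.uniform(0, 1, 20)},
            simple_markers,
        )
        table.to_csv(tmp_path / "t.csv")
        back = SpatialFeatureTable.from_csv(tmp_path / "t.csv", "s1", simple_markers)
        pd.testing.assert_frame_equal(table.data, back.data)


class TestAggregate:
    def test_row_counts_sum(self, simple_markers):
        t1 = make_table({"DNA_1": np.ones(10), "A": np.ones(10), "B": np.ones(10)},
                        simple_markers, sample_id="a")
        t2 = make_table({"DNA_1": np.ones(20), "A": np.ones(20), "B": np.ones(20)},
                        simple_markers, sample_id="b")
        agg = aggregate_samples([t1, t2])
        assert agg.n_cells == 30
        assert set(agg.data["sample_id"]) == {"a", "b"}

    def test_single_table_is_identity(self, simple_markers):
        t = make_table({"DNA_1": np.ones(5), "A": np.ones(5), "B": np.ones(5)},
                       simple_markers)
        pd.testing.assert_frame_equal(aggregate_samples([t]).data, t.data)

    def test_marker_mismatch_names_symmetric_difference(self):
        m1 = [MarkerMetadata(0, "DNA_1", 1, True), MarkerMetadata(1, "A", 1, False)]
        m2 = [MarkerMetadata(0, "DNA_1", 1, True), MarkerMetadata(1, "C", 1, False)]
        t1 = make_table({"DNA_1": np.ones(3), "A": np.ones(3)}, m1, sample_id="a")
        t2 = make_table({"DNA_1": np.ones(3), "C": np.ones(3)}, m2, sample_id="b")
        with pytest.raises(SchemaError, match="'A', 'C'"):
            aggregate_samples([t1, t2])

    def test_split_then_aggregate_restores_table(self, simple_markers):
        rng = np.random.default_rng(1)
        parts = [
            make_table(
                {"DNA_1": rng.uniform(size=7), "A": rng.uniform(size=7),
                 "B": rng.uniform(size=7)},
                simple_markers, sample_id=s,
            )
            for s in ("a", "b", "c")
        ]
        whole = aggregate_samples(parts)
        split = [
            whole.with_data(whole.data[whole.data["sample_id"] == s])
            for s in ("a", "b", "c")
        ]
        pd.testing.assert_frame_equal(aggregate_samples(split).data, whole.data)


class TestDownsample:
    def test_factor_one_is_identity(self):
        a = np.arange(12.0).reshape(3, 4)
        assert np.array_equal(downsample_channel(a, 1), a)

    def test_constant_grid_preserved(self):
        out = downsample_channel(np.full((4, 4), 7.0), 2)
        assert out.shape == (2, 2)
        assert np.array_equal(out, np.full((2, 2), 7.0))

    def test_known_block_means(self):
        a = np.arange(16.0).reshape(4, 4)
        out = downsample_channel(a, 2)
        expected = np.array([[np.mean(a[0:2, 0:2]), np.mean(a[0:2, 2:4])],
                             [np.mean(a[2:4, 0:2]), np.mean(a[2:4, 2:4])]])
        assert np.array_equal(out, expected)

    def test_factor_below_one_rejected(self):
        with pytest.raises(ParameterError):
            downsample_channel(np.ones((4, 4)), 0)

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        arr=arrays(np.float64, (7, 9),
                   elements=st.floats(0, 1e4, allow_nan=False)),
        factor=st.integers(1, 5),
    )
    def test_matches_per_block_averaging(self, arr, factor):
        """Every output pixel equals the mean of its (possibly partial) block."""
        out = downsample_channel(arr, factor)
        h, w = arr.shape
        assert out.shape == (int(np.ceil(h / factor)), int(np.ceil(w / factor)))
        for i in range(out.shape[0]):
            for j in range(out.shape[1]):
                block = arr[i * factor : (i + 1) * factor, j * factor : (j + 1) * factor]
                assert out[i, j] == pytest.approx(block.mean(), rel=1e-12)


class TestCheckpoint:
    def _state(self, simple_markers):
        rng = np.random.default_rng(3)
        table = make_table(
            {"DNA_1": rng.uniform(0, 5e3, 10), "A": rng.uniform(size=10),
             "B": rng.uniform(size=10)},
            simple_markers,
        )
        log = RedactionLog.for_table(table)
        log.redact([("s1", 1), ("s1", 2)], "selectROIs", "negative ROI")
        log.rescue([("s1", 2)], "metaQC")
        return PipelineState(
            table=table, log=log, completed=["selectROIs"],
            module_hashes={"selectROIs": "abc"}, seed=7,
        )

    def test_round_trip_equal_state(self, tmp_path, simple_markers):
        state = self._state(simple_markers)
        save_checkpoint(state, tmp_path / "c.zip")
        back = load_checkpoint(tmp_path / "c.zip", {"selectROIs": "abc"})
        pd.testing.assert_frame_equal(back.table.data, state.table.data)
        pd.testing.assert_frame_equal(
            back.log.status_frame(), state.log.status_frame()
        )
        pd.testing.assert_frame_equal(
            back.log.events_frame(), state.log.events_frame()
        )
        assert back.completed == state.completed
        assert back.seed == 7

    def test_downstream_edit_allowed(self, tmp_path, simple_markers):
        state = self._state(simple_markers)
        save_checkpoint(state, tmp_path / "c.zip")
        load_checkpoint(
            tmp_path / "c.zip", {"selectROIs": "abc", "clustering": "zzz"}
        )

    def test_executed_edit_rejected(self, tmp_path, simple_markers):
        state = self._state(simple_markers)
        save_checkpoint(state, tmp_path / "c.zip")
        with pytest.raises(StaleCheckpointError, match="selectROIs"):
            load_checkpoint(tmp_path / "c.zip", {"selectROIs": "CHANGED"})

    def test_corrupt_file_raises_io_error(self, tmp_path):
        (tmp_path / "bad.zip").write_bytes(b"not a zip archive")
        with pytest.raises(IOError):
            load_checkpoint(tmp_path / "bad.zip", {})
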