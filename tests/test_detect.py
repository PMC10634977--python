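"""Artifact detector: morphology oracles, flood fill, masks, redaction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import scipy.ndimage as ndi

from plexqc import (
    DetectionParams,
    RedactionLog,
    build_artifact_mask,
    detect_channel,
    find_seed_points,
    flood_fill_region,
    redact_by_mask,
    transform_channel,
)
from plexqc.detect import disk_footprint, rescale_to_uint8
from plexqc.errors import ParameterError

from conftest import make_table


# ---------------------------------------------------------------------------
# brute-force oracles
# ---------------------------------------------------------------------------


def _windows(arr, fp):
    """All disk neighborhoods of arr under reflect (symmetric) padding."""
    r = fp.shape[0] // 2
    padded = np.pad(arr.astype(float), r, mode="symmetric")
    win = np.lib.stride_tricks.sliding_window_view(padded, fp.shape)
    return win[..., fp]  # (H, W, n_in_disk)


def brute_min(arr, fp):
    return _windows(arr, fp).min(axis=-1)


def brute_max(arr, fp):
    return _windows(arr, fp).max(axis=-1)


def brute_mean(arr, fp):
    return _windows(arr, fp).mean(axis=-1)


def bfs_flood(grid, seed, tol):
    """Breadth-first 8-connected region growth from the seed."""
    from collections import deque

    h, w = grid.shape
    x0, y0 = seed
    v0 = int(grid[y0, x0])
    seen = np.zeros_like(grid, dtype=bool)
    seen[y0, x0] = True
    q = deque([(y0, x0)])
    while q:
        y, x = q.popleft()
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                ny, nx = y + dy, x + dx
                if 0 <= ny < h and 0 <= nx < w and not seen[ny, nx]:
                    if abs(int(grid[ny, nx]) - v0) <= tol:
                        seen[ny, nx] = True
                        q.append((ny, nx))
    return seen


# ---------------------------------------------------------------------------
# morphology stages
# ---------------------------------------------------------------------------


class TestMorphologyStages:
    @pytest.mark.parametrize("n_grids", [50])
    def test_each_stage_equals_brute_force_disk_neighborhood(self, n_grids):
        """Erosion/local-mean/dilation equal per-pixel min/mean/max over the
        reflect-padded disk neighborhood on random grids."""
        rng = np.random.default_rng(7)
        fp = disk_footprint(5)
        for _ in range(n_grids):
            g = rng.integers(0, 256, size=(32, 32)).astype(np.uint8)
            ero = ndi.grey_erosion(g, footprint=fp, mode="reflect")
            assert np.array_equal(ero, brute_min(g, fp))
            dil = ndi.grey_dilation(g, footprint=fp, mode="reflect")
            assert np.array_equal(dil, brute_max(g, fp))
            mean = ndi.correlate(g.astype(float), fp / fp.sum(), mode="reflect")
            assert np.allclose(mean, brute_mean(g, fp), atol=1e-9)

    def test_constant_grid_transforms_to_constant(self):
        out = transform_channel(np.full((64, 64), 13.0), DetectionParams())
        assert (out == out.flat[0]).all()

    def test_single_bright_pixel_removed_by_erosion(self):
        g = np.zeros((40, 40))
        g[20, 20] = 1000.0
        p = DetectionParams(downsample_factor=1, kernel_diameter=5)
        out = transform_channel(g, p)
        assert out[20, 20] == out[0, 0]  # back at background level

    def test_constant_channel_rescales_to_zero(self):
        assert (rescale_to_uint8(np.full((8, 8), 42.0)) == 0).all()


# ---------------------------------------------------------------------------
# seeds
# ---------------------------------------------------------------------------


class TestSeeds:
    def test_flat_background_has_no_seeds(self):
        g = np.zeros((50, 50), dtype=np.uint8)
        assert find_seed_points(g, DetectionParams()) == []

    def test_single_plateau_single_seed(self):
        g = np.zeros((60, 60), dtype=np.uint8)
        g[20:30, 20:30] = 200
        seeds = find_seed_points(g, DetectionParams(kernel_diameter=5))
        assert len(seeds) == 1
        x, y = seeds[0]
        assert (20, 20) == (y, x)  # lexicographically smallest plateau pixel

    def test_two_distant_discs_two_seeds_matching_exhaustive_scan(self):
        g = np.zeros((120, 120), dtype=np.uint8)
        yy, xx = np.mgrid[:120, :120]
        d1 = (yy - 25) ** 2 + (xx - 25) ** 2 <= 64
        d2 = (yy - 95) ** 2 + (xx - 95) ** 2 <= 64
        g[d1] = 180
        g[d2] = 220
        p = DetectionParams(kernel_diameter=5, seed_expansion=2.0)
        seeds = find_seed_points(g, p)
        assert len(seeds) == 2
        assert any(d1[y, x] for x, y in seeds) and any(d2[y, x] for x, y in seeds)
        # independent exhaustive local-maxima scan: every seed must dominate
        # its expanded neighborhood and clear the floor
        fp = disk_footprint(10)
        mx = brute_max(g, fp)
        for x, y in seeds:
            assert g[y, x] == mx[y, x] and g[y, x] > p.intensity_floor

    def test_seeds_below_floor_rejected(self):
        g = np.zeros((40, 40), dtype=np.uint8)
        g[10:20, 10:20] = 30  # below default floor of 50
        assert find_seed_points(g, DetectionParams()) == []


# ---------------------------------------------------------------------------
# flood fill
# ---------------------------------------------------------------------------


class TestFloodFill:
    def test_constant_grid_tolerance_zero_fills_everything(self):
        g = np.full((12, 12), 77, dtype=np.uint8)
        assert flood_fill_region(g, (5, 5), 0).all()

    def test_isolated_seed_fills_only_itself(self):
        g = np.full((9, 9), 10, dtype=np.uint8)
        g[4, 4] = 200
        region = flood_fill_region(g, (4, 4), 50)
        assert region[4, 4] and region.sum() == 1

    def test_negative_tolerance_rejected(self):
        with pytest.raises(ParameterError):
            flood_fill_region(np.zeros((4, 4), np.uint8), (1, 1), -1)

    @pytest.mark.parametrize("trial", range(50))
    def test_matches_bfs_region_growth(self, trial):
        rng = np.random.default_rng(100 + trial)
        g = rng.integers(0, 40, size=(16, 16)).astype(np.uint8)
        seed = (int(rng.integers(0, 16)), int(rng.integers(0, 16)))
        tol = int(rng.integers(0, 25))
        assert np.array_equal(
            flood_fill_region(g, seed, tol), bfs_flood(g, seed, tol)
        )

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 10_000), t1=st.integers(0, 30), t2=st.integers(0, 30))
    def test_region_monotone_in_tolerance(self, seed, t1, t2):
        if t1 > t2:
            t1, t2 = t2, t1
        rng = np.random.default_rng(seed)
        g = rng.integers(0, 60, size=(12, 12)).astype(np.uint8)
        small = flood_fill_region(g, (6, 6), t1)
        big = flood_fill_region(g, (6, 6), t2)
        assert (small <= big).all()


# ---------------------------------------------------------------------------
# mask building and redaction
# ---------------------------------------------------------------------------


class TestArtifactMask:
    def test_no_regions_all_false(self):
        am = build_artifact_mask([], (64, 64), 4)
        assert am.mask.shape == (64, 64) and not am.mask.any()

    def test_union_area_bounds(self):
        r1 = np.zeros((16, 16), bool)
        r2 = np.zeros((16, 16), bool)
        r1[2:8, 2:8] = True
        r2[5:12, 5:12] = True
        am = build_artifact_mask([r1, r2], (16, 16), 1)
        assert max(r1.sum(), r2.sum()) <= am.area <= r1.sum() + r2.sum()

    def test_upscale_expands_each_pixel_to_factor_block(self):
        rng = np.random.default_rng(0)
        work = rng.random((64, 64)) < 0.2
        am = build_artifact_mask([work], (256, 256), 4)
        expected = np.repeat(np.repeat(work, 4, axis=0), 4, axis=1)
        assert np.array_equal(am.mask, expected)

    def test_seeds_rescaled_and_inside_mask(self):
        work = np.zeros((8, 8), bool)
        work[3:6, 2:5] = True
        am = build_artifact_mask([work], (32, 32), 4, seeds=[(3, 4)])
        assert am.seeds == [(12, 16)]
        assert am.mask[16, 12]


class TestRedactByMask:
    def _setup(self, simple_markers):
        t = make_table(
            {"DNA_1": np.ones(3), "A": np.ones(3), "B": np.ones(3)},
            simple_markers, x=np.array([5.0, 20.0, 40.0]),
            y=np.array([5.0, 20.0, 40.0]),
        )
        return t, RedactionLog.for_table(t)

    def test_all_false_mask_no_redactions(self, simple_markers):
        t, log = self._setup(simple_markers)
        assert redact_by_mask(t, log, np.zeros((64, 64), bool)) == 0

    def test_centroid_lookup(self, simple_markers):
        t, log = self._setup(simple_markers)
        m = np.zeros((64, 64), bool)
        m[18:25, 18:25] = True
        assert redact_by_mask(t, log, m, detail="chan") == 1
        assert set(log.redacted_keys()) == {("s1", 2)}

    def test_previously_redacted_cell_keeps_provenance(self, simple_markers):
        t, log = self._setup(simple_markers)
        log.redact([("s1", 2)], "selectROIs", "negative ROI")
        m = np.ones((64, 64), bool)
        redact_by_mask(t, log, m)
        status = log.status_frame().set_index("cell_id")
        assert status.loc[2, "module"] == "selectROIs"
        assert (status.loc[[1, 3], "module"] == "artifactDetect").all()


# ---------------------------------------------------------------------------
# end-to-end on planted artifacts
# ---------------------------------------------------------------------------


class TestEndToEnd:
    def test_planted_artifacts_recovered(self, detection_dataset):
        """Default parameters find the planted aggregate and fold with one or
        more seeds each and IoU >= 0.6 vs the ground-truth masks."""
        markers = detection_dataset["markers"]
        images = detection_dataset["images"]
        gt = detection_dataset["gt"]
        p = DetectionParams()
        union = np.zeros(images.shape[1:], dtype=bool)
        for m in markers:
            union |= detect_channel(images[m.channel_index], p, m.marker_name).mask
        lab, ncomp = ndi.label(union)
        assert ncomp == 2
        for name in ("aggregate_1", "fold_1"):
            gmask = gt.artifact_masks[name]
            best = max(
                ((lab == c) & gmask).sum() / ((lab == c) | gmask).sum()
                for c in range(1, ncomp + 1)
            )
            assert best >= 0.6, f"{name} IoU {best:.3f}"

    def test_artifact_free_channel_yields_tiny_mask(self, clean_dataset):
        """Specificity: on artifact-free channels the mask covers <= 0.5%."""
        markers = clean_dataset["markers"]
        images = clean_dataset["images"]
        p = DetectionParams()
        total = 0
        for m in markers:
            total += detect_channel(images[m.channel_index], p, m.marker_name).area
        assert total <= 0.005 * images.shape[1] * images.shape[2]
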