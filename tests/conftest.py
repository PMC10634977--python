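"""Shared fixtures: synthetic study datasets reused across test modules."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

from plexqc import (
    MarkerMetadata,
    RedactionLog,
    SpatialFeatureTable,
)
from plexqc.synthetic import (
    ArtifactSpec,
    SynthParams,
    default_artifact_plan,
    generate_dataset,
)


@pytest.fixture(scope="session")
def detection_dataset():
    """1024x1024, 500 cells, planted aggregate + fold + 20% detachment."""
    params = SynthParams(artifacts=tuple(default_artifact_plan()), seed=0)
    images, markers, mask, table, gt = generate_dataset(params)
    return {
        "params": params,
        "images": images,
        "markers": markers,
        "mask": mask,
        "table": table,
        "gt": gt,
    }


@pytest.fixture(scope="session")
def clean_dataset():
    """Artifact-free replicate: same conditions, empty artifact plan."""
    params = SynthParams(seed=0)
    images, markers, mask, table, gt = generate_dataset(params)
    return {
        "params": params,
        "images": images,
        "markers": markers,
        "mask": mask,
        "table": table,
        "gt": gt,
    }


def make_table(
    intensities: dict[str, np.ndarray],
    markers: list[MarkerMetadata],
    x: np.ndarray | None = None,
    y: np.ndarray | None = None,
    sample_id: str = "s1",
) -> SpatialFeatureTable:
    """Build a minimal feature table directly from intensity vectors."""
    n = len(next(iter(intensities.values())))
    data = pd.DataFrame(
        {
            "sample_id": sample_id,
            "cell_id": np.arange(1, n + 1),
            "x": x if x is not None else np.linspace(1, 99, n),
            "y": y if y is not None else np.linspace(1, 99, n),
            "area": 50,
        }
    )
    for k, v in intensities.items():
        data[k] = np.asarray(v, dtype=float)
    return SpatialFeatureTable(data, markers)


@pytest.fixture
def simple_markers():
    return [
        MarkerMetadata(0, "DNA_1", 1, True),
        MarkerMetadata(1, "A", 1, False),
        MarkerMetadata(2, "B", 1, False),
    ]


@pytest.fixture
def fresh_log():
    def _make(table: SpatialFeatureTable) -> RedactionLog:
        return RedactionLog.for_table(table)

    return _make


# ---------------------------------------------------------------------------
# full-pipeline fixtures shared by the orchestration and acceptance suites
# ---------------------------------------------------------------------------


def pipeline_marker_entries():
    entries = []
    m = 0
    for c in range(1, 4):
        entries.append({"name": f"DNA_{c}", "cycle": c, "counterstain": True})
        for _ in range(3):
            entries.append({"name": f"M{m:02d}", "cycle": c})
            m += 1
    return entries


def pipeline_config(paths, seed=5, overrides=None):
    from plexqc import QCConfig
    from plexqc.config import CANONICAL_ORDER

    raw = {
        "seed": seed,
        "modules": list(CANONICAL_ORDER),
        "samples": [
            {"sample_id": "s1", "image": str(paths["image"]),
             "mask": str(paths["mask"]), "table": str(paths["table"]),
             "outline": str(paths["outline"])}
        ],
        "markers": pipeline_marker_entries(),
        "artifactDetect": {"kernel_diameter": 9},
        "dnaIntensity": {"lower": 500},
        "areaFilter": {"upper": 120},
        "cycleCorrelation": {"lower": -0.5, "upper": 0.5},
        "pruneOutliers": {"cutoffs": [{"marker": "M00", "p_lo": 0.1,
                                       "p_hi": 99.9}]},
        "clustering": {"min_cluster_size": 15},
        "curateThumbnails": {"n_per_cluster": 3},
    }
    raw.update(overrides or {})
    return QCConfig.from_dict(raw)


@pytest.fixture(scope="session")
def sample_on_disk(tmp_path_factory):
    """A 512x512 specimen with aggregate, fold and detachment, on disk."""
    from plexqc.synthetic import write_sample

    root = tmp_path_factory.mktemp("pipe")
    params = SynthParams(
        shape=(512, 512), n_cells=300, cell_radius=5, seed=11,
        artifacts=(
            ArtifactSpec("aggregate", {"center": (120, 120), "radius": 55,
                                       "channel": "M00"}),
            ArtifactSpec("fold", {"vertices": [(250, 220), (470, 240),
                                               (480, 460), (260, 470)]}),
            ArtifactSpec("detachment", {"fraction": 0.15, "after_cycle": 2}),
        ),
    )
    paths = write_sample(root / "sample", params, "s1")
    return root, paths, params


@pytest.fixture(scope="session")
def reference_run(sample_on_disk):
    """One full pipeline execution, reused as the determinism reference."""
    from plexqc import run_pipeline

    root, paths, _ = sample_on_disk
    cfg = pipeline_config(paths)
    run = run_pipeline(cfg, root / "ref")
    return root, paths, cfg, run
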