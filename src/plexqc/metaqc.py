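"""metaQC: audit gating bias by clustering redacted and retained cells together.

Human-guided QC is subject to error and bias in both directions. The metaQC
step samples an equal-parts pool of redacted ("noisy") and retained ("clean")
cells, clusters the pool on its marker profiles with the same
embedding + HDBSCAN chain as the clustering module, and reclassifies pooled
cells by their cluster's composition: noisy-origin cells in predominantly
clean clusters are rescued back into the dataset, clean-origin cells in
predominantly noisy clusters are dropped. "Predominantly" is the threshold
``t`` (default 0.5 = simple majority). Decisions apply to pooled cells only —
labels are not extrapolated to unsampled cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .clustering import cluster_cells, embed_cells
from .errors import ParameterError
from .gates import rescale_unit_interval
from .model import Key, RedactionLog, SpatialFeatureTable

__all__ = ["QCPool", "ReclassDecision", "sample_qc_pool", "reclassify", "run_metaqc"]


@dataclass
class QCPool:
    """Equal-parts sample of retained (clean) and redacted (noisy) cells."""

    cells: pd.DataFrame  # columns: sample_id, cell_id, origin ("clean"|"noisy")
    fraction: float
    seed: int

    @property
    def keys(self) -> list[Key]:
        return [
            (s, int(c))
            for s, c in zip(self.cells["sample_id"], self.cells["cell_id"])
        ]


@dataclass
class ReclassDecision:
    """Per-cell keep/rescue/drop decisions and per-cluster composition."""

    decisions: pd.DataFrame  # sample_id, cell_id, origin, cluster, action
    cluster_stats: pd.DataFrame = field(default_factory=pd.DataFrame)

    def rescued_keys(self) -> list[Key]:
        d = self.decisions
        sel = d[d["action"] == "rescue"]
        return [(s, int(c)) for s, c in zip(sel["sample_id"], sel["cell_id"])]

    def dropped_keys(self) -> list[Key]:
        d = self.decisions
        sel = d[d["action"] == "drop"]
        return [(s, int(c)) for s, c in zip(sel["sample_id"], sel["cell_id"])]


def sample_qc_pool(
    retained: list[Key],
    redacted: list[Key],
    fraction: float = 1.0,
    seed: int = 0,
) -> QCPool | None:
    """Draw ``floor(fraction * min(|retained|, |redacted|))`` cells from each set.

    Uniform draws without replacement; reproducible under the seed. Returns
    ``None`` when the redacted set is empty (nothing to audit).
    """
    if not 0 < fraction <= 1:
        raise ParameterError("fraction must be in (0, 1]")
    if len(redacted) == 0 or len(retained) == 0:
        return None
    m = int(np.floor(fraction * min(len(retained), len(redacted))))
    if m == 0:
        return None
    rng = np.random.default_rng(seed)
    retained = sorted(retained)
    redacted = sorted(redacted)
    pick_clean = rng.choice(len(retained), size=m, replace=False)
    pick_noisy = rng.choice(len(redacted), size=m, replace=False)
    rows = [
        {"sample_id": retained[i][0], "cell_id": retained[i][1], "origin": "clean"}
        for i in sorted(pick_clean)
    ] + [
        {"sample_id": redacted[i][0], "cell_id": redacted[i][1], "origin": "noisy"}
        for i in sorted(pick_noisy)
    ]
    return QCPool(cells=pd.DataFrame(rows), fraction=fraction, seed=seed)


def reclassify(
    pool: QCPool, labels: np.ndarray, threshold: float = 0.5
) -> ReclassDecision:
    """Reclassify pooled cells by their cluster's noisy fraction.

    Per cluster with noisy fraction f: if ``f < threshold`` the cluster is
    predominantly clean and its noisy-origin members are rescued; if
    ``f > threshold`` it is predominantly noisy and its clean-origin members
    are dropped; otherwise (and for unclustered cells) everything keeps its
    prior status. The rule is symmetric: swapping the origin flags and
    replacing t by 1 - t swaps rescue and drop decisions exactly. At the
    default t = 0.5 this is a simple majority vote.
    """
    if not 0 < threshold < 1:
        raise ParameterError("threshold must be in (0, 1)")
    labels = np.asarray(labels)
    if len(labels) != len(pool.cells):
        raise ParameterError("labels must align with the pool")
    df = pool.cells.copy()
    df["cluster"] = labels
    df["action"] = "keep"
    stats = []
    for lab, grp in df.groupby("cluster"):
        if lab < 0:
            stats.append(
                {"cluster": lab, "size": len(grp), "noisy_fraction": np.nan,
                 "action": "none"}
            )
            continue
        noisy_frac = float((grp["origin"] == "noisy").mean())
        action = "none"
        if noisy_frac < threshold:
            idx = grp.index[grp["origin"] == "noisy"]
            df.loc[idx, "action"] = "rescue"
            if len(idx):
                action = "rescue noisy members"
        if noisy_frac > threshold:
            idx = grp.index[grp["origin"] == "clean"]
            df.loc[idx, "action"] = "drop"
            if len(idx):
                action = "drop clean members"
        stats.append(
            {"cluster": int(lab), "size": len(grp), "noisy_fraction": noisy_frac,
             "action": action}
        )
    return ReclassDecision(decisions=df, cluster_stats=pd.DataFrame(stats))


def pool_features(
    table: SpatialFeatureTable, log: RedactionLog, pool: QCPool
) -> pd.DataFrame:
    """0-1 rescaled marker features for the pooled cells.

    The rescale is anchored on the RETAINED cells' min/max per marker, so
    redacted cells are mapped with the same affine transform and the two
    origins are directly comparable in feature space.
    """
    df = table.data.set_index(["sample_id", "cell_id"])
    retained_idx = pd.MultiIndex.from_tuples(log.retained_keys())
    feats = df[table.feature_marker_names]
    anchored = feats.copy()
    for name in table.feature_marker_names:
        ret_vals = feats.loc[retained_idx, name].to_numpy(dtype=float)
        lo, hi = float(ret_vals.min()), float(ret_vals.max())
        if hi == lo:
            anchored[name] = 0.0
        else:
            anchored[name] = (feats[name] - lo) / (hi - lo)
    pool_idx = pd.MultiIndex.from_tuples(pool.keys)
    return anchored.loc[pool_idx]


def run_metaqc(
    table: SpatialFeatureTable,
    log: RedactionLog,
    fraction: float = 1.0,
    threshold: float = 0.5,
    seed: int = 0,
    method: str = "umap",
    n_neighbors: int = 15,
    min_cluster_size: int = 20,
) -> ReclassDecision | None:
    """Full metaQC pass: pool, embed, cluster, reclassify, update the log.

    Returns the decision record, or ``None`` when there is nothing to audit
    (no redacted cells). Rescues flip terminal status back to retained and
    are logged; drops are redacted under module "metaQC".
    """
    pool = sample_qc_pool(
        log.retained_keys(), log.redacted_keys(), fraction=fraction, seed=seed
    )
    if pool is None:
        return None
    feats = pool_features(table, log, pool)
    emb = embed_cells(feats, method=method, seed=seed, n_neighbors=n_neighbors)
    labels = cluster_cells(emb, min_cluster_size=min_cluster_size)
    decision = reclassify(pool, labels, threshold=threshold)
    log.rescue(decision.rescued_keys(), "metaQC", "predominantly clean cluster")
    log.redact(decision.dropped_keys(), "metaQC", "predominantly noisy cluster")
    return decision
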