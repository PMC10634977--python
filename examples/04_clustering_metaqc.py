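"""Cluster retained cells, audit with silhouettes, and run metaQC.

The clustering module embeds 0-1 rescaled marker intensities with UMAP and
clusters the embedding with HDBSCAN (-1 = unclustered). metaQC then pools
equal parts of redacted and retained cells, clusters the pool, and corrects
gating mistakes: redacted cells in predominantly clean clusters are rescued,
retained cells in predominantly noisy clusters are dropped.
"""

import numpy as np
from sklearn.metrics import adjusted_rand_score

from plexqc import (
    RedactionLog,
    SynthParams,
    cluster_cells,
    cluster_profile,
    embed_cells,
    generate_dataset,
    meta_cluster,
    run_metaqc,
    silhouette_by_cell,
)

params = SynthParams(seed=0)  # artifact-free, 4 cell types
_, markers, _, table, gt = generate_dataset(params)
feat_names = [m.marker_name for m in markers if not m.is_counterstain]
feats = table.data[feat_names].apply(lambda c: (c - c.min()) / (c.max() - c.min()))

emb = embed_cells(feats, seed=0)
labels = cluster_cells(emb, min_cluster_size=25)
sil = silhouette_by_cell(emb, labels)
truth = np.array([gt.cell_types[c] for c in table.data["cell_id"]])
print(f"clusters found: {labels.max() + 1}, unclustered: {(labels < 0).sum()}")
print(f"ARI vs planted cell types: {adjusted_rand_score(truth, labels):.3f}")
print(f"positive silhouettes: {100 * (sil[labels >= 0] > 0).mean():.1f}%")

profile = meta_cluster(cluster_profile(feats, labels), k=2)
print("cluster-normalized profile (rows=clusters):")
print(profile.normalized.round(2).to_string())

# metaQC demo on a specimen with a real tissue fold: redact the truly noisy
# fold cells AND 20 normal cells by mistake, then audit. The mistakes
# co-cluster with retained (clean) cells and are rescued; the fold cells
# stay redacted because their clusters are predominantly noisy.
from plexqc import default_artifact_plan

params2 = SynthParams(artifacts=tuple(default_artifact_plan()), seed=0)
_, markers2, _, table2, gt2 = generate_dataset(params2)
fold_cells = gt2.affected_cells["fold_1"]
mistakes = [c for c in table2.data["cell_id"] if c not in fold_cells][:20]
log = RedactionLog.for_table(table2)
log.redact([("synthetic", c) for c in sorted(fold_cells)], "selectROIs", "fold")
log.redact([("synthetic", c) for c in mistakes], "selectROIs", "mistake")
dec = run_metaqc(table2, log, threshold=0.5, seed=0, min_cluster_size=15)
d = dec.decisions.set_index("cell_id")
pooled = [c for c in mistakes if c in d.index]
rescued = (d.loc[pooled, "action"] == "rescue").sum()
fold_rescued = (d.loc[[c for c in fold_cells if c in d.index], "action"]
                == "rescue").sum()
print(f"\nmetaQC rescued {rescued}/{len(pooled)} pooled mistakes and "
      f"{fold_rescued}/{len(fold_cells & set(d.index))} true fold cells")
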