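"""Histogram/threshold gates: cycle correlation and percentile pruning.

Cells lost during cyclic imaging have near-zero late-cycle nuclear stain, so
log10(DNA_1/DNA_n) separates them as a peak far right of 0; gating to
[-0.5, 0.5] removes them. Percentile pruning then trims per-channel
intensity outliers (e.g. antibody-aggregate cells) and rescales each marker
to [0, 1].
"""

import numpy as np

from plexqc import (
    GateInterval,
    PercentileCutoffs,
    RedactionLog,
    SynthParams,
    default_artifact_plan,
    gate_cycle_ratio,
    generate_dataset,
    log_cycle_ratio,
    prune_channel_outliers,
)

params = SynthParams(artifacts=tuple(default_artifact_plan()), seed=0)
_, markers, _, table, gt = generate_dataset(params)

ratio = log_cycle_ratio(table)
detached = table.data["cell_id"].isin(gt.detached_cells)
print(f"log10(DNA_1/DNA_n): stable cells {ratio[~detached].mean():+.3f} "
      f"+- {ratio[~detached].std():.3f}, detached {ratio[detached].mean():+.3f}")

log = RedactionLog.for_table(table)
gate_cycle_ratio(table, log, GateInterval("log_ratio", lower=-0.5, upper=0.5))
redacted = {cid for _, cid in log.redacted_keys()}
print(f"gate [-0.5, 0.5] redacted {len(redacted)} cells; "
      f"exact match with planted detachment: {redacted == gt.detached_cells}")

# percentile pruning of the aggregate channel: the planted aggregate pushes
# its cells' M00 means far beyond the biological distribution
rescaled = prune_channel_outliers(
    table, log, [PercentileCutoffs("M00", p_lo=0.1, p_hi=99.9)]
)
pruned = {cid for _, cid in log.redacted_keys()} - redacted
agg = gt.affected_cells["aggregate_1"]
print(f"pruneOutliers removed {len(pruned)} cells "
      f"({len(pruned & agg)} of {len(agg)} aggregate cells)")
kept = log.retained_mask(rescaled)
v = rescaled.data.loc[kept, "M00"]
print(f"retained M00 after 0-1 rescale: min={v.min():.1f}, max={v.max():.1f}")
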