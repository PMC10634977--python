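# Methods

This note records the models, conventions and numerical choices behind
`plexqc`, and what its synthetic benchmarks do and do not establish about
real data.

## Data model and conventions

All geometry is in full-resolution pixel coordinates, 0-based, with
x = column and y = row; centroids may be fractional. Intensities are
arbitrary fluorescence units (AFU). The spatial feature table keeps one row
per segmented cell (`sample_id`, `cell_id`, `x`, `y`, `area`, one column per
marker); cells are never deleted — the redaction log holds each cell's
terminal status (retained/redacted), the single module responsible, and an
append-only event history, so provenance survives metaQC rescues and the
per-module redaction fractions can be reconstructed exactly (gross module
counts, rescues as a negative contribution, artifact-free remainder; the
fractions sum to 1 by construction).

CSV interchange is comma-separated UTF-8 with a header row; intensity
columns match marker names exactly, and reads use round-trip float parsing
so a write/read cycle is bit-exact (this is what makes checkpoint-resume
byte-identical to an uninterrupted run). Checkpoints are a single zip
archive holding the table, the event log and a JSON header with per-module
parameter hashes; on resume only the hashes of *executed* modules are
checked, so editing a downstream module never invalidates a checkpoint.

Cell membership for every redaction geometry (ROIs and detector masks) is
decided by the rounded centroid pixel, not by any-pixel overlap: the table
row is the unit of redaction, and one membership rule everywhere keeps
positive/negative ROI modes exactly complementary. Polygon membership uses
the even–odd fill rule with the boundary counting as inside — deterministic
even for self-intersecting hand-drawn lassos.

## Artifact detector

The detector targets structures whose spatial extent is much larger than a
cell: folds, aggregates, illumination aberrations. Per channel:

1. block-mean downsample by `downsample_factor` (default 4; at 0.65 µm/px
   this puts the working pixel near 2.6 µm). Block means, not striding, so
   single-pixel noise cannot masquerade as structure;
2. linear min–max rescale to integer levels 0–255. No percentile clipping:
   artifacts are assumed to be the brightest structures, and clipping would
   saturate them together with signal. A constant channel maps to all
   zeros (degenerate, documented);
3. grey-level erosion → local mean → grey-level dilation, all three sharing
   one disk kernel (`kernel_diameter`, working-resolution pixels). Erosion
   deletes anything narrower than the kernel (cells), the mean smooths
   residue, dilation restores the extent of what survived. Reflect padding
   at the border avoids a spurious dark rim that would erode edge
   artifacts;
4. seed search: local maxima within the kernel expanded by
   `seed_expansion` (default 2.0), strictly above `intensity_floor`
   (default 50 of 255), mutually separated by at least the expanded
   diameter. Adjacent maxima necessarily share a value, so each connected
   plateau collapses to its lexicographically smallest (y, x) pixel —
   a deterministic tie-break;
5. flood fill from each seed with `tolerance` grey levels (in the 8-bit
   units the transform produces), 8-connectivity — artifacts are blobby and
   corner connectivity avoids fragmenting diagonal boundaries. Regions grow
   monotonically with tolerance;
6. the union of regions, upscaled nearest-neighbor to full resolution, is
   the artifact mask. Detection and application are two phases, so masks
   can be reviewed or exported (8-bit TIFF + seed JSON) before any cell is
   dropped.

Defaults were calibrated once against the generator's scales: cells of
radius 6 px are 3 working pixels wide at factor 4, so `kernel_diameter = 9`
is three cell diameters (within the intended 3–5×), comfortably above cell
scale and far below artifact scale; `tolerance = 40` keeps a flood seeded
on a dim fold plateau (~60–90 levels) from leaking into background (~2–8
levels) while still capturing most of an aggregate's edge gradient. With
these defaults the planted aggregate and fold are recovered as exactly two
regions at IoU ≥ 0.75 and ≥ 0.94 respectively, with zero mask area on
artifact-free replicates.

The intensity floor deliberately makes the detector conservative: a channel
whose artifacts are dimmer than ~20% of its own maximum will not seed. That
is the intended division of labor — such channels are what the ROI and
percentile modules are for.

## Gates

Interval gates (`dnaIntensity`, `areaFilter`, `cycleCorrelation`) are
boundary-inclusive: a value equal to a bound is kept. The counterstain gate
uses the first cycle's DNA channel by default. The cycle-correlation
statistic is `log10((DNA_1 + ε)/(DNA_n + ε))` with ε = 1 AFU, which keeps
zero-intensity (fully detached) cells finite and far right of the stable
peak while perturbing bright cells by < 0.005 decades.

`pruneOutliers` computes linear-interpolation percentiles over the cells
still retained when each channel is processed (channels are cumulative, in
config order), batch-pooled by default (per-sample scope available).
Redaction at the percentile cutoffs is *inclusive* — a cell at or beyond
the cutoff is removed — so a point mass of identical outliers sitting
exactly at the empirical cutoff is removed in full rather than surviving a
strict comparison; percentiles of exactly 0/100 are open ends, keeping
(0, 100) a no-op. Pruning redacts cells (it does not winsorize): the
affected values are assumed corrupt, not merely extreme. After all
channels, every marker is min–max rescaled to [0, 1] on the retained cells;
redacted rows get the same affine map so pooled re-analysis (metaQC)
remains comparable. Thresholds themselves are user decisions supplied via
config; an export hook writes histogram CSVs/plots for choosing them, in
place of interactive sliders.

## Clustering and metaQC

Phenotype features are the pruned, 0–1 rescaled markers with counterstain
channels excluded (the nuclear stain is a reference, not a phenotype).
Embedding is UMAP (or t-SNE) with a fixed seed; HDBSCAN runs on the 2-D
embedding — matching the module sequence of reduction followed by density
clustering — with −1 marking unclustered cells. Silhouettes are computed in
embedding space over clustered cells (unclustered and singleton-cluster
cells report 0 by convention); negative values flag under-clustering.
Cluster profiles are means over clustered cells, min–max normalized per
marker across clusters (a marker constant across clusters maps to 0);
meta-clustering is average-linkage agglomeration on Euclidean distances
between normalized profiles — the conventional clustermap defaults, chosen
because nothing stronger is implied by the method description.

metaQC pools `floor(f · min(|retained|, |redacted|))` cells from each side
(default f = 1), uniformly without replacement, rescales the pool with the
retained min/max, and clusters it with the same chain. Reclassification is
symmetric in the threshold *t*: a cluster with noisy fraction below *t* has
its redacted members rescued, one above *t* has its retained members
dropped; at the default *t* = 0.5 this is a majority vote, and swapping the
origin flags while replacing *t* by 1 − *t* swaps rescues and drops
exactly. Decisions apply only to pooled cells — labels are not extrapolated
to unsampled cells — and a run with no redacted cells skips the module with
a log notice.

## Galleries

Display limits are the (0.1, 99.9) pixel percentiles of a reference
sample's channels (overridable), applied to every sample in the batch so a
given intensity renders identically everywhere; a constant channel renders
mid-grey. Thumbnails are S×S patches (default S = 30 px, ≈ 20 µm at
0.65 µm/px — the patch is specified in pixels, the micron size is derived)
centered on the rounded centroid, zero-padded at image borders, shown with
the cluster's top-3 markers by normalized profile value (rank 1 green,
2 red, 3 blue; ties break toward the earlier channel) over the grey
counterstain, with the center pixel forced to display maximum as the
reference-cell dot and an optional segmentation-outline overlay. Cells are
drawn per cluster uniformly without replacement under the gallery seed, so
the manifest is reproducible.

## Pipeline

Modules run in the canonical order (any subset enabled):
selectROIs → artifactDetect → dnaIntensity → areaFilter →
cycleCorrelation → pruneOutliers → metaQC → clustering → setContrast →
curateThumbnails. Automated detection follows manual ROIs and both precede
the gates, so the histogram-based modules see a table already stripped of
gross artifacts. One global seed fans out to per-module sub-seeds by stable
hashing of the module name, making module-level randomness independent of
the execution path; this is what lets a resumed run reproduce an
uninterrupted one byte for byte. A checkpoint is written after every module
(plus a per-module history used by resume), and a failing module leaves the
last completed checkpoint intact.

## Synthetic data generator

The generator defines the study conditions for all tests. Defaults: a
1024×1024 image, 500 non-overlapping disc cells of radius 6 px (discs give
exact analytic areas and centroids for oracle tests), 4 cell types, 3
cycles of 1 counterstain + 3 marker channels. Type *t* expresses the
markers congruent to *t* modulo the number of types — orthogonal templates.
Background is 100 AFU with Gaussian read noise σ = 5 (clipped at 0);
expressed markers add 80 AFU × lognormal(σ = 0.2) per cell and channel.
The counterstain adds 2000 AFU × a per-cell lognormal factor (σ = 0.2)
shared across cycles — DNA content is a property of the cell — times a
small per-cycle jitter (σ = 0.05) for imaging variation. These scales were
chosen so that (a) the cycle-correlation statistic separates detached cells
(ratio ≈ 1.2) from stable ones (|ratio| < 0.15) by an order of magnitude,
and (b) marker channels stay dim enough relative to background that a 2–3×
tissue fold clears the detector's intensity floor, as real folds do against
real backgrounds.

Artifact classes: *aggregate* — a disc set to ≥ 5× the channel's 99th
percentile of biological signal; *fold* — a polygon multiplying all
channels by a factor drawn in [2, 3] (matching the observation that fold
cells exceed type averages in every channel); *fiber* — a 3-px-wide bright
random-walk curve in ≥ 2 channels; *detachment* — a random cell fraction
whose counterstain and marker amplitudes in cycles > c are scaled by
δ = 0.01 before noise; *defocus* — Gaussian blur over a rectangular tile.
Artifacts apply in plan order; ground truth records each mask, the affected
cells (centroid-in-mask), the detached set and the pre/post-detachment
counterstain amplitudes. An optional doublet fraction fuses two discs 1.5 r
apart (area ≈ 1.9× a single cell) to emulate under-segmentation for the
area gate. Identical parameters and seed reproduce every output
bit-identically.

What the generator does *not* model: realistic cell morphology and packing,
point-spread functions, autofluorescence spectra, illumination gradients,
or registration error. Passing benchmarks therefore establish algorithmic
correctness and calibration on controlled conditions — recovery of planted
structure at known scales — not performance on real tissue, where gate
thresholds and detector parameters remain specimen-dependent decisions.

## Benchmark problem sizes

The bundled test suite and acceptance script use a 1024² / 500-cell
specimen for detection and gating, a 512² / 300-cell specimen for the full
pipeline (run twice plus a resume to verify byte-identity), 800 cells for
the metaQC populations and 10,100 values for the pruning benchmark —
sizes at which every planted effect is comfortably detectable while a
complete run stays within a few minutes on one CPU.

## Known limitations

Fibers and defocus tiles are generated and masked in ground truth but have
no dedicated detector: thin curves are erased by the erosion step (they are
narrower than any sensible kernel) and defocus changes sharpness, not
intensity — both are left to ROI review, percentile pruning or the
counterstain gates, mirroring how such artifacts are actually handled.
The detector's flood fill undershoots sharp high-contrast artifact edges by
roughly half a kernel radius (visible as aggregate IoU ≈ 0.77 vs fold
IoU ≈ 0.94), a direct consequence of anchoring the tolerance band at the
seed value. metaQC is a single pass by design; iterating it would let
rescued cells re-seed pools but also compound clustering noise. Lateral
spillover between neighboring cells is out of scope.
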