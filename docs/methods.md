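# Methods

This note documents the models, numerical choices and limitations behind
`srtqc`. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Data model and baseline QC

Transcript tables are pandas DataFrames with canonical columns
`x, y, z` (µm), `gene`, `qv` (phred-scaled decoding quality),
`cell_id` (string; the sentinel `"UNASSIGNED"` marks reads outside any
cell) and optionally `overlaps_nucleus`. Count matrices and references
are AnnData objects: raw integer counts in `.X`, per-cell metadata
(centroid, `cell_type`, read totals) in `.obs`, control-probe flags in
`.var`. MatrixMarket + TSV sidecars round-trip integer data bit-exactly.

Two filters define the baseline QC, both with deliberate inequality
conventions:

* read filter: keep `qv > qv_min` (strict; default 20, ≈ 1 % decoding
  error). Both filters are idempotent and monotone in their thresholds.
* cell filter: keep cells with `total reads >= min_reads` (default 10 —
  cells with *fewer than* ten reads are excluded).

Coordinates are micrometers throughout; pixel↔µm conversions use a
configurable pixel size (default 0.2125 µm/px). Distance and spatial
bins are half-open `[a, b)`; indexing is 0-based. Control probes are
recognized by configurable name prefixes (`NegControlProbe_`,
`NegControlCodeword_`, `BLANK_`, `antisense_`).

The dataset summary reports mean reads per cell both for all assigned
reads and for quality-filtered reads, because platform-level summaries
are ambiguous about which variant they quote.

## Specificity metrics

**Negative marker purity (NMP).** Definitions and the two-branch
formula are given in the README. Numerical conventions:

* The type universe C for the balancing normalization is the set of
  cell types present in **both** modalities; pairs referencing other
  types are dropped and counted.
* Pairs whose gene has zero total mean expression in either modality
  are dropped with a warning rather than treated as 0/0.
* The permutation baseline permutes the labels of the matrix under
  evaluation (a `baseline_matrix` hook accepts an external binning
  reference when one exists). Each of the `n_perm` (default 20)
  permutations uses `numpy.random.default_rng([seed, index])`, so the
  stream is independent of evaluation order. The scaled score is
  `(raw − b) / (1 − b)`; values below baseline stay negative; `b = 1`
  returns 1.

**Negative co-expression purity (NCP).** "Non-coexpressed" is not
numerically pinned down in the literature; here a cell co-expresses a
pair when both counts are > 0, and a pair is non-coexpressed when the
co-positive cell fraction is `< 0.005`, mirroring the negative-marker
threshold for internal consistency. Both thresholds are configurable,
and the in-situ evaluation reuses the reference threshold by default.
Pairs with genes absent from the spatial panel are dropped and counted.

The 0.5 % co-positivity threshold makes NCP sharply sensitive to
uniform noise at high per-gene depth: once the expected noise count per
cell and gene approaches ~0.01–0.03, *every* cross-type marker pair
crosses the threshold together. NCP is therefore informative in the
sparse regime in situ panels actually occupy (mean counts per gene per
cell well below 1); the noise-response validation uses an ISS-depth
world for exactly this reason (see Simulator).

## Detection efficiency

Per gene, *positive cells* are cells with at least `positive_min` reads
(default 2 — the literal reading of "more than one read"; the flag
switches to ≥ 1). The efficiency ratio is the spatial positive-cell
median divided by the reference positive-cell median. Medians use the
lower-median convention (the `(n−1)//2`-th order statistic) so integer
counts give integer medians and bit-identical cross-implementation
results. Genes with no positive cells in either modality are flagged
undefined, not errored.

Pseudobulk comparisons divide per-gene totals by region area; genes
absent in the denominator assay give infinite ratios, reported
separately from the finite-ratio median. Centroid-distance profiles use
2D (x, y) distance, ignoring z, and report at each bin edge d the
fraction of assigned reads at distance ≥ d (1 at d = 0,
non-increasing).

## Optimal nuclear expansion

Signatures are gene-composition vectors (nonnegative, summing to 1):

* *nuclear*: per cell type, from nucleus-overlapping assigned reads;
* *background*: per tissue domain, from unassigned reads;
* *distance-binned*: per (type, domain), reads binned by distance to
  the **nearest cell centroid** in half-open 1-µm bins. The nearest
  centroid (rather than the assigned cell's) is used because unassigned
  reads have no owning cell and the crossover must be measurable beyond
  the cell edge; for reads inside their own cell the two coincide.

For each (type, domain) pair with at least `min_reads` binned reads
(default 5,000, intended for full datasets; fixtures lower it), each
bin's composition is Pearson-correlated — on raw compositions over all
panel genes, zeros included, no transform — with the nuclear and the
background signature. The crossover is the left edge of the smallest
bin where the background correlation strictly exceeds the nuclear one;
pairs with no such bin are flagged unbounded and excluded from the
per-type mean. Bins whose composition is constant (correlation
undefined) are skipped.

The nuclear radius is estimated per cell as the mean distance from the
nuclear-read centroid to the convex-hull vertices of the nuclear reads
(cells with < 3 or collinear points are skipped with a warning). Hull
vertices lie slightly inside the true boundary at finite read counts;
at the generator's default nuclear depth (150 reads/nucleus) the bias
is a few percent. Crossover minus nuclear radius gives the implied
expansion distance.

## Segmentation evaluation

* `expand_labels` grows masks into background up to a distance via
  scikit-image's Euclidean-distance-transform expansion: growth is
  Voronoi-constrained, so masks never overlap and the count-matrix
  invariant (each read counted once) survives.
* `assign_reads` maps reads to the label under their pixel (`inside`),
  optionally assigning background reads to the nearest label within
  `max_dist` (`nearest`). Distances are computed on the pixel grid
  (EDT convention). Out-of-bounds reads stay unassigned.
* `majority_vote_types` transfers a prior per-read annotation to new
  cells by most-frequent type; ties break lexicographically so results
  are deterministic.
* `background_intensity_filter` tiles the image into non-overlapping
  `window`-sized tiles anchored at (0, 0); each cell is evaluated in
  the tile holding its centroid, against the mean intensity of
  background pixels in the `surround`-sized window centered on that
  tile (defaults 1000/2000 px, factor 0.3, strict `<`). Tiling
  anchored at the origin is the simplest deterministic reading of a
  windowed filter.
* `seg_summary` reports assigned-read fraction, cell count, median and
  5th-percentile reads and genes per cell (linear-interpolation
  percentiles), plus raw and scaled NMP when a reference is supplied.

## Preprocessing workflows

A workflow is the fixed-order chain normalization → log1p → HVF
selection → scaling → PCA → kNN graph → clustering, each step optional.
Defaults encode the top-performing path for panel-restricted data:
library-size normalization to 100 counts, log-transform, scaling, all
principal components, 16 neighbors, Louvain. Conventions:

* "All principal components" means `min(n_cells, n_genes) − 1` capped
  at 50 (`max_pcs`); panels of a few hundred genes make the cap nearly
  exhaustive.
* Pearson-residual normalization forces the log step off (residuals are
  already variance-stabilized). An analytic-residual implementation
  stands in for regression-based variance stabilization, which has no
  faithful Python port.
* Louvain runs through python-igraph's `community_multilevel` (with
  resolution support) on the scanpy kNN graph, seeded via Python's
  `random` module; Leiden runs through leidenalg with an explicit
  random state. Identical (config, seed) pairs give identical labels.
  Markov clustering is a plugin hook (`CLUSTERING_REGISTRY`), not a
  built-in.
* `tune_resolution` does geometric bisection on [1e-3, 10] (≤ 25
  evaluations) until the cluster count is within ±2 of the target,
  returning the closest resolution found (flagged) otherwise.

Partition similarity: ARI (permutation-adjusted), VI computed as
H(A|B) + H(B|A) in nats — this form is exactly 0 for identical
partitions, unlike H(A)+H(B)−2I which leaves float residue — NMI with
arithmetic-mean normalization, and FMI. One-at-a-time perturbation runs
re-tune the resolution to the same target as the base workflow so
differences reflect the toggled step, not cluster-count drift.

Imputation metrics per gene over cells: PCC on raw vectors (constant
truth → NaN, flagged); SSIM on min-max-scaled vectors with the standard
stabilization constants C1 = 0.01², C2 = 0.03² at dynamic range 1;
RMSE on z-scored vectors (population std); Jensen–Shannon divergence on
sum-normalized vectors, natural log, 0·log 0 := 0.

## z-coherence

The KDE vector field sums **unnormalized** Gaussian kernels
(amplitude 1 at the read, bandwidth 2.5 µm) per gene on a 2.5 px/µm
grid, so the per-pixel norm scales like the local read support and the
low-confidence cutoff of 5 means "≈ five reads of local evidence".
With pdf-normalized kernels the same cutoff would invalidate nearly
every pixel at realistic densities; cosine similarity itself is
scale-invariant. The kernel sum is computed exactly by default (each
read contributes a separable outer product over the whole grid);
`truncate` optionally cuts kernels at a multiple of the bandwidth for
large fields, trading the exactness contract for speed.

Reads split into top/bottom halves per 2-µm xy bin around the bin's
mean z; reads at exactly the mean go to the bottom (documented tie
rule, so a constant-z bin is entirely bottom). Latent fitting samples
the full field at local maxima of its norm (8-neighborhood, ≥ all
neighbors, above the norm threshold; on tied plateaus only the
row-major-first pixel is kept) and fits PCA, retaining the smallest
number of components with cumulative explained variance ≥ 0.80 (read
as ≥). Both half-fields are transformed with the standard centered PCA
model — centering matters: an offset-free projection lets the shared
mean composition dominate and erases the top/bottom contrast the score
measures. Pixels where either half's norm is below 5, or either latent
vector is exactly zero, are invalid. Identical latent vectors are
assigned similarity exactly 1 (bypassing sqrt round-off). Nuclei are
flagged when their mean similarity over valid pixels is strictly below
0.2; nuclei with no valid pixels are unscored and excluded from the
flagged fraction's denominator.

## Simulator

**Count-level world.** `simulate_reference` draws negative-binomial
counts (Gamma–Poisson; dispersion 0.3, Poisson at 0) with per-gene
baseline means log-uniform on [3, 30] — a plausible depth for a curated
Chromium-profiled marker panel — and gives each type exclusive marker
genes: 20× elevated in the owning type, mean 0 elsewhere, so they are
negative markers for every other type and cross-type marker pairs are
non-coexpressed. The Xenium-like transformation then applies, in order:
panel restriction (union of per-type top-50 Wilcoxon DE genes, ties by
log-fold-change then name), per-gene detection efficiency as
Poisson(e·c) — one rule covering thinning (e < 1) and amplification
(e > 1), both observed in practice — uniform non-specific noise at an
expected read share ρ (cells weighted by library size, genes uniform;
`gene_weights` can give control probes a separate rate), and
mis-segmentation: a fraction f of cells each receives
Binomial(partner count, m) reads per gene from one uniformly chosen
partner, conserving totals. Default corruption rates
(ρ = 0.05, f = 0.1, m = 0.25) are mid-range plausible values — the
exact real-data rates are not published — and every step is
reproducible from `(seed, config)` via counter-keyed generators.

The NCP noise-response validation uses a sparser variant
(base means log-uniform [0.01, 0.3], 10× markers): ISS-depth data where
the 0.5 % co-positivity threshold responds gradually to noise rather
than flipping all pairs at once (see Specificity).

**Spatial world.** Cells are disjoint disks (radius R, default 10 µm)
with concentric nuclei (radius r < R, default 5 µm) on a jittered grid;
jitter is bounded so disks cannot touch, and an explicit field size
that cannot hold the requested cells fails fast. Nuclear reads (inside
r) draw genes from the type's nuclear composition, cytoplasmic reads
(in [r, R)) from a distinct cytoplasmic composition on the same gene
block, background reads (outside all cells, spatially uniform by
rejection) from a per-domain composition on a disjoint gene block.
Domains split the field into vertical strips. qv values come from a
two-component normal mixture (85 % ≈ N(35, 3), 15 % ≈ N(12, 4), clipped
to [0, 40]) so quality filters are exercisable. z is uniform over the
slice; `duplicate_z` instead emits every read twice at the two z
extremes (a perfectly z-coherent slice, giving top/bottom fields that
are bit-identical); `two_layer` stacks a second, signature-distinct
layer (its own gene block) on a fraction of cells
(`overlap_fraction`, default 0.5) — only a fraction, because a tissue
with *every* cell stacked would contain no pure per-layer signature
anywhere and the latent space could not represent the layers. Label
images (cells and nuclei) are rendered at a configurable pixel size
(default 0.4 µm/px, matching the KDE grid), and the ground truth
records compositions, geometry, per-read origins and the stacked
nuclei.

**What a green test does and does not establish.** The generator's
cells are circular, types are equally abundant, markers are perfectly
exclusive, noise is spatially and gene-uniform, and mis-segmentation
mixes whole count vectors rather than boundary reads. Green tests
establish that the *computations* are correct and respond in the right
direction at realistic magnitudes — not that real tissue satisfies
these assumptions, nor that any specific published value is reproduced
(the headline numbers of full-scale studies depend on tens of gigabytes
of data and cross-platform downloads that desk-scale validation cannot
and does not attempt to reproduce).

## Known limitations

* NMP requires the spatial matrix to carry cell-type labels from the
  reference's vocabulary; types absent from either side are ignored.
* The expansion crossover is reported at bin resolution (left edge);
  sub-bin localization is out of scope.
* `background_intensity_filter` evaluates each cell in a single tile
  (the one holding its centroid); cells spanning tile borders are not
  split.
* The KDE field is dense (H × W × G float64); panels of thousands of
  genes at high resolution need tiling or the `truncate` option.
* No reading of proprietary raw instrument output (only plain 2D
  grayscale/label images) and no zarr store support.
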