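# Methods

## Barcode grammar

A barcode is a concatenation of degenerate-repeat segments, each a short IUPAC
unit tiled over a fixed length, with fixed literal flanks. The default
blueprint is `WWSS`×60 nt, `NSW`×60 nt, a 25-nt fixed gap, `WS`×60 nt and
`SNW`×60 nt — 265 nt assembled. The gap appears in both synthesis inserts but
only once in the assembled barcode because the two inserts overlap at the gap
during assembly; the blueprint therefore stores it once (`gap_after=2` places
it between the second and third segments). The 33-nt right flank is the
vector-backbone anchor used by the extractor. The gap and the 28-nt left
flank are not part of any published vector map we encode; they are synthetic
placeholder literals and fully configurable (`BarcodeBlueprint` fields,
YAML-serializable).

Pattern space is exact integer arithmetic (degeneracy 2 for W/S, 4 for N);
the default grammar spans 2^280 sequences, so the practical limit on library
diversity is synthesis and cloning, not sequence space. The expected number
of colliding cell pairs when labeling *n* cells from a library of *D* barcodes
is the birthday estimate *n(n−1)/2D*.

Clone identifiers are the 15 nt of barcode adjacent to the anchor in vector
sense — the suffix of the full barcode. Because 15 divides into the 60-nt
`SNW` segment at a repeat boundary (offset 45 = 15 units), the suffix obeys
`SNW` at phase 0, which is what the extractor's pattern check asserts.
Reporting the anchor-adjacent window (rather than a window at the read 5'
end) makes extraction strand-invariant and independent of read length.

## Extraction QC cascade

Each read is scanned for the anchor on both strands (exact match by default;
a Hamming-distance budget is configurable), orientation-normalized, and
resolved through a fixed status order: `no_anchor` → `empty_vector` (the
bases immediately 5' of the anchor equal a configurable signature sequence;
the filter's detection rule is our design choice) → `short` (fewer than 15 nt
of barcode in the read) → `pattern_fail` (the 15-mer violates the terminal
repeat) → `ok`. Statuses partition reads by construction.

Resolution collapses reads per (cell, UMI) with majority consensus (ties
discard the UMI), counts UMIs per (cell, clone), drops clones below
`min_umi_support` (default 1) within a cell, and removes cells with two or
more surviving clones as presumptive doublets or multiple infections. The
reported `fraction_assigned` divides assigned cells by cells with at least
one `ok` hit. The consensus step is what makes assignment robust to
sequencing errors: an erroneous read inside a multi-read UMI is outvoted, and
error-only UMIs are rare at realistic per-base error rates.

## Fate classification

Clone trajectories are fit on normalized abundance A(t) = proportion ×
tumor volume (× an optional global-activity scalar, default 1). This matters:
raw proportions of expanding clones saturate once those clones dominate the
population, destroying the exponential form, whereas volume normalization is
proportional to absolute clone size and preserves it. Each trajectory is
rescaled by its own maximum before fitting so the RSS < 0.1 acceptance
threshold is scale-free (the original abundance units for the threshold are
not defined anywhere authoritative; rescaling is our documented choice).

Fits use `scipy.optimize.curve_fit` with `a0 ≥ 0`, `k ∈ [0, 10]`/day,
initialized from the first rescaled value and the log-linear slope;
non-convergence is treated as a failed fit (RSS = ∞), never an exception.
Decision rule: a clone whose proportion never reaches `low_abundance_max`
(default 1e-4) is low-abundance outright; otherwise growth/decay fits with
RSS below threshold compete, lower RSS winning ties, with exact ties and
double failures falling to low-abundance — fully deterministic.

Shannon diversity is reported in nats (configurable base), with Hutcheson's
variance and two-tailed t-test (Welch degrees of freedom) for pairwise
comparisons. Overlap between samples is `100·|pre ∩ post|/|pre|`, normalized
by the first argument; k-way intersections support "shared across all
replicates" summaries.

## Permutation recurrence testing

Gene recurrence is the number of tumors carrying the gene; pathway recurrence
counts tumors with ≥1 mutated member (pathway genes are intersected with the
universe first). The null redraws each tumor's gene set uniformly without
replacement at its observed burden. Two statistics are offered because the
scientific question has two readings: `per_item` p-values for each gene or
pathway, and a `max_statistic` family-wide p for "is any recurrence beyond
chance at all" (the default for gene level, where per-gene p-values across a
whole exome are rarely the question). Empirical p is the plain fraction of
permutations meeting or exceeding the observed value; `add_one` smoothing
((r+1)/(B+1)) is available to avoid exact zeros. Default B = 10,000, seeded.
BH q-values come from `statsmodels` and are attached to pathway tables.

## Scores and spatial statistics

- **CNV score**: fraction of genes strictly outside (0.9, 1.1) in a matrix
  centered at 1; boundary values are neutral. Invariant to gene order.
- **Moran's I**: `(n/ΣΣw)·(ΣΣ w_ij z_i z_j)/(Σ z_i²)` on a symmetric
  zero-diagonal weight matrix — rook adjacency for lattices (unstandardized),
  symmetrized k-NN for spot arrays. Optional permutation p by value
  shuffling. Closed-form checks: −1 on a checkerboard, E[I] = −1/(n−1) under
  the null.
- **Patch co-localization**: the image is partitioned into k×k patches with
  integer boundaries at `round(i·H/k)` (patch sizes differ by ≤1 pixel; no
  pixel discarded), a patch is channel-positive at ≥`min_pixels` set pixels
  (default 1; positivity is not defined anywhere authoritative), and the
  2×2 patch table is tested with Fisher's exact test — one-sided *greater* by
  default since the question is enrichment; two-sided available. The standard
  readout reports k ∈ {4, 6, 8, 10}.
- **Separation indices**: Calinski–Harabasz and mean Silhouette via
  scikit-learn, behind one call for persister-program separation analyses.

## Synthetic data: what it emulates and what it does not

Generator defaults are fixed study conditions: 300 clones at fate fractions
(0.30 persister, 0.50 sensitive, 0.20 low-abundance), sampling days
(0, 21, 57, 91), baseline tumor volume 500 mm³, persister growth 0.08/day and
sensitive decay 0.10/day (chosen once to give relapse-scale expansion over
~3 months; per-day rates of this order make a clone grow ~e⁷ over the
study), multiplicative log-normal noise with sd 0.1, and Dirichlet(5) initial
clone sizes to mimic skewed clone-size distributions. Tumor volume tracks
total simulated cell mass, so normalized abundance recovers each clone's
exponential form — the same reason the classifier uses volume normalization.
Low-abundance clones are planted below the proportion floor (0.2–0.5 ×
`low_abundance_max`), and the floor's default of 1e-4 keeps Dirichlet-drawn
sensitive clone sizes (mean 1/300) clearly above it, so the fate labels are
well separated by construction.

Read simulation embeds each clone's barcode suffix and the anchor in both
orientations, with configurable decoy rates (anchor ablation, empty-vector
signature, multi-clone cells) and uniform substitution errors; outputs are
written in both the FASTQ header-tag and SAM CB/UB dialects. Mutation
profiles are uniform burden-matched draws with an optionally forced recurrent
gene (swaps preserve burden). CNV matrices are 1 + Gaussian noise with
planted contiguous shifted blocks. Spatial generators produce checkerboard,
single-block and i.i.d. lattices, and blob-structured mask pairs (identical /
independent / disjoint).

What passing tests on these data do **not** show: the generators have no
transcriptome (no genes beyond the barcode reads), no PCR amplification bias
or UMI collisions, no chimeric reads, no mouse-read contamination, spatially
unstructured noise, and exponential dynamics that match the classifier's
model family by construction. Recovery rates here are upper bounds on real
data; the value of the tests is correctness of the statistics and plumbing,
not a claim about biological error rates.

## Numerical choices and limitations

Seeds thread through every generator and permutation engine (NumPy
`default_rng`); fixed seeds give bit-identical outputs, which the CLI records
in a JSON manifest per run. Degenerate inputs raise early (`ValueError`) with
the failing condition: empty count vectors, constant spatial fields,
out-of-range p-values, burdens exceeding the universe. The Hutcheson test is
asymptotic and anticonservative for very small samples; the permutation
engine's per-item mode is resolution-limited at 1/B; `curve_fit` local optima
are mitigated (not eliminated) by the log-linear initialization; patch
positivity at `min_pixels=1` is sensitive to single-pixel noise in masks —
raise it for noisy rasters. Problem sizes in the test suite (≤300 clones,
≤10⁵ reads, B ≤ 40,000, 200-replicate Moran null) are chosen as the smallest
scales at which the statistical checks are stable.
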