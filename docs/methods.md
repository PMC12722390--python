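# Methods

This note documents the models and procedures implemented in `lineaconv`,
the parameters that matter, and the design choices made where the methods
left the design open.

## The experimental design being modelled

Adult oesophageal epithelium carrying a constitutive tdTomato reporter
("red") is grown over denuded skin dermis; the regrown tissue is profiled
by droplet scRNA-seq at day 3 and day 10, alongside oesophagus regrown on
its own stroma as a control. Libraries are spiked with ~5% EGFP⁺ in vitro
skin cells ("green") that serve as a reference for skin identity. A small
fraction of red cells converts towards skin identity through a
transitioning state; the analysis must (i) assign every cell an origin from
its reporter reads and transcriptome, (ii) clean the matrix, (iii)
characterise expression changes along the conversion trajectory, and (iv)
quantify conversion rates in companion grafting assays.

## Synthetic data generator

`synthetic.simulate_dataset` draws UMI counts per cell and gene as negative
binomial with a shared size parameter *r* (`nb_dispersion`, default 5;
variance m + m²/r) around per-cell expected profiles:

- A base abundance profile is lognormal(0, 1.5) across genes. Identity
  marker genes get an 8× abundance boost, emulating the well-expressed
  structural genes (keratins etc.) that real identity signatures consist
  of; this also keeps them inside the 1000-most-abundant window the DEG
  stage restricts itself to.
- The profile is normalised per cell within three blocks: mitochondrial
  genes carry `mito_fraction` (default 0.05) of the depth, ribosomal genes
  `ribo_fraction` (0.20), both times a per-cell lognormal jitter with mean
  1 (σ 0.5 and 0.25) that produces realistic QC spreads without biasing
  the mean; all remaining genes share the rest. Origin effects
  redistribute mass only inside the plain block, so marker fold changes do
  not distort mito/ribo content.
- Origin separation: red markers are scaled by exp(fc·(1−t)) and green
  markers by exp(fc·t), where fc = `marker_ln_fc` (default 1.0) and t is
  the cell's latent pseudotime (0 for pure red, 1 for pure green).
  Transitioning cells — a `transitioning_fraction` (default 0.15) of the
  oeSKIN day-10 sample — get t drawn uniformly inside (0, 1), so their
  marker means interpolate log-linearly between the origins.
  Transitioning-exclusive genes carry a flat exp(`tc_ln_fc`) bump for
  t ∈ [⅓, ⅔), matching the trisection that later analyses apply.
- Per-cell depth is lognormal (default median 20 000 UMIs, σ 0.35); with
  the default 4000 genes this yields ~2400 expressed genes per cell and a
  ~92% pass rate through the inclusion gate — i.e. the gate does real work
  without dominating. Dropout is an extra Bernoulli zeroing (default 5%)
  after the NB draw, which keeps the mean calibration simple.
- Contaminant (stromal/immune) cells (default 5%) express three
  marker genes at exp(3.9) ≈ 50× an ambient baseline that is itself
  ~500× below a typical gene — these markers are essentially silent in
  epithelial cells, giving the zero-inflated density the marker filter
  assumes. Doublets (default 1%) are sums of two random cells, flagged in
  the truth table; no doublet-calling method is modelled.
- Reporter reads: each cell receives Poisson(20) UMIs placed uniformly on
  its own origin's sub-transcripts, flipped to the other reporter with
  probability `reporter_leakage` (default 0.5%, which exercises the
  "independent expression" anchor criterion); 20% of rows are duplicated
  to emulate PCR duplicates.

All randomness flows from one `numpy` Generator seeded by `config.seed`,
so identical configurations are bit-identical. What the generator does
*not* emulate: batch effects, ambient RNA soup beyond the contaminant
markers, gene–gene correlation beyond the planted structure, and
UMI-level sequencing errors. Tests passing on this generator therefore
demonstrate correctness of the procedures under the stated statistical
structure, not performance on any real dataset.

`simulate_graft_counts` draws per-graft event counts as
Poisson(rate_per_cell × cells_per_graft).

### Synthetic reporter pair

`simulate_reporter_pair` builds a red/green coding-sequence pair sharing a
homologous backbone, with 5 red-specific and 3 green-specific insertions
(150 nt each) that have no counterpart in the other sequence — mirroring
the real pair, in which the red reporter is a tandem dimer and so roughly
half of it has no green counterpart. The pair is labelled synthetic
everywhere: it reproduces the *architecture* of the real reporters, not
their sequences, which are not distributed with this package.

## Reporter sub-transcript selection

The two reporters are globally aligned once with affine gap scores
(match +5, mismatch −4, open −10, extend −0.5 — EMBOSS-style DNA scoring).
The scoring matters: if gap extension is as expensive as a mismatch, the
optimal alignment pairs unrelated stretches base-to-base and scores ~25%
identity there (the expected identity of random DNA), so *no* window can
fall below a 20% threshold; with cheap extension, reporter-specific
stretches sit opposite gaps and score ~0.

Per position, a match indicator (1 when the alignment pairs the position
with an identical base; gaps count as mismatches) is smoothed with a
centred 30 nt window; maximal runs strictly below the identity threshold
(default 0.20) become sub-transcripts, trimmed of runs shorter than
`min_length` (default 30 nt). Each returned segment's `max_cross_identity`
is its unwindowed matched fraction under the same global alignment. An
*independent* re-alignment of a segment against the other reporter is
deliberately not used for this check: an optimal local or glocal
re-alignment of any ~150 nt segment against a ~1 kb sequence extracts
25%+ spurious identity from unrelated DNA (measured 0.62–0.73 on the
synthetic pair), which would veto every segment.

Quantification deduplicates assignment rows by (barcode, umi,
subtranscript) and sums counts across each marker's sub-transcripts
("algebraic sum of incident UMIs"). UMIs are not deduplicated across
sub-transcripts: the segments are disjoint, so a UMI legitimately spans at
most one. Coordinates are 0-based half-open.

## QC and marker filtering

The inclusion gate keeps a cell iff depth > 8750 (strict — "over"),
2000 ≤ expressed genes ≤ 8000 (inclusive — "between") and mito% < 15,
ribo% < 45 (strict — "lower than"); mito and ribo genes are then removed
from the matrix. Normalisation is log-CP10K (counts scaled to 10⁴ per
cell, then ln(1+x)) — a documented stand-in for variance-stabilising
normalisation, whose internals are out of scope here.

The non-epithelial filter computes, per marker gene (*Col1a2*, *Pdgfra*,
*Ptprc* by default), a Gaussian KDE (Silverman bandwidth) of normalised
expression over all cells on a 512-point grid from 0 to the max; the
threshold is the first grid point lower than both neighbours to the right
of the global (zero-inflation) mode. Cells strictly above the threshold
for **any** marker are excluded (the markers are alternatives — "or");
a marker with no local minimum excludes no one. Raw-vs-normalised was
ambiguous in the source description; normalised expression is used. Note
the rule is aggressive by construction: with any ambient background, a
single stray count on one marker can exceed a threshold sitting in the
valley just above zero.

## Origin classifier

1. **Anchors**: per marker, cells with own-reporter UMIs > 0 and
   other-reporter UMIs = 0 (strict independence; relaxable via
   `max_other_umis`), ranked by own UMIs (ties by barcode), top 70.
   Fewer eligible cells produce a warning, none an error.
2. **Discriminative genes**: route A trains a 500-tree random forest
   (fixed seed) on anchor expression and keeps the top 50 genes by Gini
   importance (mean decrease in impurity — the reading adopted for
   "variation of gini index"). Route B runs Welch's t, two-sample KS and
   Mann–Whitney U per gene, applies Benjamini–Hochberg separately per test
   family, and keeps genes significant at 0.05 in **all three** (the
   conservative AND; the combination rule was unstated). Genes constant in
   both classes are skipped by the tests but stay eligible for the forest.
   The final set is the intersection of the two routes.
3. **Distances**: expression over the final genes is standardised per gene
   by the anchor-pool mean and SD before computing 1 − Pearson (and
   1 − Spearman) against every anchor. Standardisation is essential on
   log-normalised data: the abundance profile shared by every cell
   otherwise dominates the correlation (all correlations ≈ 1) and the
   decision gap collapses.
4. **Minimum-IQR decision**: q1 = 25th percentile (linear interpolation)
   of each distance vector, s = mean of the two sample SDs; the cell takes
   the label of the smaller q1 iff |q1_red − q1_green| > s, else
   `unknown`; an exact q1 tie is `unknown`. Pearson is the reporting
   method; Spearman disagreement is flagged in a `concordant` column.
   Cells with zero variance over the gene set are `unknown`.

On the default simulation (planted ln FC 1.0, 70+70 anchors, 2000 test
cells) the chain labels ≥95% of pure-origin cells correctly with ≤5%
unknown, and the unknown fraction rises monotonically as the planted
separation shrinks towards zero.

## Trajectory and patterns

- **Branches**: a cluster joins a sample-origin branch when >75% (strict)
  of its cells share that origin; otherwise it is split and each cell
  follows its own origin.
- **DEGs**: genes are ranked by total raw counts and the top 1000 tested;
  per group pair, a two-sided Wilcoxon rank-sum per gene with Bonferroni
  correction over the tested genes; records kept at |ln FC| ≥ 0.25 and
  p_adj < 0.01. ln FC is computed on de-logged means of normalised
  expression with pseudocount 1e-9 (the usual single-cell convention).
- **Patterns**: per-gene group means are affinely mapped to [0, 100]
  (min → 0, max → 100; constant profiles map to 0 and join a degenerate
  pattern), then clustered hierarchically with 1 − Pearson distance and
  average linkage (linkage was unstated) and cut into k patterns. The
  pattern lists always partition the input gene set. An explicit
  `pattern_map` can merge fine clusters into named coarse patterns, since
  merging rules are analysis-specific.
- **Trisection**: the pseudotime range [min, max] is cut at thirds into
  Oesophagus / TC / Skin (skin reference fixed at the trajectory
  endpoint). DEGs among the three groups are called as above; the
  TC-exclusive list keeps genes with |ln FC| > 0.2 between Oesophagus and
  TC (absolute value — signedness was unstated). Note the rank test's
  attainable p-value floor scales with the smallest group: below ~15 cells
  in the TC interval, Bonferroni-corrected significance over 1000 genes is
  mathematically out of reach.
- **Smoothing**: a cubic B-spline basis (df 10) penalised GAM fit of one
  gene's expression on pseudotime, with the penalty weight chosen from a
  log-spaced grid (1e-6 … 1e6) by generalised cross-validation; penalties
  whose IRLS fit degenerates (perfect separation on noiseless data) are
  skipped. The grid search replaces the library's built-in penalty
  optimiser, which aborts on exactly-interpolable data. The 95% band is
  the pointwise normal interval from the penalised coefficient covariance.
- **PAC**: k-means (10 restarts, seeded) on the top 50 principal
  components of 100 subsamples of 80% of cells; the consensus matrix
  entry (i, j) is the co-clustering fraction among co-sampled pairs;
  PAC(k) = CDF(0.9) − CDF(0.1) of off-diagonal consensus values. Lower is
  more stable; over-clustering separated data inflates PAC.
- **Fallback pseudotime**: where no trajectory tool output is supplied,
  cells are ordered by correlation to the mean profile of a designated
  endpoint group, min-max rescaled. Graph-based trajectory inference is
  out of scope.

## Graft statistics

Rates are events per grafted **cell** (the assays normalise by cell
totals); per-graft rates are reported as a secondary column. The ratio CI
conditions on the total event count: treatment events are binomial with
success probability p = r·C_t/(r·C_t + C_c); a Clopper–Pearson interval on
p maps to the ratio via r = (p/(1−p))·(C_c/C_t). A zero-event control
yields a flagged infinite ratio with a lower bound only. Replacement
efficiency is 100 × replaced/original.

## Pipeline

Stages run in dependency order with per-stage seeds derived from the
global seed by hashing (blake2, reduced below 2³¹), all hand-offs through
files in the output directory, and a JSON run report of parameters and
per-stage summaries. Configs are flat YAML validated field-by-field with
named error messages. Disabling QC while classifying triggers a logged
warning (classification then runs on log-normalised raw counts).

## Problem sizes

The bundled analysis scripts simulate 600 cells per sample (~2550 cells,
4000 genes), chosen so every stage — including rank-test significance in
the smallest trisection group — operates in its intended regime; the test
suite uses smaller configurations per property. The reproduction script
(`scripts/acceptance.py`) uses 2140 cells for classifier recovery, 200
replicates for the DEG null, and 1000 random vector pairs for the
minimum-IQR oracle check.

## Known limitations

- The normalisation stand-in (log-CP10K) differs from variance-stabilising
  transforms; thresholds interacting with normalised scales (the marker
  density filter) would shift under a different normalisation.
- The marker density filter's any-marker OR rule excludes cells with
  single stray counts when a marker's threshold sits just above zero.
- Sub-transcript counts depend on the alignment scoring; the shipped
  scores are standard for DNA but not the only defensible choice.
- The classifier's accuracy depends on anchors being truly pure; heavy
  reporter leakage or index hopping would contaminate the anchor sets.
- PAC uses a k-means/PCA backend; a different clustering backend changes
  absolute PAC values (relative ordering across k is the robust signal).
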