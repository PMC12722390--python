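# lineaconv

Analysis toolkit for single-cell studies of **oesophageal-to-skin lineage
conversion** in heterotypic (epithelium × foreign stroma) culture and
grafting experiments. When adult oesophageal epithelium (constitutively
tdTomato⁺, "red") regrows over denuded skin dermis, a small fraction of
cells converts towards skin identity; an EGFP⁺ in vitro skin reference
("green") spiked into the libraries pins down what skin identity looks
like. `lineaconv` implements the computational stages such an experiment
needs:

- **`synthetic`** — a seeded negative-binomial simulator of the whole
  design: two origins with planted marker genes, a transitioning-cell
  continuum along a latent pseudotime, mito/ribo content, depth variation,
  dropout, doublets, contaminant stromal/immune cells and per-UMI reporter
  reads, plus Poisson graft-count simulation and a synthetic red/green
  reporter sequence pair.
- **`reporter`** — selection of reporter *sub-transcripts* (segments of
  each reporter with windowed cross-identity < 20% under a global
  alignment, so reads on them are unambiguous) and per-cell reporter
  expression as sums of deduplicated UMIs.
- **`qc`** — the cell-inclusion gate (depth > 8750 UMIs, 2000–8000
  expressed genes, mito% < 15, ribo% < 45), log-CP10K normalisation, and
  removal of non-epithelial cells whose *Col1a2*/*Pdgfra*/*Ptprc*
  expression exceeds the first local minimum of a kernel density estimate.
- **`classifier`** — a semi-supervised origin classifier: ~70 anchor cells
  per marker with independent reporter expression; discriminative genes
  from a random-forest Gini route intersected with a t/KS/Mann–Whitney
  route (BH-adjusted p < 0.05); labels from the **minimum-IQR rule** on
  1 − correlation distances: a cell is labelled by the closer anchor set
  only when |q1_red − q1_green| exceeds the mean of the two distance SDs,
  else `unknown`.
- **`trajectory`** — branch assignment by a strict >75% cluster-composition
  rule; pairwise Wilcoxon rank-sum DEGs (Bonferroni, |ln FC| ≥ 0.25,
  p_adj < 0.01) over the 1000 most abundant genes; expression patterns from
  hierarchical clustering (1 − Pearson) of per-gene group profiles affinely
  scaled to [0, 100]; pseudotime trisection into Oesophagus / Transitioning
  Cells / Skin with transition-exclusive genes (|ln FC| > 0.2 vs
  Oesophagus); penalised-spline smoothing with 95% bands; and clustering
  stability via PAC (proportion of ambiguous clustering).
- **`graft`** — per-cell event-rate ratios for hair-follicle reconstitution
  assays with exact conditional-binomial confidence intervals, and
  replacement-efficiency percentages.
- **`pipeline` / CLI** — a seeded end-to-end orchestrator
  (`lineaconv run --config pipeline.yaml`) with subcommands `simulate`,
  `reporter select|quantify`, `qc` and `graft`.

## Worked example

The numbered scripts under `analysis/` run the stages on a simulated
experiment (seed 1) and write tables under `results/`:

```sh
python analysis/01_simulate.py
python analysis/02_reporter_quant.py
python analysis/03_qc.py
python analysis/04_classify.py
python analysis/05_trajectory.py
python analysis/06_graft_stats.py
```

Selected output, with what it means:

```
red: 5 sub-transcripts ... (planted: 5)   green: 3 sub-transcripts ... (planted: 3)
```
Sub-transcript selection recovers every reporter-specific region planted in
the synthetic red/green pair (the red reporter mirrors a tandem-dimer
architecture, hence more specific regions).

```
inclusion gate: kept 2196/2551 cells
marker density filter: removed 402 cells (99 planted contaminants of 101)
```
The QC gate removes low-depth/high-mito cells; the density rule catches
nearly all planted stromal/immune contaminants (plus cells with stray
ambient counts on any of the three markers — the rule is an OR).

```
pure cells (n=1578): accuracy vs planted origin 99.9%, unknown 0.1%
transitioning cells (n=59): called {'red': 23, 'green': 20, 'unknown': 16}
```
Pure-origin cells are labelled almost perfectly, while cells genuinely in
transit between identities scatter across red/green/unknown — exactly the
ambiguity the minimum-IQR rule is designed to expose.

```
TC-exclusive genes: 57 (13/20 planted recovered)
```
Trisecting the conversion pseudotime and filtering on |ln FC| > 0.2 vs the
oesophageal state recovers most of the planted transitioning-cell genes
(recovery is limited by the small middle-third group, n = 18).

```
hif1a-inhibited: rate ratio vs control = 5.44 (~5.4x), 95% CI [2.34, 12.89]
sox9-inactivated: rate ratio vs control = 9.17 (~9.2x), 95% CI [4.85, 18.81]
```
From the pooled grafting counts (14 events / 3×10⁶ cells and
55 / 7×10⁶ vs control 12 / 14×10⁶), lifting the HIF1a–SOX9 regenerative
barrier raises the per-cell hair-follicle formation rate ~5.4× and ~9.2×.

## Layout

```
src/lineaconv/     library (all computation lives here)
analysis/          numbered narrative drivers over the library
tests/             pytest suite incl. the acceptance properties
scripts/           acceptance.py reproduction script
docs/methods.md    models, parameters, design choices, limitations
```
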