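# Methods

This note documents the models, numerical conventions and design choices
behind `crossova`, and what the synthetic benchmark does and does not
establish about real data.

## Synthetic multi-species generator

Counts are negative binomial, sampled as a Gamma–Poisson mixture with a
single global dispersion φ (default 0.3, variance `μ + φμ²`) — the
standard scRNA-seq noise model with one knob.  The log-mean of gene *g*
in cell *c* of species *s* is

```
log μ = b_g + e_{s,g} + marker(type(c), g)
        + log a_{c,r} (regulon multiplier) + log pathway effect + log L_c
```

- `b_g ~ N(0,1)` is a shared baseline; `e_{s,g} ~ N(0, σ_s²)` is a
  per-species shift (σ_s configurable per species, default 0.3).
- Marker programs add a natural-log fold change (default 2.0) to 20 genes
  per cell type, shared across species; optional private programs add
  species-specific marker sets (default 8 genes) for designated
  (species, cell type) pairs.  **Marker-program genes sit at a common
  baseline (b = 0)** so every type's planted program claims the same
  expected share of the library.  Without this, the random baseline draw
  hands each cell type a different total-count boost, and depth
  normalization converts that imbalance into spurious ±0.1–0.3 log2 fold
  changes on *unrelated* genes — a compositional artifact that would
  contaminate the marker ground truth.
- Regulons: each TF plus (default) 15 targets is driven by a latent
  per-cell Gamma multiplier of mean 1 (shape 4), scaled by
  `exp(activity_lfc)` (default 1.0) in the regulon's designated cell
  type.  This produces the target co-expression AUCell detects without
  simulating motifs.
- Pathways: (default) 10 gene sets of 10 genes drawn from a shared pool,
  so sets overlap (a gene may belong to several pathways); a configurable
  fraction carries a multiplicative mean shift (default 2-fold) in one
  designated cell type.
- QC truth: 5% of genes carry the `MT-` symbol prefix; a 5% "low-quality"
  cell subset has its mitochondrial means boosted 8-fold so the mito
  filter has genuine positives.  Library sizes are log-normal per cell
  (σ = 0.3) around the configured mean.

Marker, regulon and pathway genes come from disjoint pools so every
planted signal is attributable to one mechanism.  Species gene ids are
species-prefixed while reference symbols are shared, making ortholog
translation non-trivial; the generated ortholog table labels exactly
`round(frac_one2one × n_genes)` reference genes `one2one_ortholog` in
every species (planted genes first, so ground truth survives
harmonization), the rest `one2many` or `none`.

What the generator does **not** emulate: ambient RNA, doublets, batch
effects beyond the species shift, gene-length or GC biases, realistic
gene-gene correlation beyond the planted programs, or cross-species
differences in assay sensitivity.  Passing tests therefore demonstrate
the statistics' correctness and calibration under a faithful NB model of
the planted structure — not robustness to every artifact of real tissue.

## QC and normalization

"Fewer than 200 genes" and "more than 10% mitochondrial" are read as
strict removal bounds: keep `n_genes_detected ≥ min_genes` and
`mito_fraction ≤ max_mito` (a cell at exactly 10% stays).  The gene
filter (detected in ≥ 3 cells) runs *after* the cell filter.
Mitochondrial genes are identified by a configurable, case-insensitive
symbol prefix (default `MT-`), matched on the features-file symbol column
when present.  Applying the filter twice can in principle remove further
cells (removed genes lower detection counts); at realistic thresholds the
operation is idempotent and the suite checks that.

Normalization is `ln(1 + count/total × 10⁴)` (natural log, scale 10,000 —
the conventional defaults).  HVGs follow the vst recipe: per-gene raw
count mean and variance, a lowess trend of log10 variance on log10 mean
(span 0.3), standardized values clipped above at √n, and the uncentred
variance of the clipped values as the ranking statistic, ties broken by
gene id.  With a batch key, genes are ranked per replicate and combined
by how many replicates select them, then median rank (pooled computation
available by omitting the key).

## Ortholog harmonization

Only genes annotated `one2one_ortholog` in every analysed species are
kept; each matrix is re-indexed to reference symbols in one shared sorted
order.  Genes mapped in the table but absent from any matrix are dropped
globally rather than zero-filled — zero-filling would fabricate absence
signal.  Expression values are never altered.  No corrected embedding is
computed: all downstream statistics operate on expression in the shared
gene space, so results are interpretable gene-wise, at the cost of not
removing residual species effects the way anchor-based integration would.

## Neighbor voting

The unsupervised variant: the cross-species question is precisely whether
labels transfer, so no within-dataset supervision is used.  Similarity is
the Spearman correlation over the union of per-species HVGs restricted to
shared orthologs, rank-normalized per cell to (0,1] with midranks; votes
are degree-normalized; AUROC uses midranks (equal to the Mann–Whitney
U statistic divided by n₊n₋, which the tests assert to 1e-12).  The two
training directions are averaged; the diagonal is 1 by convention and
same-species off-diagonal entries are left undefined.  Being rank-based
end to end, the score is invariant to any monotone transform of
expression.  Groups under 2 cells are excluded with a warning.

## Regulon statistics

AUCell ranks genes per cell with ties broken by ascending gene id — a
deterministic choice where the reference tool randomizes; reproducibility
is preferred and documented.  The top fraction is 0.05 (the reference
tool's default).  The score is the recovery-curve area divided by its
maximum, so it is 1 exactly when the set occupies the top ranks and 0
when no member enters the threshold.

RSS uses base-2 Jensen–Shannon divergence so both JSD and RSS live in
[0,1].  "AUCell score > 0.1" is interpreted as the mean AUCell over the
cells of the type (the per-cell reading is not well defined for a
type-level call); RSSZ is z-scored across regulons within each cell type,
which identifies type-specific regulators — the other axis is available
via `z_axis="within_regulon"`.

CSI uses cell-level activity correlations, strict inequalities, and the
N−2 denominator (A and B excluded).  Module detection screens for at
least one off-diagonal CSI strictly above 0.8, Ward-clusters `1 − CSI`,
and cuts at a user-chosen k (a silhouette-based suggestion is provided;
no selection rule is imposed).

Importance estimation is pluggable.  The default `correlation` estimator
is deterministic: IM = |Spearman ρ| × 10, mapping correlation onto the
conventional IM axis where 1 marks a moderate association.  The
`tree_ensemble` estimator fits one seeded random-forest regression per
target and rescales sklearn's normalized importances by the regulator
count, so 1 is the importance of an average regulator.  Target extraction
uses a strict IM > threshold.

## Pathway activity

Relative expression normalizes each gene's per-type mean by its average
across types (1 = average), excluding genes with zero mean everywhere.
Outlier trimming pools each pathway's relative values over cell types
(the "within each pathway" reading; per-type trimming available by flag)
and removes values above 3×Q75 or below Q25/3, with linear-interpolation
quantiles.  Weights are 1 / (number of supplied pathways containing the
gene).  The permutation test shuffles cell-type labels uniformly and
reruns the entire computation; because a gene with any counts keeps a
positive pooled mean under every relabeling, gene exclusion is
permutation-invariant and is precomputed.  The default test is two-sided
on |activity − 1| with the add-one correction
`p = (1 + #{perm ≥ obs}) / (1 + n_perm)`; a one-sided variant is exposed.
Under label-independent data the p-values are uniform (KS-checked in the
suite) and the false-positive rate at α = 0.05 is calibrated.

Cohen's d uses the pooled-SD convention and refuses degenerate inputs
(n < 2 or zero pooled variance).

## Markers

Fold changes are computed on de-logged normalized means with ε = 1e-9
(the convention of the standard toolchain); Bonferroni divides by the
number of genes tested in that comparison (post-QC), not the genome.
Markers are the positive side only; the DE table itself is two-sided.
The cross-species partition adds an explicit *intermediate* bucket for
genes shared by some but not all species — the three buckets are disjoint
and cover the mapped union, which the suite asserts.  Conservation is
strict intersection across all listed species.

## Problem sizes

The demo study and test suite run three species × 600 cells × 500 genes
(12 regulons, 10 pathways), with 200–1000 permutations and 10–20 seeds
for the power and calibration checks — sizes chosen so the full analysis
reruns from scratch in about a minute while keeping every group large
enough (≥ 140 cells/type after QC) for the asymptotic Wilcoxon and the
permutation nulls to behave.

## Known limitations

- The AUROC matrix leaves same-species comparisons undefined rather than
  cross-validating within species.
- The vst trend uses lowess on all positive-variance genes; with very few
  genes (< ~10) the trend is unstable and rankings should not be
  over-read.
- The asymptotic Wilcoxon p is an approximation below ~8 cells per group
  (the suite documents agreement with exact enumeration to |Δp| < 0.06 at
  4 vs 4).
- `k`, the module count, is a user decision; the silhouette suggestion is
  advisory only.
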