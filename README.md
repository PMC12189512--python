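# crossova

Cross-species single-cell comparative statistics for the vertebrate ovary
(and any other tissue with shared cell-type vocabularies): quality control
and one-to-one ortholog harmonization, neighbor-voting AUROC cell-type
replicability, regulon activity / specificity / module structure,
permutation-based metabolic pathway activity, and the partition of
cell-type markers into cross-species conserved versus species-specific
sets.  A synthetic multi-species generator with planted ground truth makes
every stage testable without any downloads.

## Who this is for

Comparative transcriptomics of ovarian cell types — granulosa, theca,
endothelial, immune, smooth-muscle, epithelial — across species (e.g.
zebrafish, mouse, donkey, macaque, human) asks three recurring questions:
which cell types are transcriptionally conserved, which regulatory
programs drive them, and which expression programs are private to one
lineage.  This package implements the statistics those questions need as
plain, tested Python functions over `AnnData` matrices.

## The statistics

- **Neighbor-voting AUROC** (MetaNeighbor-style). Build a cell–cell
  Spearman similarity network over highly variable genes, rank-normalize
  it per cell, let each test cell accumulate degree-normalized votes from
  a training species' cell type, and score the votes by AUROC against the
  test species' labels, averaging both training directions:
  `vote(b) = Σ_{a∈A_t} S[b,a] / Σ_{a∈A} S[b,a]`.
- **AUCell** activity: per cell, the normalized area under a regulon's
  recovery curve within the top 5% of the cell's expression ranking.
- **RSS** (regulon specificity): `RSS = 1 − √JSD₂(p, q)` between the
  regulon's activity distribution `p` over cells and the cell-type
  indicator `q`; z-scored across regulons within a type (RSSZ), with
  significance at mean AUCell > 0.1 and RSSZ > 1.
- **CSI** (connection specificity index): for regulons A, B, the fraction
  of other regulons whose Pearson correlation with both A and B is below
  PCC(A,B); Ward clustering of `1 − CSI` above the 0.8 screen yields TF
  modules.
- **Pathway activity**: gene-wise relative expression
  `r(g,t) = mean(g,t) / mean over types`, trimmed at 3×Q75 and Q25/3
  within each pathway, averaged with weights 1 / (pathway membership
  count); significance by shuffling cell-type labels (default 5000
  permutations, add-one corrected two-sided p on |activity − 1|), effect
  sizes by Cohen's d with the pooled SD.
- **Markers**: two-sided Wilcoxon rank-sum with midranks, tie and
  continuity correction; Bonferroni-adjusted p < 0.05 and |log2FC| > 0.25;
  per-type marker sets are mapped through the one-to-one ortholog table
  and split into conserved (all species), species-specific (exactly one)
  and intermediate buckets.

## Worked example

The numbered drivers under `analysis/` run the full demo study — three
synthetic species sharing conserved cell-type programs, with one species
(`spC`) carrying a private granulosa program:

```bash
python analysis/01_simulate.py            # writes results/data/
python analysis/02_qc_normalize.py
python analysis/03_harmonize_orthologs.py
python analysis/04_celltype_similarity.py
python analysis/05_regulon_programs.py
python analysis/06_pathway_activity.py
python analysis/07_marker_conservation.py
```

Output of the run (each line printed by the corresponding driver):

```
simulated 1800 cells in 3 species, 500 genes, 12 regulons, 10 pathways -> results/data
spA: removed 30/600 cells (30 over the mito bound), 0 genes
450 one-to-one orthologs across 3 species; 450 present in every matrix (0 dropped), 1710 cells total
matched-type AUROC mean 1.000 (min 1.000); mismatched mean 0.333
Spearman rho over 12 (pair, type) comparisons: mean 0.975, min 0.950
12 regulons scored on 570 spA cells; 7 significant (regulon, type) calls (mean AUCell > 0.1 and RSSZ > 1)
4 CSI modules over 12 regulons; ARI vs RSS-called programs 1.00
planted pathway shifts detected at p<0.05: 5/5
conserved granulosa markers: 75; spC-specific recovered 8/8 planted (exact)
```

Reading: matched cell types replicate perfectly across species while
mismatched pairs sit at the 1/3 baseline expected with three alternative
types; the twelve planted regulons cluster into exactly their four
programs; every planted 2-fold pathway shift is significant; and the
marker partition returns the private granulosa program of `spC` exactly,
with the conserved bucket holding the shared programs (planted markers
plus regulon-target and pathway genes elevated in granulosa everywhere).

The same pipeline is scriptable end to end from one YAML config:

```bash
crossova run --config demo.yaml --out run1 --seed 7
```

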