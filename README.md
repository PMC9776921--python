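# mdconet

Differential co-expression analysis for paired two-condition cohorts:
weighted co-expression modules, the **modular differential connectivity
(MDC)** permutation statistic, enrichment scoring, three-criterion
key-gene prioritisation, and a cross-validated ROC classifier — with a
synthetic-cohort generator that plants the statistical structure the
analysis assumes, so every stage can be validated against known truth.

## The problem

Progressive diseases such as atherosclerosis are often profiled as
two-condition expression cohorts (non-plaque vs plaque tissue, early vs
advanced lesions). Classical differential expression asks which genes
change in *mean*; it misses changes in *co-regulation* — modules of
genes whose mutual correlation tightens or dissolves as disease
advances. This package implements the full analysis graph for that
question on any pair of gene-by-sample matrices:

1. **Differential expression** per cohort (Welch's t on the log2 scale,
   Benjamini–Hochberg adjustment), top-K up/down selection and
   cross-cohort intersection into common regulated gene lists.
2. **Weighted co-expression networks** per cohort: variance filter,
   unsigned adjacency `a_ij = |cor(x_i, x_j)|^β`, topological overlap
   `TOM_ij = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij)` with
   `l_ij = Σ_u a_iu a_uj`, average-linkage clustering of `1 − TOM`,
   a static tree cut, and iterative merging of modules whose eigengenes
   (first principal component of the standardized module submatrix)
   are closer than 0.25 in correlation dissimilarity.
3. **Modular differential connectivity**: for each module,
   `MDC = r̄_A / r̄_B`, the ratio of the mean absolute pairwise member
   correlation computed in condition-A versus condition-B samples, with
   an empirical p-value from label-shuffling permutations of
   `|log2 MDC|` (1000 permutations, pseudocounted).
4. **Enrichment**: hypergeometric over-representation (ORA) with BH
   adjustment, and a weighted running-sum enrichment score (GSEA-style)
   with a "gene set" permutation null.
5. **Key genes**: the intersection of three criteria over the common
   regulated genes — top-20 degree in the candidate-induced PPI
   subgraph, top-20 count of significant pathways containing the gene,
   and module hubness (`|kME| > 0.85` with the eigengene of a module in
   which the candidates are over-represented).
6. **Classification**: ridge-stabilised logistic regression on the
   key-gene panel, 3-fold stratified cross-validated ROC/AUC, compared
   with random same-size gene panels.

The synthetic generator plants all of this structure (single-factor
Gaussian modules with per-condition correlation, disease-axis factor
shifts, shared/private DE genes, a PPI graph whose degree concentrates
on designated key genes, gene sets aligned with the planted DE
structure) and returns the ground truth, which the test suite and the
acceptance script score against.

## Worked example

```python
from mdconet import PipelineConfig, default_config, run_pipeline

config = PipelineConfig(
    simulation=default_config(seed=1),
    n_perm=200, baseline_draws=30, out_dir="run", seed=1,
)
manifest = run_pipeline(config)
print(manifest.results["key_genes"])
print(manifest.results["classifier"])
```

prints

```
['G0000', 'G0001', 'G0002', 'G0003', 'G0100', 'G0101', 'G0102', 'G0103']
{'fold_aucs': [0.96, 0.958333, 1.0], 'average_auc': 0.973333,
 'baseline_mean_auc': 0.766806, 'baseline_draws': 30}
```

All eight planted key genes (four up-regulated in disease module 1,
four down-regulated in disease module 2) are recovered exactly, and the
key-gene logistic classifier separates the two conditions with an
average cross-validated AUC of 0.97, far above the 0.77 mean of random
eight-gene panels drawn from the same transcriptome (random panels sit
above 0.5 because the simulated transcriptome, like a real one,
contains many differential genes).

The `examples/` directory holds one short narrative script per
capability (simulation, differential expression, module detection, MDC,
enrichment, key genes + classifier); each prints the numbers it
computes and a line on what they mean. A thin CLI mirrors the stages:

```bash
mdconet simulate --seed 1 --out data/
mdconet run --seed 1 --out run/
```

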