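# mirlink

Paired miRNA–mRNA analysis for two-group cohort designs: negative-binomial
differential expression, pre-ranked gene-set enrichment, an all-pairs
Pearson negative-correlation screen intersected with miRNA target-database
evidence, and bipartite regulatory-network assembly — plus the supporting
cohort, qPCR, and reporter-assay statistics.

The package is aimed at transcriptomics studies that profile both mRNA and
small RNA from the same small patient cohorts (here: dilated cardiomyopathy
of volume-overload vs. ischemic etiology, 3–9 samples per arm) and want to
nominate miRNA→target relationships from the joint data. Because candidate
screens at this scale cannot be validated on the real cohort alone, the
package ships a first-class synthetic-data generator that plants known
differential expression and repressive miRNA→gene couplings, so every stage
of the pipeline can be tested against ground truth.

## The model in brief

- **Differential expression.** Counts are modelled per feature as
  NB(μ, α) with Var = μ + αμ². Per-sample size factors come from the
  median-of-ratios estimator; dispersions are moment estimates moderated
  toward a parametric mean–dispersion trend; the group contrast is a Wald
  test on the NB GLM coefficient, with Benjamini–Hochberg FDR control.
  Features pass the screen when |log2FC| > 0.5 and adjusted p < 0.05
  (strict inequalities).
- **Pre-ranked GSEA.** Genes ranked by signed log2FC; the enrichment score
  ES is the signed extremum of the weighted Kolmogorov–Smirnov running sum
  (weight p = 1); significance and the normalized score NES come from a
  gene-permutation null with (b+1)/(m+1) smoothing.
- **Interactome screen.** Pearson r for every DE-miRNA × gene pair on
  log2(normalized count + 1) expression, p from t = r√((n−2)/(1−r²));
  pairs with r < −0.7 and p < 0.05 are intersected with validated
  (TarBase, miRTarbase) and predicted (DIANA-microT, ElMMo, PITA) target
  evidence and assembled into a bipartite network.
- **Cohort/bench statistics.** ROUT outlier detection (Q = 1%),
  Shapiro–Wilk-gated Student t / Mann–Whitney comparisons (also from
  printed mean ± SD summaries), uncorrected 2×2 chi-square, 2^−ΔΔCt
  relative quantification with multi-reference normalization, and
  dual-luciferase ratio analysis.

## Worked example

```python
import numpy as np
from mirlink import simulate, de, interactome

cfg = simulate.SimConfig(seed=1, n_genes=400, n_mirnas=60, n_de_genes=30)
mrna, mirna, meta, truth = simulate.generate_paired_counts(cfg)
evidence = simulate.generate_evidence_fixture(
    truth, n_decoys=40, seed=2,
    gene_ids=mrna.feature_ids, mirna_ids=mirna.feature_ids)

mirna_de = de.de_test(mirna, meta)              # 4 VCM vs 3 ICM samples
de_mirnas = list(de.filter_de(mirna_de).index)  # |log2FC|>0.5, padj<0.05
records = interactome.correlate_pairs(mirna, mrna, meta, mirna_ids=de_mirnas)
edges = interactome.merge_evidence(interactome.filter_negative(records), evidence)
graph, summary = interactome.build_network(edges, de.de_test(mrna, meta), mirna_de)
print(summary)
for e in edges:
    print(e.mirna_id, e.gene_id, round(e.r, 3), round(e.pvalue, 4), e.validated)
```

prints

```
{'n_mirnas': 4, 'n_genes': 4, 'n_edges': 4}
mir-0029 G00105 -0.904 0.0052 True
mir-0034 G00356 -0.992 0.0 True
mir-0041 G00050 -0.952 0.001 False
mir-0051 G00014 -0.951 0.001 False
```

i.e. the four planted repressive pairs (`truth.repressive_pairs`) are
recovered — each with strong negative correlation across the seven samples
— and none of the 40 decoy evidence rows survives the screen.

The same pipeline is available from the shell:

```sh
mirlink simulate --seed 1 --out-dir run/
mirlink de --counts run/mrna_counts.tsv --meta run/meta.tsv --out run/de.tsv
mirlink run-all --seed 1 --out-dir run_all/   # full chain + manifest
```

A clinical baseline table of printed group summaries (mean ± SD or %) can
be scored with `mirlink cohort --clinical table.tsv --out baseline.tsv`;
the packaged example table reproduces published two-group p-values such as
Age 0.637 and Aspirin 0.003.

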