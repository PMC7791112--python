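# permdeg

Permutation-based differential expression for small two-group RNA-seq
designs, with the downstream annotation stages that typically follow it:
transcription-factor (TF) target enrichment, gene-set enrichment, promoter
motif scanning, and assembly of a fold-change-annotated interaction network.

## Who this is for

Bulk RNA-seq comparisons with very few replicates (the motivating design is
3 wild-type vs 3 knockout muscle samples quantified as FPKM) are poorly
served by parametric p-values alone. `permdeg` implements a
permutation-calibrated caller that combines two complementary per-gene
statistics and derives its fold-change cutoff from the permutation null
itself, then carries the resulting DEG list through Fisher's-exact
enrichment, a major-TF selection rule, JASPAR-style position-weight-matrix
(PWM) scanning, and network export for viewers such as Cytoscape. A
synthetic-data module generates every input with planted ground truth, so
the whole pipeline is testable end to end without external downloads.

## The method

For each expressed gene (FPKM ≥ 1 in at least one sample) on
quantile-normalized log2 expression:

1. **Two observed statistics** — the pooled-variance Student *t* statistic
   and the log2-median-ratio (difference of group medians,
   *fc* = median(KO) − median(WT)).
2. **Permutation null** — group labels are reassigned over the samples
   (default 1000 random reassignments; a 3v3 design also supports exhaustive
   enumeration of all C(6,3) = 20 assignments), and both statistics are
   recomputed. By default permuted values are pooled across genes.
3. **Empirical p-values** — two-sided with add-one correction,
   p = (1 + #{|null| ≥ |obs|}) / (1 + N).
4. **Stouffer combination** — z_i = max(Φ⁻¹(1 − p_i), 0) · sign_i,
   z_c = (z_t + z_fc)/√2, p_c = 2(1 − Φ(|z_c|)). Concordant statistics
   reinforce; discordant ones cancel.
5. **Fold-change cutoff** — (|q₂.₅| + |q₉₇.₅|)/2 of the pooled null
   log2-fold-change distribution.
6. **DEG call** — p_c < 0.05 AND |fc| strictly above the cutoff; direction
   from the sign of *fc*.

Downstream: a TF is *major* when its targets overlap the DEG list in ≥ 5
genes with one-sided Fisher p < 0.05; gene sets are enriched at p < 0.05;
motif hits are PWM windows with relative score
(S − S_min)/(S_max − S_min) > 0.9.

## Worked example

Run the fully simulated pipeline (12 000 genes, 3v3, 5% planted DE at a
4-fold effect, 20% silent genes) from the shell:

```bash
permdeg run-all --outdir demo_run --seed 1
```

or drive the engine directly:

```python
from permdeg import (SimulationParams, simulate_expression, DegCallParams,
                     call_degs, filter_expressed, log2_transform,
                     quantile_normalize)

study = simulate_expression(SimulationParams(n_genes=12000, seed=1))
matrix = quantile_normalize(
    log2_transform(filter_expressed(study.matrix), offset=0.0))
table, summary, null = call_degs(matrix, study.design,
                                 DegCallParams(n_perm=1000, seed=1))
print(summary)
```

which prints (seed 1):

```
{'n_genes_expressed': 9599, 'cutoff_log2': 1.3093913415107004,
 'cutoff_fold': 2.478369580149641, 'n_deg': 593, 'n_up': 297,
 'n_down': 296, 'alpha': 0.05, 'n_perm': 1000, 'null_mode': 'pooled',
 'seed': 1}
```

Reading: 9 599 of 12 000 genes pass the expressed-gene filter (the planted
20% silent fraction is removed, plus low-baseline genes); the null-derived
fold-change cutoff realizes at 1.31 on the log2 scale (≈ 2.5-fold); 593
genes pass both gates, split 297 up / 296 down in the knockout. Against the
planted truth this run recovers 98.7% of the differential genes with a
false-discovery proportion of 0.002.

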