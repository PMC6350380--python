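# wtofid

Benchmarking **weighted topological overlap (wTO)** against base correlation
as a gene co-expression score when only a handful of samples is available.

Co-expression networks are usually built by thresholding a gene × gene
correlation matrix. With few measurements per gene (10–50 samples), the
correlation estimates are noisy and the resulting networks are dominated by
spurious links. The wTO score augments the direct link weight between genes
*i* and *j* with the summed products of their shared-neighbour weights,

```
              w_ij + Σ_{k≠i,j} w_ik · w_kj
wTO(i, j) = ─────────────────────────────────
             min(Σ_{k≠i} w_ik, Σ_{k≠j} w_jk) + 1 − w_ij
```

where `w_ab = |cor(a, b)|` is the absolute correlation (Spearman or biweight
midcorrelation, optionally soft-thresholded as `|cor|^β`, β = 6 by default).
Because each wTO value pools information from every shared neighbour, it is a
smoothed, noise-resistant functional of the correlation matrix. This package
quantifies that robustness with three self-contained experiments on
synthetic expression data:

1. **Fidelity under subsampling.** An ensemble of disjoint 1000-gene groups
   with planted correlated modules is generated at full quality
   (338 samples) and nested-subsampled to 10/20/50 samples. For each group
   and quality, the rank agreement (Spearman) and top-1000 Jaccard overlap
   between the low-quality and full-quality score vectors are computed for
   the base correlation and for wTO, and per-group differences are tested
   with the Wilcoxon signed-rank test.
2. **False positives on truth-free data.** I.i.d. uniform expression data
   contains no real co-expression; any pair exceeding a realistic network
   cutoff is a false positive. Spearman and wTO scores of 20 null groups
   are thresholded at shipped reference cutoffs (90th/95th/99th percentiles
   of each score over full-quality whole-blood reference data).
3. **Network topology.** Unweighted networks from the top 0.2% of pairs are
   summarised (size, clustering, degree assortativity, Louvain communities,
   modularity, hub overlap) to show how the choice of score reshapes the
   network.

## Worked example

```python
from wtofid import BenchmarkConfig, run_benchmark

cfg = BenchmarkConfig(
    mode="modular", n_groups=8, group_size=300, n_samples=100,
    n_blocks=6, block_size=20, rho=0.7, qualities=(10, 20),
    metric="bicor", top_k=300, network_fraction=0.01,
    percentiles=(90, 95), seed=7, out_dir="demo",
)
tables = run_benchmark(cfg)
print(tables["comparison"].to_string(index=False))
```

```
 quality      statistic  n_groups  n_superior_wto  mean_difference  p_value
      10 rank_agreement         8               8         0.087501 0.007812
      20 rank_agreement         8               8         0.231757 0.007812
```

In all 8 groups the low-quality wTO predicts its full-quality reference
better than the base bicor predicts its own reference (at 10 samples the
mean rank agreement improves by 0.088); with 8/8 concordant groups the
two-sided exact Wilcoxon p-value is 2/2⁸ ≈ 0.0078, its minimum possible
value at this ensemble size. The false-positive table from the same run
shows the other half of the story:

```
 percentile  quality  cutoff_spearman  cutoff_wto  fpr_spearman  fpr_wto
         90       10           0.5879      0.4826      0.073542      0.0
         95       10           0.6848      0.5202      0.035117      0.0
         90       20           0.5879      0.4826      0.007536      0.0
         95       20           0.6848      0.5202      0.001182      0.0
         90      100           0.5879      0.4826      0.000000      0.0
         95      100           0.6848      0.5202      0.000000      0.0
```

At 10 samples, 7.4% of truth-free gene pairs pass the 90th-percentile
Spearman cutoff, while wTO lets none through at its matched cutoff. The
`networks.tsv` table records the topological price: wTO networks are
smaller, far more clustered, less degree-assortative and split into fewer,
less modular communities than correlation networks built from the same
data.

The same stages are available from the shell:

```bash
wtofid simulate --genes 300 --samples 100 --mode modular \
    --block-sizes 20,20,20 --rho 0.7 --seed 7 --out expr.tsv
wtofid correlate --metric bicor --in expr.tsv --out weights.tsv
wtofid wto --in weights.tsv --out wto.tsv
wtofid network --in wto.tsv --fraction 0.01 --summary-out summary.tsv
wtofid all --config config.yaml
```

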