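# Methods

## Scores

**Base correlation.** Two pairwise metrics are implemented for expression
profiles (rows of a genes × samples matrix):

* *Spearman correlation* — Pearson correlation of the average-rank
  transforms of the two profiles. Ties receive average ranks. A constant
  profile has zero rank variance; its correlations are defined as 0 and a
  warning is logged rather than propagating a 0/0.
* *Biweight midcorrelation (bicor)* — per profile `x`, let `m = median(x)`
  and `MAD = median(|x − m|)`; set `u = (x − m) / (9·MAD)` and weights
  `(1 − u²)² · 1(|u| < 1)`. The correlation is the normalised cross-product
  of the weighted, median-centred profiles. Observations further than nine
  rescaled MADs from the median receive zero weight, which makes the
  estimate robust to gross outliers while agreeing with Pearson on clean,
  tightly clustered data. Profiles with `MAD = 0` (more than half the
  values identical) fall back to mean-centring (Pearson behaviour) for
  that profile, with a warning; this is the established convention for the
  metric.

**Weights and soft thresholding.** Network weights are absolute
correlations, optionally raised to a power β (`|cor|^β`, default β = 6
where soft thresholding is requested). Exponentiation accentuates strong
links but is strictly monotone on [0, 1], so it never changes the relative
ranking of the weights — a property the test suite asserts exactly. The
weight-matrix diagonal is zero by convention: self-similarity carries no
network information, and the zero diagonal is what lets the wTO matrix
product below exclude self-terms without correction.

**Weighted topological overlap.** For a symmetric weight matrix *W* with
zero diagonal and entries in [0, 1],

    wTO(i, j) = [ w_ij + Σ_{k≠i,j} w_ik·w_kj ]
                / [ min(s_i, s_j) + 1 − w_ij ],     s_i = Σ_{k≠i} w_ik.

The node sums exclude the self-term (the standard topological-overlap
convention; including a unit diagonal would shift every denominator by 1).
The whole-matrix implementation is one matrix product — with a zero
diagonal, `(W @ W)[i, j]` already omits the k = i and k = j terms — at
O(N³) cost for N genes, symmetrised and clipped to [0, 1] to absorb float
round-off. A deliberately slow scalar loop (`wto_pair`) implements the
same definition independently; the suite requires the two paths to agree
to 10⁻¹² on random instances, and checks the closed form
`(w + (N−2)w²) / ((N−1)w + 1 − w)` for uniform-weight graphs, which equals
1 for any perfect clique.

## Synthetic data

The generator replaces real expression matrices with two controlled
surrogates:

* **Uniform null** — every entry i.i.d. uniform on [0, 1]. Under a rank
  correlation any i.i.d. continuous distribution is equivalent; uniform
  also keeps the bicor weighting well-behaved. This is the truth-free
  input for the false-positive experiment.
* **Planted modules** — a single-factor model per block:
  `value = √ρ·factor + √(1−ρ)·noise`, factor and noise standard normal, so
  two genes of the same block have population correlation exactly ρ and
  cross-block correlation zero. Defaults in the pipeline: groups of 1000
  genes containing 20 modules of 20 genes (ρ = 0.7), the remaining 600
  genes independent noise. Partial module coverage is deliberate: in real
  tissue transcriptomes tightly co-expressed modules cover a minority of
  genes, and the benchmark's question — can neighbourhood information
  separate genuine module pairs from spuriously correlated ones? — only
  exists when both kinds of gene are present. With every gene forced into
  a module the model becomes homogeneous: all within-block true
  correlations are equal, there is no true ranking left for wTO's
  neighbourhood averaging to recover, and the wTO advantage disappears.
  Passing the directional tests on this generator therefore shows that
  the mechanism operates in a module-plus-background regime, not that the
  magnitudes transfer to any particular real data set.

What the generator does **not** emulate: heavy-tailed and count-like
marginal distributions, mean–variance coupling, batch structure,
overlapping modules, hub genes with graded memberships, and heterogeneous
correlation strengths within a module. Fidelity magnitudes on real data
will differ; only the directional contrasts are claimed.

**Nested subsampling** mimics measuring fewer samples: one random
permutation of the sample order is drawn per group and quality *q* keeps
the first *q* permuted columns, so the 10-sample set is contained in the
20-sample set, and so on. **Gene partitioning** shuffles gene order once
and cuts disjoint consecutive groups (leftover genes dropped and logged),
equivalent to drawing groups without replacement.

All randomness flows from one root seed through purpose-keyed child
streams (crc32 of a purpose label mixed into a `SeedSequence`), so e.g.
changing the group count cannot perturb sample selection, and every stage
is a pure function of its arguments.

## Fidelity statistics

Score matrices are flattened over the canonical upper-triangle pair order;
comparisons require identical gene lists. *Rank agreement* is the Spearman
correlation of two matched score vectors; identical (or exactly reversed)
rankings short-circuit to ±1.0 so that float round-off in the rank
arithmetic cannot blur an exact invariance. *Top-k Jaccard* (default
k = 1000) compares the sets of k highest-scoring pairs, with boundary ties
broken deterministically by canonical pair order — with continuous scores
ties are measure-zero, so the tie-break only pins down edge cases.

Per-group differences between wTO and base fidelity are paired
observations; they are tested with the two-sided Wilcoxon signed-rank
test, zeros dropped, using the exact null distribution by default
(feasible for the 20-group ensemble; with all 20 differences positive the
two-sided p-value is 2/2²⁰ ≈ 1.9·10⁻⁶). A normal-approximation mode is
available behind a flag for comparability with software that defaults to
it.

## False-positive experiment

Twenty 1000-gene groups of uniform null data are drawn with a full size of
338 samples and nested-subsampled to the configured qualities. Each level
is scored with Spearman weights and with the wTO of those weights
(Spearman is the natural base here: being rank-based, it makes the null
distribution-free). A pair is a false positive when its score strictly
exceeds the cutoff. The shipped cutoffs (Spearman 0.5879/0.6848/0.8303,
wTO 0.4826/0.5202/0.6321 at the 90th/95th/99th percentiles) were derived
from full-quality human whole-blood reference data and are stored as
constants so the protocol is fully self-contained; `percentile_cutoff`
recomputes cutoffs from any reference score ensemble using the
linear-interpolation percentile definition.

An independent oracle validates the Spearman side: under independence the
null of Spearman's ρ is uniform over relative orderings, so
`spearman_null_exceedance` computes P(|ρ| > cutoff) by full enumeration of
the n! permutations (n ≤ 8) or by Monte-Carlo sampling of permutations
(chunked at 5·10⁵ per batch to bound memory). Because pairs within a group
share sample columns, pooled FPR estimates are mildly correlated across
pairs; uncertainty is therefore judged from between-group variation, not
from a binomial count.

## Networks

Hard-threshold networks keep `round(fraction × n_pairs)` top-scoring pairs
(0.2% of the 499,500 pairs of a 1000-gene set → 999 edges; the exact
combinatorial count is used rather than a rounded "500,000"). Only genes
incident to a retained edge become nodes. Summaries report node/edge
counts, mean local clustering, degree assortativity (reported as
undefined, never fabricated as 0, when the graph is degree-regular),
the Louvain community count and modularity (Louvain is randomised, so a
seed is mandatory and recorded), and the top-100 nodes by degree with
ID-based tie-breaks. Hub fidelity between two networks is the overlap of
their top-100 hub lists, computed over the shorter list with a warning
when a network has fewer than 100 nodes.

## Problem sizes and runtime

The package's own experiments run at the full design scale: 20 groups ×
1000 genes, nested qualities 10/20(/50) against a 338-sample reference,
≈10⁷ scored pairs per condition in the false-positive experiment. One
1000-gene wTO evaluation is a single 1000³ matrix product, so the complete
acceptance script finishes in well under a minute on one CPU; unit and
property tests use smaller instances (tens to hundreds of genes) chosen to
exercise the same code paths.

## Known limitations

* The factor-model generator gives every within-module pair the same true
  correlation; fidelity beyond module membership is therefore
  noise-against-noise, and measured rank agreements are much smaller than
  on real data, where correlation strengths vary continuously.
* bicor's Pearson fallback mixes centring conventions for pairs in which
  exactly one profile has zero MAD; this follows the metric's standard
  definition but means such pairs are not strictly a biweight estimate.
* Louvain is a heuristic: the reported modularity is that of the seeded
  best partition found, not a global optimum.
* The shipped reference cutoffs are constants from one tissue's reference
  data; for other data sets they should be recomputed from full-quality
  score vectors via `percentile_cutoff`.
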