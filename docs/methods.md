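# Methods

## The model

`vdsignalflow` infers active signaling flow in a cell population from two
inputs: a directed protein–protein interaction (PPI) network whose edges
carry a consensus orientation of signal flow, and per-condition gene
expression. Signal transduction is modeled as a *network path*: an ordered
node sequence that starts at a cell-membrane receptor, traverses
intermediate proteins along directed edges, and ends at a transcription
factor (TF). For every receptor–TF pair the package enumerates **all**
fewest-hop directed paths (there are usually many of equal length), scores
each path by the **arithmetic mean of its nodes' expression** in a given
condition (endpoints included), pools paths across pairs, and ranks them
globally. The top-k paths are read as the condition's most active
downstream processes. Comparing the top-k edge sets of two conditions
(e.g. vehicle-control vs calcitriol-stimulated Th2 cells) yields the
edges engaged exclusively in one condition.

Assumptions worth stating explicitly:

* **Hops, not weights.** Edges are unweighted; "shortest" means fewest
  interactions. No diffusion, flow or significance model is attached to
  paths.
* **One gene, one protein.** Expression is mapped onto protein nodes
  through a strict one-to-one gene↔protein correspondence; many-to-one
  mappings are rejected rather than aggregated.
* **Directed traversal.** Paths respect edge orientation
  (receptor → … → TF). Weak connectivity is still used for the
  largest-connected-component restriction so pure-source receptors and
  pure-sink TFs are not discarded; `strong=True` is available.

## Expression preprocessing

Raw gene-level counts become per-condition node weights via:

1. **Low-count filter** — drop any gene whose count is below
   `min_count = 5` in *at least one* sample (the literal
   remove-if-low-anywhere rule; exposed as a flag).
2. **Median-of-ratios size factors** — per sample, the median over
   all-positive-count genes of count/geometric-mean. Genes with any zero
   are excluded from the reference set.
3. **Variance-stabilizing transform** — `log2(count/factor + 1)`. This is
   a deliberate, documented stand-in for shrinkage-based regularized-log
   transforms: downstream use is only mean-based path scoring, which is
   insensitive to shrinkage details but does require a log-scale,
   depth-normalized value.
4. **Batch removal** — per gene, ordinary least squares on
   `intercept + condition + batch` indicator design; only the fitted
   batch component is subtracted, so condition-associated signal is
   protected. The operation is idempotent and raises on designs where
   batch is confounded with condition.
5. **ID mapping** — injective source→target rename (e.g. mouse→human
   symbols); unmapped genes drop by default.
6. **Condition means** — arithmetic per-gene mean over each condition's
   samples. Whether a different per-condition summary (median, trimmed
   mean) would serve better is untested; the mean is the configuration
   point `condition_means` exposes.

Nodes in the network but absent from the filtered expression matrix get
the **observed minimum weight** ("floor" policy) by default, so paths may
still route through unmeasured intermediate proteins; the "drop" policy
(remove such nodes) is a stronger assumption and is opt-in.

## Tunable parameters

| parameter | default | units / scale | why |
|---|---|---|---|
| `min_count` | 5 | raw counts | filter rule above |
| `pseudocount` | 1 | counts | keeps log2 finite at zero |
| `top_k` | 50 | paths | no principled value exists; the comparison report records the edge sets so sensitivity at other k is one rerun away |
| `max_paths_per_pair` | 10 000 | paths | caps combinatorial explosion on dense graphs; truncation keeps the lexicographically first paths and is flagged in the result, never silent |
| `missing_policy` | floor | — | see above |
| LD threshold | 0.8 | r² | community convention for "high LD" |
| vitamin-D cutoff | 30 | ng/ml | clinical sufficiency threshold; the boundary value counts as sufficient |
| GWAS significance | 1e-5 | p-value | strict `p < α` |

Score ties (likely when many nodes share the floor weight) break by
shorter path first, then lexicographic node tuple — an arbitrary but
total, deterministic order, so reruns are byte-identical.

## Locus statistics

* `filter_significant`: strict `p < α` on an association table.
* `overlap_counts`: SNP positions are 1-based, interval tracks 0-based
  half-open; a SNP at position p overlaps [start, end) iff
  `start ≤ p−1 < end`. Counts are order-invariant and additive under
  splitting a region into abutting half-open pieces.
* `ld_blocks`: single-linkage clustering — two SNPs share a block iff
  chained by pairs with r² ≥ threshold. Verified against brute-force
  transitive closure.
* `interaction_logistic`: Newton–Raphson IRLS on the logistic
  log-likelihood for `outcome ~ IKZF1 + IKZF3 + vitD + IKZF1:IKZF3 +
  IKZF3:vitD + covariates`, with vitamin D binarized upstream.
  Convergence: max |score| < 1e-8 or relative log-likelihood change
  < 1e-10, at most 100 iterations. Standard errors come from the inverse
  observed information; p-values are two-sided Wald (matching single-fit
  reporting, not likelihood-ratio tests). Rank-deficient designs raise
  listing aliased columns; separation is detected from runaway
  coefficients / vanishing IRLS weights and raises naming the predictor.
  The test suite cross-checks coefficients against an independent direct
  likelihood maximization (BFGS) to 1e-6.

## The synthetic-data generator

The generator produces every input the pipeline consumes, with the
statistical structure the analysis assumes; its defaults are the study
conditions used throughout the tests (300-node network, attachment
parameter 3, 10 receptors, 10 TFs, three planted 4-node chains, 2-fold
activation, NB mean 100, dispersion 0.1, six samples per condition,
1.5× batch effect).

* **Network**: growing preferential attachment — each joining node forms
  `edge_attach` edges with existing nodes chosen proportionally to
  degree + 1, giving the hub-skewed degree distribution of curated
  interactomes. Each edge's direction is drawn uniformly at random:
  consensus-oriented interactions carry signal both into and out of hubs,
  and a strictly one-way (new→old) orientation would make the network
  acyclic and starve receptor→TF reachability, leaving candidate path
  pools of a dozen paths instead of hundreds. Receptors are guaranteed
  out-degree ≥ 1 and TFs in-degree ≥ 1.
* **Planted chains**: receptor–TF pairs are chosen at BFS distance
  ≥ `planted_len − 1` *before* planting, so the injected chain is a
  genuine shortest path and can be enumerated; interiors are node-disjoint
  across chains where the pool allows. Chains planted later can in rare
  cases create a shortcut for an earlier pair; this is logged, not
  repaired.
* **Counts**: gamma–Poisson (negative binomial) with variance
  μ + αμ², dispersion shared across genes. Planted nodes have mean
  `base_mean × fold_change` in the active condition only. The second half
  of each condition's samples gets all means multiplied by
  `batch_effect` and batch label "B" — batch is balanced against
  condition by construction, so it is removable.
* **Locus fixture**: SNP p-values are a mixture with a chosen count
  strictly below 1e-5; binding-site intervals tile a contiguous run of
  SNP positions so the overlap count is exact by construction; the r²
  matrix has within-block entries in [0.9, 1] and between-block entries
  in [0, 0.2]; phenotypes are Bernoulli draws from the logistic model at
  user-chosen coefficients.
* **Seeding**: all randomness flows from one root seed through named
  `SeedSequence` substreams (`ppi`, `plant`, `expression`, `locus`,
  `receptors`), so adding a generator never perturbs the draws of
  another, and every output is byte-identical for a fixed seed.

What the generator does **not** emulate — and hence what passing tests do
not show about real data: the true degree distribution and motif content
of curated interactomes beyond hub skew; gene-specific dispersions and
GC/length biases of real RNA-seq; LD decay with genomic distance (blocks
are idealized step functions); correlated expression between interacting
proteins; any sequence-level structure.

## Problem sizes

The default test and acceptance runs use 300-node networks with 10×10
receptor–TF pairs over 10 seeds, 200 random ≤12-node graphs for the
exhaustive path-enumeration oracle, 100 random ≤30-SNP matrices for the
LD oracle, and 100–200 logistic replicates at n = 2000 subjects. These
sizes give stable Monte-Carlo estimates (binomial SE below ~2 percentage
points for the coverage checks) while keeping a full run in seconds.

## Known limitations

* No statistical significance is attached to a path or to a
  condition-specific edge; the ranking is descriptive.
* The VST stand-in is not a variance-stabilizing transform in the strict
  sense at very low counts; with the default filter (all samples ≥ 5)
  this regime is excluded.
* `top_k` materially shapes the condition-specific edge sets; there is no
  internal criterion for choosing it.
* The truncation cap makes enumeration deterministic but biased toward
  lexicographically early paths when a pair exceeds the cap.
* Wald inference is first-order; near-separation data will show the usual
  Wald degradation before the separation detector trips.
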