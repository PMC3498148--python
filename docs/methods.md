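# Methods and design notes

## Model and assumptions

The analysis treats the disease interactome as a simple undirected graph
of gene symbols: self-interactions and duplicate pairs are dropped (with
logged counts), edge direction and interaction weights are ignored, and
exact case-sensitive symbol matching joins every input table. The
working hypothesis of the pipeline is that (i) topologically central
genes of a disease interactome implement generic disease mechanisms and
correlate with organismal essentiality, and (ii) the disease-specific
signal lives in genes that share the ontology profile of a curated
disease gene list *without* being central. Both halves are tested
explicitly on synthetic data where the ground truth is planted.

Metrics are computed on the full graph by default; a `giant_only` flag
restricts the analysis to the giant component (which choice is right
depends on whether fragments are biology or data sparsity — the default
keeps all evidence).

## Centrality conventions

- **Stress** counts each geodesic once per unordered endpoint pair. The
  doubled (ordered-pair) convention would scale every value by 2 and
  change no ranking; the unordered form matches common interactome
  tools. Both stress and betweenness come from one Brandes-style
  single-source accumulation (one BFS plus one reverse sweep per
  source), so the full metric table on a 2000-node, 8000-edge graph
  takes a few seconds in pure Python.
- **Betweenness** uses the standard Freeman/Brandes pair-ratio sum,
  normalized by (N−1)(N−2)/2 with N the size of the node's connected
  component. Pairs in different components contribute nothing.
- **Undefined values are explicit**: neighborhood connectivity of an
  isolated node, clustering coefficient at degree < 2 and average path
  length of an isolated node are NaN in memory and `NA` on disk, and
  genes with an undefined value are excluded from that metric's ranking.
  The topological coefficient is defined as 0 at degree ≤ 1 (tool
  convention), not NaN.
- All iteration is in lexicographic gene order and every ranking breaks
  ties lexicographically, so outputs are bit-stable.

## Power-law fitting

The fit follows the maximum-likelihood + Kolmogorov–Smirnov recipe:
candidate cutoffs are every distinct observed value; for each, the
exponent is estimated on the tail (discrete: numerical maximization of
the Hurwitz-zeta likelihood, used for degree; continuous: the closed
form α̂ = 1 + n/Σln(x_i/xmin), used for large-valued metrics such as
stress) and the cutoff minimizing the KS distance wins, ties toward the
smaller cutoff. Fits require ≥ 50 values (configurable) and ≥ 2 distinct
tail values. The asymptotic standard error (α−1)/√n_tail is exposed;
simulation tests require recovery within ±0.15 at n = 5000 for exponents
2.13–2.85. Exponents are reported with the negative plotting sign.

## Enrichment conventions

- **N counts every universe gene**, annotated or not. This keeps the
  background independent of annotation coverage and matches the
  two-unranked-lists design (target list against a fixed source
  universe). B is counted in the universe after true-path propagation
  over is_a and part_of.
- The filter is on the **raw p-value** (default p ≤ 0.001) plus the
  term-size cap B ≤ 100 that suppresses overly generic terms. A
  Benjamini–Hochberg column (computed per namespace) is emitted for
  information only and never filters, because the threshold-sensitivity
  behavior of the method is defined on raw p.
- The hypergeometric tail is evaluated through `scipy.stats.hypergeom`
  (log-space gammas); the test suite pins it to exhaustive
  draw-enumeration for every parameter combination with N ≤ 12 at 1e-12
  relative tolerance.

## Target refinement

Category matching ("annotated with a bone-relevant term") is evaluated
on propagated annotations, so descendants of a listed term count; a
`--direct-only` flag disables this for strict direct-annotation runs.
The packaged default categories are 10 bone-process and 19
metastasis-mechanism GO IDs; users supply their own via a two-column
TSV. Set-b (curated genes outside both the hub and enriched sets) is
never part of the candidate pool — those genes are already known — and
generic-gene removal is exact symbol matching against the supplied list,
with no pathway expansion. Refinement is monotone by construction:
growing the generic list can only shrink the target set, growing the
category lists can only grow it.

## Synthetic data: what it emulates, and what it does not

The generator's defaults are scaled from the real study's magnitudes:
a 2000-gene universe (≈ 2665), 300 curated genes (≈ 391), 250 generic
genes (≈ 328), degree-exponent target 2.85, essential fraction 0.4934,
and 10 + 21 planted bone-like/metastasis-like terms. Specifics:

- **Interactome**: preferential attachment, m = 4 edges per new gene
  (mean degree ≈ 8, near the real network's ≈ 8.7). The asymptotic
  exponent of linear preferential attachment is 3; the fitted exponent
  at n = 2000 is required only to land within ±0.4 of the 2.85 target.
  A configuration-model generator would hit the exponent exactly but
  produce multi-edges needing erasure; simplicity won.
- **Essentiality**: P(essential | degree-rank quantile q) =
  sigmoid(b0 + s·q) with slope s = 4.5 and b0 solved by root-finding so
  the expected overall fraction equals the configured 0.4934. This
  yields ≈ 88–90% essential hubs at Top75 against a ≈ 49–51% universe,
  the regime the method assumes. s = 0 removes the coupling (null
  bundles).
- **Generic list**: sampled without replacement with weight
  (degree+1)², giving hub overlap of ≈ 75–85% against a ≈ 12% random
  expectation. Bias 0 gives null behavior.
- **Planted enrichment**: curated genes draw each planted term at
  8 × the 0.02 base rate, so every planted term passes the p ≤ 0.001,
  B ≤ 100 filters with a 300-gene target, while two deliberately common
  baseline terms per namespace exceed B and exercise the size filter.
  Effect size 1 is the null: planted terms then pass only at the
  nominal false-positive rate.
- **Planted targets**: 25 genes below degree rank 300, outside the
  generic list, half inside the curated list, each forced to carry ≥ 1
  bone-like and ≥ 1 metastasis-like term.
- **Identifiability device**: every *other* gene draws planted terms
  from a single allowed category (bone or metastasis, assigned 50/50),
  so dual annotation marks exactly the planted targets. Real annotation
  data has no such exclusivity — genuinely dual-annotated non-target
  genes exist and would be predicted. Passing the recovery tests
  therefore shows the set logic and plumbing are correct, not that the
  biological prediction is precise on real data.

All randomness flows from one mandatory seed through named
`SeedSequence` spawns; serialization is sorted, so bundles and reports
are byte-reproducible. Gene symbols are synthetic (`G000001`…) to avoid
implying claims about real genes.

## Statistical comparisons against random controls

Random controls report both the control-distribution standard deviation
and the standard error of the control mean. Claims of the form "the hubs
exceed random expectation" or "non-hubs are consistent with random
draws" are made against **3 × the control distribution's sd** — the
spread of the statistic under random sampling — not the SE of the mean,
which shrinks without bound as control samples are added and would
reject any fixed observation. Note that the complement of a strongly
essential hub set is *structurally* a little below the universe
fraction (removing a 90%-essential 83-gene set from a 51%-essential
2000-gene universe leaves 49.3%), which is well inside the 3σ band but
outside any SE-of-mean band.

## Problem sizes in the test suite

Oracle-equivalence tests run exhaustive geodesic enumeration on 200
random graphs of ≤ 25 nodes and full hypergeometric enumeration at
N ≤ 12; estimator tests use 5000 draws; pipeline-level tests use the
default 2000-gene bundle (five seeds for the recovery average, 1000
random-control samples in the shared run, 100 in the per-seed runs).
These sizes keep the whole suite under a minute while leaving every
statistical check comfortably powered.

## Known limitations

- No identifier mapping: inputs must share one symbol namespace.
- No multiple-testing-corrected filtering mode; the BH column is
  informational.
- The stress/betweenness kernel is O(n·m) in pure Python — fine to
  ~10⁴ nodes, not sized for proteome-scale graphs.
- Orthology (for essentiality) is consumed as a precomputed gene→MP
  table, never inferred.
- The discrete power-law sampler tabulates the zeta CDF; for exponents
  very close to 1 the support table becomes large.
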