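# Methods

This note documents the models and procedures implemented in
`clustval`, the defaults and why they were chosen, and what the
synthetic benchmark does and does not establish about real data.

## Graphs, partitions and aggregates

A `WeightedGraph` is undirected and simple, with strictly positive edge
weights — weight 0 and "no edge" are the same thing, and the 0/1
adjacency indicator is always binary even for weighted graphs.
Negative weights are rejected (the methods here assume 0 is a global
lower bound), as are self-loops.  Graphs may carry an optional *upper
bound* on weights — the natural cap of the data, e.g. 1 for graphs
built from correlations — which several procedures consult (the
clustering-coefficient integral limit, switching-transfer caps,
bootstrap duplicate edges, noise truncation).  Vertices are identified
by string names mapped to dense 0-based ids; duplicate edge lines in an
input file are summed, which is the natural conversion of an interaction
log into a weighted graph.

All scoring functions consume a single-pass `ClusterAggregates`
cross-tabulation (internal/boundary weight and edge counts per cluster,
total and within-cluster degrees/strengths per vertex), so scoring a
partition is O(m).  Median degrees are exposed alongside, although no
shipped scoring function consumes them.

## Scoring functions

The weighted definitions reduce exactly to the classical unweighted
ones on 0/1 graphs (property-tested).  Two conventions needed fixing
where degenerate inputs make textbook formulas ill-defined:

* ratio terms with numerator and denominator both 0 (e.g. the second
  normalized-cut term when S is the whole graph) are taken as 0;
  a positive boundary over a zero denominator is NaN ("undefined"), as
  is internal density of a singleton and conductance of a cluster with
  no incident weight.  Partition-level aggregation is the unweighted
  mean over clusters with defined values, with the NaN count reported
  alongside; the aggregation lives in one function
  (`score_partition`) so a size-weighted alternative is a one-line
  change.
* out-degree fractions of isolated vertices (zero strength) count as 0.

The weighted clustering coefficient is the threshold integral
`C̃ = (1/w̄) ∫₀^w̄ C_t dt`.  The integral is evaluated exactly as a sum
over the sorted critical thresholds: a triplet centred at `i` with legs
`w_ij, w_ik` survives up to `t = min(w_ij, w_ik)` and is closed up to
the minimum of all three weights, so `Γ(t)` and `γ(t)` are
right-continuous step functions and `C_t` is constant on the intervals
between consecutive critical values.  Segments where `Γ(t) = 0`
contribute 0, which keeps `C̃` in [0, 1].  `w̄` is the graph's upper
bound when set, else the maximum edge weight.  Enumeration is
O(m + Γ log Γ).  The integral starts at `t = 0⁺`: zero-weight pairs are
never edges.  Barrat's local coefficient is included purely as a
comparison baseline (it is identically 1 on complete weighted graphs).

Modularity is computed in its per-cluster form
`Q = Σ_S [m̃_S/m̃ − (K_S/2m̃)²]`, algebraically identical to the
double-sum definition; a unit test cross-checks against igraph's
independent implementation.

## Switching null model

Each proposal draws two distinct edges uniformly from the current
positive-weight edge set, randomizes each edge's endpoint orientation
with a fair coin, and accepts only quads with four distinct vertices
and `w_AC > w_AD`, `w_BD > w_BC`.  The strict inequality is applied to
both transfer rules — it guarantees a strictly positive transfer and is
what makes the binary case coincide with the classic switching
algorithm (no multi-edges can arise).  Choices the literature leaves
open, fixed here:

* **Budget.** A run performs `ceil(T·m)` *proposals* (m = initial edge
  count); rejected and discarded proposals count.  This makes runtime
  predictable and matches the observed mixing plateau at T ≈ 1 in units
  of proposals per edge.  Default T = 100, far past the plateau.
* **Variance convention.** The "constant variance" rule preserves the
  sample variance of the weight multiset over *all* vertex pairs
  (absent pairs count as weight 0); only the four touched weights enter
  the balance, so the choice of denominator is immaterial to the rule
  itself.  `weight_variance` uses the all-pairs convention and
  constant-variance runs preserve it to ~1e−15 per step (discarded
  out-of-bounds steps change nothing).
* **Method selection.** `constant_variance` is the default above edge
  density 0.5, `max_weight` below — the former keeps dense
  (correlation-like) graphs dense; the latter deletes at least one edge
  per accepted step and keeps sparse graphs sparse.
* Edges reaching weight ≤ 1e−12 are deleted (exact zeros occur by
  construction in `max_weight`; the tolerance only mops up float dust
  in `constant_variance`).

Weighted degrees and total weight are conserved up to floating-point
summation order (asserted at 1e−9 in tests; exact in the binary case).

## WSBM benchmark generator

`n_steps` rounds the expected total weight half-up.  The sum runs over
unordered *distinct* vertex pairs — `Σ_i C(|C_i|,2) E_ii +
Σ_{i<j} |C_i||C_j| E_ij` — because that is the only convention under
which the per-step pair probabilities `E_{b(u)b(v)}/n_steps` sum to 1.
The alternative count that includes diagonal self-pairs
(`½ Σ_ij |C_i||C_j| E_ij`) is available behind
`include_self_pairs=True`; on the built-in benchmark it adds ~1–3% more
steps and does not change any qualitative result (the λ-recovery
threshold is identical under both conventions).

Sampling draws all `n_steps` unit edges at once from a single
multinomial over pairs, which is distributionally identical to
sequential draws and makes a fixed seed bit-reproducible.  Consequences
worth knowing: the total weight is *exactly* `n_steps` for every
sample; individual weights are binomial but negatively correlated
(they share the fixed total).

The built-in benchmark (sizes 40/25/25/10, diagonal scaled by λ) is
nearly uniform at λ = 1 and plants communities that modularity-based
algorithms recover exactly for λ in the low 30s.  At λ = 25 roughly
10% of samples contain an ambiguous vertex whose realized weight to a
foreign block exceeds its weight to its own block — for some of those
samples the planted partition is not even the modularity optimum — so
demanding ARI = 1 in ≥ 95% of 20 samples is met from λ = 31 in the
default sweep.  This is a property of the generator's noise at that
strength, not of any particular optimizer.

## Partition similarity

Natural logarithms everywhere; entropies, MI, VI and RMI are in nats,
which keeps `(1/n) log Ω` commensurate with the entropy terms.  The
Rand index is reported normalized to [0, 1] (agreements over `C(n,2)`
pairs).  VI values at equality are clipped at 0 (float dust of order
1e−16).

### Counting contingency tables

`Ω(a, b)` — the number of nonnegative integer matrices with row sums a
and column sums b — is computed three ways:

* **exact** — column-by-column recursion memoized on the multiset of
  remaining row sums, with a work cap (default 2·10⁶ visited
  compositions) so infeasible inputs fail fast into the estimates.
* **analytic** — margins ≤ 3 are peeled off exactly (a small margin
  contributes a short finite sum over its placements; 2×2 cores use the
  closed form `min(a₁,b₁) − max(0, a₁+b₁−n) + 1`); the remaining core
  is estimated by a maximum-entropy saddle point: table entries are
  modelled as independent geometric variables tilted so the expected
  margins match, and the probability of hitting the margins exactly is
  evaluated by a multivariate local CLT with the third/fourth-cumulant
  Edgeworth correction at the centre.  On random tables with n ≤ 40
  and up to 4×4 margins this is within 2% of the exact log-count
  (worst observed 1.7%, median 0.3%); accuracy improves as margins grow
  and degrades only when the cluster count approaches n — the regime
  the hybrid method exists for.
* **hybrid Monte Carlo** — for margins with many ones (e.g. partitions
  with many singleton clusters).  Taking the unit margins as rows,
  every table splits into a placement of the unit rows into columns
  plus a core table with reduced column margins, so
  `Ω = S^k · E[Ω_core(b − counts)]` over uniform placements; the
  expectation is estimated from 10⁴ seeded samples (inner counts exact
  when cheap, else analytic, memoized), giving an unbiased estimator
  with a reported standard error on the log scale.

`auto` tries exact (only for n ≤ 40 and small margin grids, with a
reduced work cap so the attempt never dominates runtime), then the
hybrid when ≥ 5 and ≥ 25% of one side's margins are ones, else the
analytic estimate.

NRMI divides RMI by the mean of the two self-RMIs; it is 1 for
identical partitions, ~0 for unrelated ones, and NaN when both
partitions are the single trivial cluster.  The all-singletons-vs-
one-cluster pair scores 0 — the pathology that makes plain NMI
unusable for detecting degenerate clusterings.

## Significance

Per algorithm: one clustering of the original graph, then one
clustering of each of `n_null` (default 100, percentile resolution
0.01) independently re-randomized graphs, each scored.  The percentile
rank uses mid-rank ties, so a null identical to the original yields 0.5
everywhere and relative scores of exactly 1 (tested with T = 0).
Null means are taken over defined (non-NaN) null scores with the NaN
count reported.  Degenerate partitions (one cluster, or all
singletons) are scored but flagged: external-connectivity scores are
trivially optimal for them and should be disregarded.

## Stability

Defaults: R = 999 replicates; noise sd = 0.1 × the empirical standard
deviation of the original edge weights (the data's own scale is the
only meaningful reference; a single exposed knob); duplicate policy
`upper_bound` for bounded graphs and `top_quantile` (top 5% of the
original weights) otherwise.  Three or more copies of a vertex form a
clique of heavy edges — cohesion among copies is the point of the
device.  Truncated-normal noise keeps weights within [0, ub] (or
[0, ∞)).  Each replicate partition is compared against the original
partition *pulled back* through the resampling map (a copy inherits its
source's original label) — the only well-defined vertex correspondence
under resampling.  Degenerate replicates are included in the
distributions but flagged; failed algorithm runs are recorded as
missing, never as zeros.

## Problem sizes used in the shipped checks

The test suite and the acceptance script run the benchmark at the
sizes the methods are specified at: 20 samples per λ for the recovery
sweep, 10 seeds for the mixing-plateau diagnostic (T ∈ {1, 100}),
20 fixtures for the switching conservation suite, 200 samples for the
WSBM moment check, and R = 100 replicates for the bootstrap
comparison; the full default of R = 999 is a command-line flag away.

## Known limitations

* Directed and signed graphs are out of scope; multigraphs are
  collapsed by summation on input.
* The switching model preserves each vertex's weighted degree but not
  joint degree–degree correlations.
* The WSBM benchmark plants sharp, assortative blocks with independent
  pair draws; it does not emulate heavy-tailed weight distributions,
  degree heterogeneity within blocks, overlapping communities, or the
  metric structure of correlation matrices (a sampled "correlation"
  graph need not be positive semidefinite).  Passing the benchmark
  checks therefore demonstrates the machinery's correctness and
  calibration under a known null/alternative — not that any particular
  real network has significant clusters.
* The analytic Ω estimate assumes the cluster counts are well below n;
  outside that regime `auto` falls back to the hybrid estimator, whose
  error is statistical and reported.
* Spin-glass requires a connected graph; its adapter raises
  `AlgorithmNotApplicable` rather than guessing.
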