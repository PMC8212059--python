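# Methods

## Data model

The observed data is an N×M matrix of per-cell mutation calls, cells in
rows.  In binary mode calls are {0,1}; in ternary mode {0,1,2}, where 2
records a heterozygous mutation mis-called homozygous through allele
dropout.  The hidden genotype is binary in both modes.  Emission
probabilities are

| hidden | p(0) | p(1) | p(2) (ternary) |
|---|---|---|---|
| 0 | 1−α (binary) / 1−α−αβ/2 | α | αβ/2 |
| 1 | β (binary) / β/2 | 1−β | β/2 |

with false-positive rate α and false-negative rate β; each row sums to 1.
Missing observations contribute a factor of 1 to every likelihood (they are
skipped), the only convention under which an all-missing cell is equally
compatible with every node of every tree.

## Tree representation

A mutation tree over M mutations with at most k losses per mutation has
ζ = (k+1)M+1 labelled event nodes stored as a parent vector: node 0 is the
root, nodes 1..M the gain events, the rest k interchangeable loss copies
per mutation.  −1 marks an unattached node; the root carries its own
sentinel.  A loss of mutation *a* may only hang below a node whose genotype
still carries *a*.  The restriction is per root-path, so with k ≥ 2 two
loss copies of one mutation may sit on different branches.  The
interchangeable loss copies are deduplicated during search: only the
lowest-id free copy is ever offered as a candidate, which removes an
exactly symmetric part of the search space.

Genotypes are derived incrementally — a child's profile is its parent's
with one bit set (gain) or cleared (loss) — and cached for every attached
node; a unit test asserts the incremental profile equals a full path walk.

## Generative tree search

Starting from the root-only tree, each iteration scores every legal
(split point p, free node c) pair and attaches the argmax.  With W[i,p]
the current posterior attachment probability of cell i at node p (uniform
prior over attached nodes) and R[i] the single-site likelihood ratio of
c's event applied to p's genotype, the expected direct flow π̄ (cells
moving from p to c) and indirect flow π̃ (cells arriving at c from other
nodes) reduce to

    u = W[i,p]·R[i];   π_c = Σ_i u/(1+u);   π̄ = Σ_i W[i,p]·u/(1+u);
    π̃ = π_c − π̄;      s = λ·π̄ + (1−λ)·π̃

so scoring one candidate touches only the new node's per-cell likelihood
ratio — the property that makes the builder O(t·(ζ−t)·N) per iteration
instead of quadratic in the tree.  Both flows are provably non-negative in
this form; the public per-candidate scorer still clips at −10⁻⁹ for
defensive hygiene.  The batch kernel (numba) and the pure-numpy
per-candidate scorer are checked against each other and against a
no-caching recomputation of the posterior-flow definitions to 10⁻⁹.

Tie-breaking in the argmax, unspecified in the original formulation, is
(1) larger resulting data log-likelihood, then (2) smallest (p,c)
lexicographically — deterministic, and likelihood-aware where it matters.
The stop test `s < κ` (strict) is evaluated *before* the global-best
update, matching the published loop order; when it fires, the globally
best tree by data log-likelihood — not the last tree — is returned.  After
each accepted edge the full posterior cache (log-normalizers, W, π) is
refreshed from the exact per-node log-likelihood columns rather than
updated incrementally, trading a small O(N·t) cost per iteration for
numerical hygiene.

Defaults λ = 0.7, κ = 1.  κ in units of expected cells: growth stops when
no candidate edge would capture one cell's worth of posterior flow.  A
consequence of the published loop order is that a low-score step can hide
a later likelihood-improving step; this is intentional and reproduced
as-is.

## Error-rate estimation

f(α,β) = best-tree log-likelihood, maximized by Bayesian optimization:
a Latin-hypercube design of n_init = 50 points, then n_iter = 15
expected-improvement acquisitions under a Gaussian-process surrogate
(Matérn 5/2, per-dimension lengthscales, objective standardized, jitter
10⁻⁸ escalating ×10 on factorization failure, hyperparameters refit by
marginal likelihood every 5 evaluations).  The GP operates on the search
box α ∈ [10⁻⁴, 0.1], β ∈ [10⁻⁴, 0.5] — wide enough for reported real-data
estimates (β up to ~34%) — linearly rescaled to the unit square.  Linear,
not logit, scaling is deliberate: under a logit rescaling most of the
square maps to vanishing rates, and the acquisition spends its budget
exploring that empty region instead of refining the likelihood basin
(observed directly in failing runs).  The design and the EI candidate pool
are likewise uniform over the rate box, the pool augmented with a Gaussian
cloud around the incumbent; EI is maximized over the pool plus one
L-BFGS-B refinement from its best point.  The returned estimate is the
best *evaluated* point, not the GP posterior maximizer.

The objective is a profile likelihood through a greedy, adaptively-sized
tree, so β̂ is biased low when per-node cell support is thin (the tree
absorbs part of the dropout signal as structure).  How far this degrades
the estimate depends strongly on cells-per-node: with a few cells behind
every node the bias is a modest, monotone compression and estimated rates
track the truth closely (Pearson r ≈ 0.87 across replicates at N = 200,
M = 50 on this simulator); at one cell per node the profile top becomes
rugged and nearly flat over a wide β range, its argmax decouples from the
generating rate, and correlations fall to ≈ 0.4–0.6.  This is a property
of the objective under sparse support, not of the optimizer — the search
demonstrably reaches the profile optimum (checked against grid scans).

## Simulator

One replicate = ground-truth tree → uniform cell attachment → noise.
Defaults: N = 200 cells, M = 200 mutations, α = 0.01, β = 0.2, missing
rate η = 0.1, doublet rate ρ = 0.1, k = 0.

* **Tree shape.** Gains attach in random order; with probability γ the
  parent is uniform over all attached nodes, otherwise the most recently
  attached node is extended.  γ = 0 gives a chain, γ = 1 (default) a
  random recursive tree.  When k > 0 each mutation receives one loss event
  with probability `loss_prob` (default 0.5), placed uniformly among nodes
  still carrying it.  This mechanism and its default are this package's
  own construction: the procedure used to produce the reference benchmark
  trees is not public, and *tree-shape-sensitive quantities (CASet/DISC
  distances, error-rate identifiability) measured on this simulator are
  not comparable in absolute terms to results obtained under a different
  tree generator.*  At N = M = 200 a γ = 1 tree gives roughly one cell per
  node, which makes adjacent event order frequently unidentifiable;
  genotype-level quantities (imputation accuracy, genotype error rate) are
  insensitive to this and do transfer.
* **Doublets.** With probability ρ a cell's profile is OR-merged with the
  profile of a uniformly drawn node before errors are applied — the
  standard two-transcriptome doublet model.  Doublet rows are excluded
  from all evaluation metrics but remain in the inference input.
* **Noise order** is doublet → genotype error → missing: missing entries
  are a sequencing artifact layered on the (already noisy) signal.
* Not emulated: read-level signal (coverage, VAFs), copy-number segments,
  per-site or per-cell error-rate heterogeneity, doublet-specific missing
  patterns.  Passing benchmarks on this simulator therefore demonstrates
  correctness of the estimator under its own model assumptions, not
  robustness to those real-data effects.

## Evaluation metrics

Imputation accuracy = % of originally-missing entries whose predicted
genotype (profile of the cell's maximum-likelihood node) matches the
truth; genotype error rate = fraction of all entries wrong; both exclude
doublet rows and raise on an empty evaluation set rather than returning a
vacuous number.

For tree distances, both trees are first reduced by *linear-chain
aggregation*: while a node has exactly one child and no attached cells
(hard ML attachments for the inferred tree, generating attachments for the
truth), it merges with its child, pooling mutation labels — the relative
order of those mutations is unidentifiable from the data.  The rule is
confluent, so merge order is irrelevant, and idempotent at its fixpoint.
CASet∩ averages Jaccard distances between the two trees'
common-ancestor-set intersections over unordered mutation pairs; DISC∩
does the same for ancestor-set differences over ordered pairs; both
restrict the mutation universe to mutations present in both trees,
define the Jaccard distance of two empty sets as 0, and include a
mutation in its own ancestor set.  With k ≥ 1 the universe is gain events
only — the distances compare acquisition chronology; loss nodes
participate in aggregation but carry no labels.  Both distances are
computed exactly via boolean matrix products and are validated against a
direct set-by-set reference implementation.

## Problem sizes in the benchmark script

`scripts/acceptance.py` uses 50 replicates for the single-factor sweeps
(matching the reference protocol), 15 replicates at M = 1000, and 20
replicates for the error-rate recovery sweep (reduced from 100); the test
suite uses 10–20 replicates per scenario.  Medians of the reported metrics
are stable well below these counts at the default matrix sizes.

## Known limitations

* Greedy growth cannot revisit an edge; once a weakly-supported order is
  chosen it persists.  Expected errors are adjacent inversions at nodes
  with ~1 attached cell.
* κ-stopping leaves mutations with less than one expected cell of flow
  unplaced; they are simply absent from the inferred tree (and from the
  ∩-restricted distance universe).
* Doublets are not modelled in the likelihood; high ρ degrades placement.
* β̂ from the profile likelihood is biased toward 0 under thin cell
  support (see above); treat absolute estimates with care when N/M is
  small.
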