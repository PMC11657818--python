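# Methods

## The model space

A species delimitation model over a sample of `n` lineages (or
populations) is a set partition ψ of the lineage labels: `K` non-empty,
pairwise-disjoint blocks whose union is the whole label set, each block
one species unit. `delimetrics` treats two models as identical exactly
when their canonical block structures coincide; labels and support values
are metadata. The canonical form sorts labels within a block
lexicographically and orders blocks by descending size, ties broken by
the smallest member — a purely cosmetic convention that makes every
output table deterministic.

Element labels are opaque strings compared by exact equality; no case or
whitespace normalization is applied, because labels are identifiers from
heterogeneous inference pipelines and any silent coercion risks merging
distinct lineages. Partitions over different label sets are
*incomparable* and raise an error rather than auto-restricting to the
shared subset: no partition metric is defined across unequal domains, and
the correct cross-dataset object of comparison is the *distances*, which
the n-invariance of VI (below) makes commensurable.

## The statistics

With block probabilities `p(k) = n_k / n` (block size over total size):

* **Entropy** `H(ψ) = −Σ_k p(k) log p(k)` — the uncertainty of a random
  lineage's species assignment; 0 for the one-species model, `log n` for
  all-singletons.
* **Mutual information**
  `I(ψᵘ, ψᵛ) = Σ_ij p(k_i,k_j) log [p(k_i,k_j)/(p(k_i)p(k_j))]`, with the
  joint probability `p(k_i,k_j)` the proportional size of the block
  intersection (the contingency table over n).
* **Joint entropy** `H(ψᵘ, ψᵛ) = H(ψᵘ) + H(ψᵛ) − I`; equivalently the
  entropy of the meet (common refinement) of the two partitions.
* **Variation of information** `VI = H(ψᵘ) + H(ψᵛ) − 2I` — a true metric:
  non-negative, symmetric, zero iff equal, triangle inequality.
* **Normalized VI** `NVI = VI / H(ψᵘ, ψᵛ) ∈ [0, 1]` (see below).
* **Match ratio** `MR = 2m / (K_u + K_v)`, `m` the number of blocks
  identical as sets — the conventional similarity index, kept as a foil:
  it is not a metric and collapses to 0 under any exact-match failure.

All logarithms default to base 2, so every quantity is in bits; the
worked values on the 4-element set (VI between the one-block model and
two equal halves = 1 bit, etc.) are only consistent with base 2, and all
tests pin it. A `base` argument exists on every function for users who
prefer nats.

Numerical conventions: `0·log 0 := 0` by continuity, zero contingency
cells are skipped, and mutual information is clipped at 0 to absorb the
~1e-16 signed-sum round-off. `VI(u, u)` and `I(u, u) = H(u)` are returned
as exact identities when the canonical forms are equal, because the two
independent float paths for H and I can otherwise disagree by ~2e-16 and
a "zero distance" must be exactly zero for downstream histogramming.
Internal identities are asserted to 1e-9 absolute; the worked examples to
1e-6.

## Why VI

Three properties make VI the right geometry for delimitation models:

1. **Lattice alignment.** Partitions of a fixed set form a lattice under
   refinement (U ⊑ V when every block of U sits inside a block of V);
   Hasse edges are single lump/split moves. A model's VI-nearest
   neighbors are always one cover edge away, and VI adds exactly along
   refinement chains, so distances decompose into interpretable
   lump/split costs (the 1 + ½ + ½ = 2 chain from the single-species
   model to all-singletons at n = 4 is the canonical instance).
2. **Convex additivity.** For models over a disjoint union of two sample
   sets, VI is the size-weighted mix of the per-set VIs — results from
   independent subclades combine linearly.
3. **n-invariance.** VI depends only on block proportions: replicating
   every lineage m times changes nothing, so distances are comparable
   across datasets of different sizes.

Upper bounds: `VI ≤ 2 log K_max` when the number of species is capped,
`VI ≤ log n` when any partition is possible; `vi_upper_bound` returns the
tighter when both apply. For the pairwise bound check the package uses
the maximum K of the pair; a global cap over a model set is expressible
by passing that K instead.

## Normalization choice

Several [0, 1] rescalings of VI circulate. The package's default divides
by the joint entropy, `NVI = VI / H(u, v) = 1 − I / H(u, v)`, which
remains a metric and keeps distances comparable across datasets. The
bound-based alternatives — dividing by `2 log K` or by `log n` — are
exposed as named variants (`two-log-k`, `log-n`) because they are in
common use, but they tie the scale to the dataset (breaking cross-study
comparison) and destroy convex additivity, so they are never the default.
The degenerate case of two single-block partitions (VI = joint entropy =
0) is defined as NVI = 0, the metric's identity value.

## Lattice computations

Enumeration uses restricted-growth strings (duplicate-free, O(B(n))),
with a hard cap at n = 12 (B(12) ≈ 4.2 million) and an explicit override
flag; pairwise work beyond that is not desk-scale. Cover edges are found
as refinement pairs whose block counts differ by one — for the partition
lattice this is exactly the transitive reduction, which the test suite
cross-checks against an independent brute-force reduction of the full
refinement relation for n ≤ 5. Nearest-neighbor queries return all ties,
since symmetric partitions produce exact ties and a single arbitrary
winner would misrepresent the neighborhood.

## Synthetic model sets

The generator module makes every test and example self-contained:

* **uniform** — exact uniform draws over all B(n) partitions via the
  first-element block-size recursion on Bell numbers (the block
  containing the first remaining element has size k with probability
  `C(n−1, k−1)·B(n−k)/B(n)`). Integer weights are converted to float
  probabilities; the chi-square check at n = 4 (15,000 draws against the
  exact 1/15 target) bounds any conversion error far below detectability.
* **crp** — a Chinese restaurant process with concentration α (default
  1.5): the standard exchangeable partition prior, giving lumped models
  for small α and finely split ones for large α.
* **perturbation** — a uniform anchor plus a configurable number of
  random lattice cover moves (lump or split, type drawn uniformly,
  blocked moves falling back to the feasible type), emulating a posterior
  sample concentrated around one delimitation.

Support models emulate ranked inference output: `dirichlet` draws a
probability vector summing to 1, `geometric` a fixed ratio-½ profile;
both are sorted descending as a "most probable models" list would be.
One root seed drives named substreams (partition draws, supports) so the
addition of a new artifact never shifts existing fixtures. Defaults
(12 elements, 20 models, Dirichlet supports) are sized for a readable
figure, not for any real dataset.

What the generators do *not* emulate: correlation between a model's
support and its position in partition space (real posteriors concentrate;
the uniform and CRP sets do not), lineage labels with phylogenetic
structure, and inference noise. Passing tests therefore demonstrate the
correctness of the metric machinery on arbitrary partitions, not that any
particular empirical pattern (e.g. "high-support models are mutually
close") must appear in real data.

## Visualization

The support-vs-distance scatter places each ordered non-self pair of
models at (log₁₀ support₁, log₁₀ support₂), colored by the chosen metric
on a blue→red gradient, over a background regionalized at the
0.25/0.5/0.75 quantiles of the pooled per-model support vector (one value
per model, identical breaks on both axes); each of the 4×4 cells is
shaded by its mean pair distance. The numeric `RegionalizedGrid`
(breaks, cell means with explicit NaN for empty cells, cell counts) is
always returned and can be written as TSV, so the plot is testable
without image comparison. Ordered pairs (the full square minus the
diagonal) are plotted rather than unordered ones mirrored — the two
renderings are visually identical for a symmetric metric, and the full
square keeps the grid construction and counts trivial. Self-pairs are
excluded: their zero distance is uninformative and compresses the color
scale. Zero or missing supports are an error by default, with an opt-in
floor, because silently log-flooring zeros distorts the reading; log base
10 is the convention for probability magnitudes and is configurable.

## Interfaces and scope

The importable API is primary; the `delimetrics` console script
(`compile` → `evaluate` → `visualize`) is a thin wrapper for shell
pipelines, writing data only to declared files and logging to stderr.
Comparison tables render floats with 9 significant digits — enough to
round-trip every metric at the package's tolerances (values of magnitude
~4 reproduce to ~5e-9 absolute). The DELINEATE-style and SPART-XML
readers target the documented, fixture-backed schema subsets described in
`docs/formats.md`, preserving unrecognized fields into metadata for
forward compatibility. Out of scope by design: fuzzy or partial
partitions, weighted elements, Rand-type indices, the taxonomic congruence
index (defined only for nested models), and significance testing of
distances.
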