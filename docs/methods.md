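# Methods

## Model and procedure

The package operates on a rooted phylogenetic tree with non-negative branch
lengths (any distance metric; typically sequence edit distances) whose
leaves represent OTUs, joined to an environment table mapping each leaf to
one or more samples with positive integer abundance counts.

**Weighted UniFrac.** For samples A and B, a single postorder pass tallies
per-branch descendant counts A_i, B_i as integers. The raw distance is
`Σ_i b_i·|A_i/A_T − B_i/B_T|` over every branch (the root has no branch);
the normalized distance divides by `Σ_j d_j·(A_j/A_T + B_j/B_T)` over
leaves j at depth d_j, which is the largest value the numerator can attain,
so normalized values lie in [0, 1]. The root's own length, if present in
the Newick source, is ignored: the tested quantity lives on the rooted
topology below the root, and the root term would be identically zero anyway.

**The compact ↔ expanded transform.** `expand` replaces every leaf whose
total count exceeds 1, or which carries multiple sample labels, by an
interior node with one unit-count child per individual, attached at branch
length exactly 0; `collapse` is its inverse, absorbing every *pre-terminal*
node (an internal node with only leaf children) whose child branches are
all exactly 0 back into a count-annotated leaf, iterated bottom-up to a
fixed point so stacked zero-length levels fully collapse. Because a
distance of 0 means identity (the coincidence axiom), the two forms are
the same object semantically, and the distance code is written so they are
the same object numerically too (see below).

**The significance test.** The p-value is the fraction of random
re-labelings whose between-sample distance is ≥ the observed one — no +1
pseudo-count by default, with the standard `(n_ge+1)/(n_null+1)` correction
available as `plus_one`. Two shuffle semantics are implemented:

* *compact*: each leaf's full `sample:count` bundle moves as one unit;
* *expanded*: the tree is expanded first (a no-op if already expanded) and
  the individual unit labels are shuffled.

Both a Monte-Carlo estimator (`mc_pvalue`, default 100 permutations — the
conventional web-tool default, which is statistically coarse; raise it for
stable estimates) and exact enumeration (`exact_pvalue`) are provided.
Exact enumeration iterates the distinct permutations of the annotation
multiset; every distinct assignment corresponds to the same number of raw
orderings (the product of the multiplicity factorials), so counting each
once preserves the uniform-shuffle semantics. The enumeration refuses to
start above a cap (default 10^6 distinct assignments) and directs the
caller to the Monte-Carlo path.

**Each-pair mode.** `pairwise_significance` tests every unordered sample
pair with only that pair's counts participating; other samples' individuals
are stripped from the environment, while their leaves remain in the
topology as empty annotations. Whether those empty (or other-sample)
annotation slots take part in the shuffle is not standardized anywhere we
could anchor it, so both behaviors exist: `scope="all"` (default) permutes
annotations across every leaf, `scope="occupied"` only across leaves
occupied by the tested pair. P-values are uncorrected by default;
`bonferroni` multiplies by the number of pairs, clipped at 1.

## Numerical choices

* **Bitwise transform invariance.** Branch tallies are accumulated as
  integers, and the normalization denominator aggregates integer leaf
  counts per distinct depth (in first-encounter postorder order) before any
  division. Zero-length branches then contribute exact zeros, and the
  distance on a tree and on its expansion agrees bit for bit — the test
  suite asserts `==`, not approximate equality. Accumulation order is the
  deterministic postorder traversal throughout.
* **Tie handling.** The "≥ observed" comparison uses a relative tolerance
  of 1e-9 on the equality side, so null labelings that are symmetric images
  of the original tie exactly despite floating point; with the fixed
  accumulation order the tolerance only guards cross-platform drift.
* **Exact zero test in `collapse`.** A branch qualifies as zero only if its
  length is exactly 0; an implicit epsilon would silently change which
  trees count as equivalent. `tol` opts into a tolerance explicitly (the
  un-clustered-sequences scenario, where near-zero lengths should *not*
  collapse, is exercised in the tests with lengths of 0.01).
* **Degenerate inputs.** A sample with zero total count is an error; a
  normalization denominator of 0 (every individual of both samples at
  depth 0) raises a degenerate-input error rather than returning 0/0.
* **Vectorized null distributions.** The significance engine precomputes a
  leaf-by-branch incidence matrix restricted to positive-length branches
  (zero-length branches contribute nothing to the numerator), so a batch of
  permutations is one matrix product and memory stays linear in leaf count
  even on a 20,000-leaf expansion.
* **Randomness.** All shuffling flows through `numpy.random.default_rng`
  seeded per run; the seed is recorded in every result object.

## Input formats

Newick parsing is deliberately literal: labels are taken byte-for-byte (no
quoting rules, no underscore-to-space), because leaf-name identity is what
joins the tree to the environment table. A branch without an explicit
`:length` is an error unless a default is supplied explicitly — a silent 0
would blur exactly the zero-length semantics the transform rests on. The
environment format is `leaf  sample  [count]`, whitespace-delimited, count
defaulting to 1; repeated (leaf, sample) lines are an error unless merging
is requested, since silent summation changes p-values. Writers round-trip
exactly (branch lengths via `repr`). Leaf↔environment joins are strict by
default; `strict=False` keeps unlabeled leaves without counts, logged.

Generated leaf names in `expand` follow `<parent>__<sample>__<k>`
(k = 1..N): deterministic, join-safe, and reversible; a collision with an
existing leaf name is an error, never an automatic rename. Names do not
affect distances or p-values.

## Synthetic fixtures

`gen_labeled_tree` emulates small OTU trees: random recursive agglomeration
with occasional 3-way merges below a bifurcating root, branch lengths
uniform in [0.01, 1] with an optional fraction forced to exactly 0, counts
uniform in [1, max_count], every sample on at least one leaf, ~15% of
leaves carrying a second label. It does **not** emulate real community
structure — no clustered abundances, no depth gradients, no realistic tree
shapes — so passing property tests demonstrates the algebraic contracts
(round-trips, invariances, estimator convergence, agreement with an
independent weighted-UniFrac implementation to 1e-10), not ecological
validity on field data.

The reference inputs are tiny by construction — two-leaf trees with counts
4 (and 10,000 in the scaled variant) and their eight-leaf expansion — and
their exact null spaces (2 and 70 assignments) are enumerated outright, so
the headline numbers are exact rather than estimated; the Monte-Carlo
variant is summarized as a median over 11 seeds at the conventional 100
permutations.

## Known limitations

* Only the weighted UniFrac variant is implemented (no unweighted,
  generalized, or variance-adjusted forms), on rooted trees only.
* Exact enumeration is feasible only for small annotation multisets; above
  the cap the Monte-Carlo path is the honest alternative.
* The compact-semantics shuffle with more than two samples follows the
  all-leaves default described above; tools in the wild may differ, which
  is precisely why both scopes are exposed.
* NEXUS/phyloXML/BIOM input, tree inference, re-rooting, rarefaction, and
  ordination are out of scope.
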