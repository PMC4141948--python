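# wunifrac

Weighted UniFrac distances and permutation significance tests for microbial
community comparison — together with the invertible *compact ↔ expanded*
tree transform that exposes a surprising fact: the significance test's
p-value can depend on which of two semantically identical input formats
you choose.

## The problem

Weighted UniFrac compares two communities (samples) placed on a rooted
phylogeny. With per-branch lengths *b<sub>i</sub>*, per-branch descendant
tallies *A<sub>i</sub>*, *B<sub>i</sub>* and sample totals *A<sub>T</sub>*,
*B<sub>T</sub>*, the raw distance is

```
u = Σ_i  b_i · | A_i/A_T − B_i/B_T |
```

normalized by the maximum attainable value
`D = Σ_j d_j · (A_j/A_T + B_j/B_T)` over leaves *j* at root-to-leaf depth
*d<sub>j</sub>*, so normalized distances lie in [0, 1].

Significance is assessed by shuffling leaf annotations: the p-value is the
fraction of random labelings whose between-sample distance is **greater
than or equal to** the observed one. But the input tree can carry its
abundances in two equivalent forms:

* **compact** — each leaf holds sample labels with abundance counts
  (`A  Sample1  4`);
* **expanded** — each individual is its own unit-count leaf, attached to
  the original leaf by a branch of length exactly 0 (a zero distance means
  identity, so the expansion changes nothing semantically — and indeed the
  weighted UniFrac distance is bitwise identical on both forms).

The permutation test, however, treats them differently. If the shuffle
moves each leaf's whole `sample:count` bundle as one unit (*compact
semantics*), a two-leaf tree with counts 4 | 4 admits only 2 symmetric
assignments and the p-value is always **1.0**. If unit labels are shuffled
across the 8 expanded leaves (*expanded semantics*), there are C(8,4) = 70
distinct assignments, only the original and its mirror reach the observed
distance, and the exact p-value is **2/70 ≈ 0.029**. Same data, opposite
conclusion. This package implements both semantics (Monte-Carlo and exact
enumeration), the transform, and the metric, so the discrepancy is
reproducible, measurable — and avoidable, by expanding your input before
testing.

## Worked example

```
$ wunifrac fixtures demo          # writes the reference inputs
$ cat demo/fig2.tree demo/fig2.env
(A:0.1,B:0.1);
A       Sample1 4
B       Sample2 4

$ wunifrac signif demo/fig2.tree demo/fig2.env --method exact --mode compact
pair    observed        p_value n_null  method  seed
Sample1:Sample2 1       1       2       exact

$ wunifrac signif demo/fig2.tree demo/fig2.env --method exact --mode expanded
pair    observed        p_value n_null  method  seed
Sample1:Sample2 1       0.02857142857   70      exact
```

The observed normalized distance is 1 (the two samples share no branch).
Under compact semantics both of the 2 bundle assignments tie the observed
distance → p = 1.0, "not significantly different". Under expanded
semantics only 2 of the 70 unit-label assignments reach it →
p = 2/70 ≈ 0.0286. A 100-permutation Monte-Carlo run of the expanded test
(`--method mc --n-perm 100 --seed 1`) gives p = 0.03, within the 0–0.04
band typical at that permutation count.

To make any compact input safe for a bundle-shuffling tester, expand it
first:

```
$ wunifrac expand demo/fig2.tree demo/fig2.env -o demo/expanded
$ head -1 demo/expanded.tree
((A__Sample1__1:0,A__Sample1__2:0,A__Sample1__3:0,A__Sample1__4:0)A:0.1,(B__...
$ wunifrac collapse demo/expanded.tree demo/expanded.env -o demo/back   # inverse
```

`wunifrac dist` prints the all-pairs normalized distance matrix. The same
operations are available as a library: `wunifrac.weighted_unifrac`,
`wunifrac.exact_pvalue`, `wunifrac.mc_pvalue`, `wunifrac.expand`,
`wunifrac.collapse`.

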