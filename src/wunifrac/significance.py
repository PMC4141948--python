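"""The UniFrac significance test under both permutation semantics.

The test shuffles leaf annotations uniformly at random, recomputes the
weighted UniFrac distance between the two samples for each shuffle, and
reports

    p = #{ null distances >= observed } / #{ null labelings }

with no pseudo-count (pass ``plus_one=True`` for the standard +1 permutation
correction). The ">=" uses a relative tolerance of 1e-9 on the equality
side, so labelings that are symmetric images of the original tie exactly
despite floating point.

Two permutation semantics are provided, and their disagreement on
compact-form input is the phenomenon this package exists to measure:

* ``compact`` — each leaf's entire annotation bundle (all of its
  sample:count pairs) moves as one indivisible unit; the abundance counts
  stay permanently attached to their labels.
* ``expanded`` — the tree is first expanded so every individual is its own
  unit-count leaf on a zero-length branch, and the individual unit labels
  are shuffled independently. (Inputs already in expanded form pass through
  the expansion unchanged, so pre-expanding is a no-op.)

For a two-leaf tree with counts 4 and 4, compact semantics admit only 2
bundle assignments — both symmetric, hence p = 1.0 — while expanded
semantics admit C(8,4) = 70 unit-label assignments of which only the
original and its mirror reach the observed distance, hence p = 2/70.

Exact enumeration iterates the distinct multiset permutations of the
annotation multiset (every distinct assignment arises from the same number
of underlying orderings, so counting each once preserves the uniform
semantics); Monte Carlo draws independent uniform permutations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from itertools import combinations
from typing import Literal

import numpy as np
from sympy.utilities.iterables import multiset_permutations

from .errors import ContractError, EnumerationCapError, InvalidCountError
from .metric import DistanceResult, branch_partition, weighted_unifrac
from .transform import expand
from .tree import EnvironmentTable, LabeledTree, validate

__all__ = [
    "PermutationSemantics",
    "SignificanceResult",
    "shuffle_labels",
    "mc_pvalue",
    "exact_pvalue",
    "pairwise_significance",
]

#: relative tolerance for the equality side of "distance >= observed"
GE_RTOL = 1e-9

#: default cap on the number of distinct assignments exact enumeration will visit
DEFAULT_ENUM_CAP = 10**6


class PermutationSemantics(str, Enum):
    """Which objects the null distribution shuffles across leaves."""

    COMPACT = "compact"
    EXPANDED = "expanded"


def _as_mode(mode: "PermutationSemantics | str") -> PermutationSemantics:
    return PermutationSemantics(mode)


@dataclass
class SignificanceResult:
    """Outcome of one significance test.

    ``p_value`` equals ``n_ge / n_null`` exactly (or ``(n_ge+1)/(n_null+1)``
    when the +1 correction was requested).
    """

    observed: DistanceResult
    p_value: float
    n_null: int
    n_ge: int
    mode: PermutationSemantics
    method: Literal["monte_carlo", "exact"]
    seed: int | None


def _is_expanded(lt: LabeledTree) -> bool:
    return all(
        sum(b.values()) <= 1 for b in (lt.env.bundle(l.name) for l in lt.root.leaves())
    )


def shuffle_labels(
    lt: LabeledTree,
    mode: "PermutationSemantics | str",
    rng: np.random.Generator,
) -> LabeledTree:
    """One uniformly random re-assignment of the leaf annotations.

    Topology and branch lengths are untouched; the multiset of annotations
    (whole bundles in compact mode, unit labels in expanded mode) is
    permuted uniformly across the leaves, so per-sample totals are
    conserved. In expanded mode the tree must already be in expanded form
    (every leaf carrying at most one unit-count label).
    """
    mode = _as_mode(mode)
    if mode is PermutationSemantics.EXPANDED and not _is_expanded(lt):
        raise ContractError(
            "expanded-mode shuffling requires an expanded tree; call "
            "expand() first (or use mc_pvalue/exact_pvalue, which do)"
        )
    leaves = [leaf.name for leaf in lt.root.leaves()]
    bundles = [lt.env.bundle(name) for name in leaves]
    perm = rng.permutation(len(leaves))
    entries = {
        leaves[i]: bundles[perm[i]] for i in range(len(leaves)) if bundles[perm[i]]
    }
    return validate(lt.root.copy(), EnvironmentTable(entries), strict=False)


class _PairEngine:
    """Vectorized null-distribution machinery for one sample pair.

    Precomputes a leaf-by-branch incidence matrix once; a batch of
    permutations then costs one matrix product. Each leaf slot carries an
    annotation id; ids map to the two per-leaf quantities the distance
    needs, r = cA/A_T - cB/B_T and s = cA/A_T + cB/B_T, where cA, cB are
    the annotation's counts for the tested pair.
    """

    def __init__(
        self,
        lt: LabeledTree,
        sample_a: str,
        sample_b: str,
        mode: PermutationSemantics,
        scope: Literal["all", "occupied"] = "all",
    ):
        if mode is PermutationSemantics.EXPANDED:
            lt = expand(lt)
        self.lt = lt
        self.mode = mode
        self.sample_a = sample_a
        self.sample_b = sample_b

        part = branch_partition(lt)
        self.a_t = part.totals.get(sample_a, 0)
        self.b_t = part.totals.get(sample_b, 0)
        if self.a_t < 1 or self.b_t < 1:
            raise InvalidCountError(
                f"both samples need positive totals ({sample_a}: {self.a_t}, "
                f"{sample_b}: {self.b_t})"
            )
        leaves = lt.root.leaves()
        self.n_leaves = len(leaves)
        # only branches of positive length enter the raw sum, so the
        # incidence matrix keeps columns for those alone — on a fully
        # expanded tree this is what keeps memory linear in leaf count
        keep = {int(i): c for c, i in enumerate(np.nonzero(part.lengths > 0)[0])}
        node_col = {
            id(n): keep[i] for i, n in enumerate(part.nodes) if i in keep
        }
        incidence = np.zeros((self.n_leaves, len(keep)))
        leaf_slot = {id(leaf): j for j, leaf in enumerate(leaves)}
        depths = np.zeros(self.n_leaves)
        # leaf j descends through branch i iff i is on j's root path
        stack = [(lt.root, (), 0.0)]
        while stack:
            node, cols, depth = stack.pop()
            if node is not lt.root:
                depth += node.length
                if id(node) in node_col:
                    cols = cols + (node_col[id(node)],)
            if node.is_leaf:
                j = leaf_slot[id(node)]
                incidence[j, list(cols)] = 1.0
                depths[j] = depth
            for child in node.children:
                stack.append((child, cols, depth))
        self.branch_lengths = part.lengths[part.lengths > 0]
        self.depths = depths
        self.incidence = incidence

        # annotation item per leaf slot: hashable bundle key -> id
        bundles = [
            tuple(sorted(lt.env.bundle(leaf.name).items())) for leaf in leaves
        ]
        keys: dict[tuple, int] = {}
        self.items = np.array([keys.setdefault(b, len(keys)) for b in bundles])
        self.n_items = len(keys)
        r = np.zeros(self.n_items)
        s = np.zeros(self.n_items)
        for key, idx in keys.items():
            bundle = dict(key)
            ca = bundle.get(sample_a, 0)
            cb = bundle.get(sample_b, 0)
            r[idx] = ca / self.a_t - cb / self.b_t
            s[idx] = ca / self.a_t + cb / self.b_t
        self.item_r = r
        self.item_s = s

        if scope == "occupied":
            occupied = np.array(
                [self.item_r[i] != 0 or self.item_s[i] != 0 for i in self.items]
            )
            self.slots = np.nonzero(occupied)[0]
        else:
            self.slots = np.arange(self.n_leaves)

        self.observed = self.distances(self.items[np.newaxis, :])[0]

    def distances(self, item_rows: np.ndarray) -> np.ndarray:
        """Normalized distances for a batch of full leaf-slot assignments
        (rows of annotation ids, one column per leaf in postorder)."""
        r = self.item_r[item_rows]
        s = self.item_s[item_rows]
        tallies = r @ self.incidence  # (batch, branches)
        raw = np.abs(tallies) @ self.branch_lengths
        denom = s @ self.depths
        out = np.zeros(len(raw))
        nonzero = denom > 0
        out[nonzero] = raw[nonzero] / denom[nonzero]
        return out

    def null_rows(self, slot_perms: np.ndarray) -> np.ndarray:
        """Expand permutations (index arrays) of the shuffled slots into
        full slot rows."""
        return self.item_rows(self.items[self.slots][slot_perms])

    def item_rows(self, slot_items: np.ndarray) -> np.ndarray:
        """Full slot rows from explicit item assignments to the shuffled
        slots (one row per assignment)."""
        rows = np.tile(self.items, (len(slot_items), 1))
        rows[:, self.slots] = slot_items
        return rows

    def count_ge(self, null_d: np.ndarray) -> int:
        thresh = self.observed - GE_RTOL * abs(self.observed)
        return int(np.count_nonzero(null_d >= thresh))

    def n_distinct(self) -> int:
        """Number of distinct assignments of the annotation multiset."""
        items = self.items[self.slots]
        n = len(items)
        total = math.factorial(n)
        for mult in np.unique(items, return_counts=True)[1]:
            total //= math.factorial(int(mult))
        return total


def _result(
    engine: _PairEngine,
    n_ge: int,
    n_null: int,
    method: Literal["monte_carlo", "exact"],
    seed: int | None,
    plus_one: bool,
) -> SignificanceResult:
    observed = weighted_unifrac(
        engine.lt, engine.sample_a, engine.sample_b, normalized=True
    )
    if plus_one:
        p = (n_ge + 1) / (n_null + 1)
    else:
        p = n_ge / n_null
    return SignificanceResult(
        observed=observed,
        p_value=p,
        n_null=n_null,
        n_ge=n_ge,
        mode=engine.mode,
        method=method,
        seed=seed,
    )


def mc_pvalue(
    lt: LabeledTree,
    sample_a: str,
    sample_b: str,
    mode: "PermutationSemantics | str" = PermutationSemantics.COMPACT,
    n_perm: int = 100,
    seed: int | None = None,
    scope: Literal["all", "occupied"] = "all",
    plus_one: bool = False,
) -> SignificanceResult:
    """Monte-Carlo significance test for one sample pair.

    Draws ``n_perm`` independent uniform shuffles of the annotation
    multiset (per ``mode``), computes the normalized weighted UniFrac
    distance for each, and reports the fraction at or above the observed
    distance. Fully reproducible given ``seed``. The default of 100
    permutations mirrors common web-tool usage and is statistically coarse;
    raise it for stable estimates.

    ``scope`` controls which leaves participate in the shuffle when other
    samples occupy some leaves: ``"all"`` (default) permutes annotations
    across every leaf, ``"occupied"`` only across leaves carrying counts of
    the tested pair.
    """
    mode = _as_mode(mode)
    if n_perm < 1:
        raise InvalidCountError(f"n_perm must be >= 1, got {n_perm}")
    engine = _PairEngine(lt, sample_a, sample_b, mode, scope)
    rng = np.random.default_rng(seed)
    k = len(engine.slots)
    n_ge = 0
    chunk = 20_000
    for start in range(0, n_perm, chunk):
        size = min(chunk, n_perm - start)
        perms = np.argsort(rng.random((size, k)), axis=1)
        null_d = engine.distances(engine.null_rows(perms))
        n_ge += engine.count_ge(null_d)
    return _result(engine, n_ge, n_perm, "monte_carlo", seed, plus_one)


def exact_pvalue(
    lt: LabeledTree,
    sample_a: str,
    sample_b: str,
    mode: "PermutationSemantics | str" = PermutationSemantics.COMPACT,
    scope: Literal["all", "occupied"] = "all",
    plus_one: bool = False,
    cap: int = DEFAULT_ENUM_CAP,
) -> SignificanceResult:
    """Exact-enumeration significance test for one sample pair.

    Visits every distinct assignment of the annotation multiset exactly
    once. Distinct assignments are equiprobable under uniform shuffling
    (each corresponds to the same number of raw orderings), so the count of
    assignments at or above the observed distance over the total is the
    exact p-value.

    Raises
    ------
    EnumerationCapError
        More than ``cap`` distinct assignments; use :func:`mc_pvalue`.
    """
    mode = _as_mode(mode)
    engine = _PairEngine(lt, sample_a, sample_b, mode, scope)
    total = engine.n_distinct()
    if total > cap:
        if total < 10**18:
            shown = str(total)
        else:  # avoid stringifying astronomically large integers
            shown = f"~10^{int(total.bit_length() * 0.30103)}"
        raise EnumerationCapError(
            f"{shown} distinct assignments exceed the enumeration cap "
            f"({cap}); use mc_pvalue instead"
        )
    items = [int(i) for i in engine.items[engine.slots]]
    n_ge = 0
    batch: list[list[int]] = []
    chunk = 20_000
    for perm in multiset_permutations(items):
        batch.append(perm)
        if len(batch) == chunk:
            null_d = engine.distances(engine.item_rows(np.asarray(batch)))
            n_ge += engine.count_ge(null_d)
            batch = []
    if batch:
        null_d = engine.distances(engine.item_rows(np.asarray(batch)))
        n_ge += engine.count_ge(null_d)
    return _result(engine, n_ge, total, "exact", None, plus_one)


def pairwise_significance(
    lt: LabeledTree,
    mode: "PermutationSemantics | str" = PermutationSemantics.COMPACT,
    method: Literal["monte_carlo", "exact"] = "monte_carlo",
    n_perm: int = 100,
    seed: int | None = None,
    scope: Literal["all", "occupied"] = "all",
    plus_one: bool = False,
    bonferroni: bool = False,
) -> dict[tuple[str, str], SignificanceResult]:
    """Each-pair-of-environments significance tests.

    For every unordered sample pair, only that pair's counts participate:
    other samples' individuals are stripped from the environment before the
    pair's test (their leaves remain in the topology, carrying empty
    annotations that still take part in the shuffle under the default
    all-leaves scope). P-values are uncorrected by default; ``bonferroni``
    multiplies each by the number of pairs, clipped to 1.
    """
    mode = _as_mode(mode)
    samples = lt.samples
    if len(samples) < 2:
        raise InvalidCountError("need at least 2 samples")
    pairs = list(combinations(samples, 2))
    results: dict[tuple[str, str], SignificanceResult] = {}
    for k, (a, b) in enumerate(pairs):
        sub = validate(lt.root.copy(), lt.env.restrict([a, b]), strict=False)
        if method == "exact":
            res = exact_pvalue(sub, a, b, mode, scope, plus_one)
        else:
            pair_seed = None if seed is None else (seed + 7919 * k) % (2**31)
            res = mc_pvalue(sub, a, b, mode, n_perm, pair_seed, scope, plus_one)
        if bonferroni:
            res.p_value = min(1.0, res.p_value * len(pairs))
        results[(a, b)] = res
    return results
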