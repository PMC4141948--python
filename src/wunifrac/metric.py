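"""Weighted UniFrac distance between samples on a labeled tree.

For two samples A and B with per-branch descendant tallies A_i, B_i and
totals A_T, B_T, the raw weighted UniFrac distance is

    u = sum_i  b_i * | A_i/A_T - B_i/B_T |

over every branch i (the root has no branch), with b_i the branch length.
The normalized variant divides by the maximum attainable value

    D = sum_j  d_j * ( A_j/A_T + B_j/B_T )

over leaves j, where d_j is the root-to-leaf path length and A_j, B_j the
leaf counts; normalized distances lie in [0, 1].

Implementation notes that matter for reproducibility:

* Branch tallies are accumulated as integers in a single postorder pass, so
  a compact tree and its zero-length expansion produce bitwise-identical
  per-branch terms (the added branches contribute exact zeros).
* The denominator aggregates integer leaf counts per distinct depth before
  any division, in first-encounter postorder order, for the same reason.
* Accumulation order is the deterministic postorder traversal throughout.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DegenerateInputError, InvalidCountError
from .tree import LabeledTree, PhyloNode

__all__ = ["BranchPartition", "DistanceResult", "branch_partition",
           "weighted_unifrac", "distance_matrix"]


@dataclass
class BranchPartition:
    """Per-branch per-sample descendant tallies.

    ``nodes`` lists every non-root node in postorder; ``lengths[i]`` is the
    branch length leading to ``nodes[i]`` and ``tallies[sample][i]`` the
    total abundance of ``sample`` among leaves descending through that
    branch. ``totals[sample]`` is the sample's whole-tree total, which
    equals the tally on any branch covering all of the sample's leaves.
    """

    nodes: list[PhyloNode]
    lengths: np.ndarray
    tallies: dict[str, np.ndarray]
    totals: dict[str, int]


def branch_partition(lt: LabeledTree) -> BranchPartition:
    """Tally per-sample descendant counts on every branch (postorder, O(n))."""
    samples = lt.samples
    index = {s: k for k, s in enumerate(samples)}
    nodes: list[PhyloNode] = []
    lengths: list[float] = []
    rows: list[np.ndarray] = []
    # per-node tally vectors, built children-first
    acc: dict[int, np.ndarray] = {}
    for node in lt.root.postorder():
        if node.is_leaf:
            vec = np.zeros(len(samples), dtype=np.int64)
            for sample, count in lt.env.bundle(node.name).items():
                vec[index[sample]] = count
        else:
            vec = np.zeros(len(samples), dtype=np.int64)
            for child in node.children:
                vec += acc.pop(id(child))
        acc[id(node)] = vec
        if node is not lt.root:
            nodes.append(node)
            lengths.append(node.length)
            rows.append(vec)
    total_vec = acc[id(lt.root)]
    tallies = {
        s: np.array([row[index[s]] for row in rows], dtype=np.int64)
        for s in samples
    }
    totals = {s: int(total_vec[index[s]]) for s in samples}
    return BranchPartition(nodes, np.asarray(lengths, dtype=float), tallies, totals)


@dataclass
class DistanceResult:
    """Raw and normalized weighted UniFrac distance for one sample pair."""

    raw: float
    normalized: float | None
    sample_pair: tuple[str, str]

    @property
    def value(self) -> float:
        """Normalized distance when computed, otherwise the raw distance."""
        return self.raw if self.normalized is None else self.normalized


def weighted_unifrac(
    lt: LabeledTree,
    sample_a: str,
    sample_b: str,
    normalized: bool = True,
) -> DistanceResult:
    """Weighted UniFrac distance between two samples.

    Parameters
    ----------
    lt : LabeledTree
    sample_a, sample_b : str
        Sample names; both must have positive totals in ``lt``.
    normalized : bool
        Compute the normalized distance (default, in [0, 1]) in addition to
        the raw value. The raw value is always returned.

    Raises
    ------
    InvalidCountError
        Unknown sample or zero total.
    DegenerateInputError
        Normalization requested but every individual of both samples sits
        at depth 0 (denominator would be 0).
    """
    for s in (sample_a, sample_b):
        if s not in lt.samples:
            raise InvalidCountError(f"unknown sample {s!r}")
    part = branch_partition(lt)
    a_t = part.totals[sample_a]
    b_t = part.totals[sample_b]
    if a_t < 1 or b_t < 1:
        raise InvalidCountError(
            f"samples must have positive totals ({sample_a}: {a_t}, "
            f"{sample_b}: {b_t})"
        )
    ta = part.tallies[sample_a]
    tb = part.tallies[sample_b]
    raw = 0.0
    for i in range(len(part.lengths)):
        ai = int(ta[i])
        bi = int(tb[i])
        if ai == 0 and bi == 0:
            continue  # contributes 0; skipping fixes nothing but time
        raw += part.lengths[i] * abs(ai / a_t - bi / b_t)

    norm: float | None = None
    if normalized:
        # integer leaf counts grouped by exact depth before any division:
        # keeps compact trees and their zero-length expansions bitwise equal
        depth_counts: dict[float, list[int]] = {}
        order: list[float] = []
        stack: list[tuple[PhyloNode, float]] = [(lt.root, 0.0)]
        while stack:
            node, depth = stack.pop()
            if node.is_leaf:
                bundle = lt.env.bundle(node.name)
                ca = bundle.get(sample_a, 0)
                cb = bundle.get(sample_b, 0)
                if ca or cb:
                    if depth not in depth_counts:
                        depth_counts[depth] = [0, 0]
                        order.append(depth)
                    depth_counts[depth][0] += ca
                    depth_counts[depth][1] += cb
            for child in reversed(node.children):
                stack.append((child, depth + child.length))
        denom = 0.0
        for depth in order:
            ca, cb = depth_counts[depth]
            denom += depth * (ca / a_t + cb / b_t)
        if denom == 0.0:
            raise DegenerateInputError(
                "normalization denominator is 0: every individual of "
                "both samples sits at depth 0"
            )
        norm = raw / denom
    return DistanceResult(raw, norm, (sample_a, sample_b))


def distance_matrix(lt: LabeledTree, normalized: bool = True) -> pd.DataFrame:
    """All-pairs weighted UniFrac distances as a labeled symmetric matrix."""
    samples = lt.samples
    if len(samples) < 2:
        raise InvalidCountError("need at least 2 samples for a matrix")
    mat = np.zeros((len(samples), len(samples)))
    for i, a in enumerate(samples):
        for j in range(i + 1, len(samples)):
            d = weighted_unifrac(lt, a, samples[j], normalized=normalized)
            mat[i, j] = mat[j, i] = d.value
    return pd.DataFrame(mat, index=samples, columns=samples)
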