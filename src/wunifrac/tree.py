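"""Core rooted-tree and environment data structures.

A :class:`PhyloNode` is a rooted tree node with a branch length leading to
it from its parent; a leaf represents an OTU. An :class:`EnvironmentTable`
binds leaf names to per-sample abundance counts (positive integers). A
:class:`LabeledTree` is the validated join of the two — the object every
distance and significance routine consumes.

Branch lengths may be any distance metric; units are arbitrary. The root's
own branch length, if present in the source, is ignored and treated as 0.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterator, Mapping

from .errors import InvalidCountError, JoinError, TreeFormatError

logger = logging.getLogger(__name__)

__all__ = ["PhyloNode", "EnvironmentTable", "LabeledTree", "validate", "leaf_depths"]


@dataclass
class PhyloNode:
    """A node of a rooted phylogenetic tree.

    Parameters
    ----------
    name : str
        Node label. Leaves must be named; internal nodes may be anonymous
        (empty string).
    length : float
        Length of the branch leading to this node from its parent.
        Non-negative; ignored (treated as 0) on the root.
    children : list of PhyloNode
        Ordered children. Empty list means this node is a leaf.
        Multifurcations (three or more children) are permitted.
    """

    name: str = ""
    length: float = 0.0
    children: list["PhyloNode"] = field(default_factory=list)

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def postorder(self) -> Iterator["PhyloNode"]:
        """Yield nodes children-first, in a fixed deterministic order."""
        stack: list[tuple[PhyloNode, bool]] = [(self, False)]
        while stack:
            node, expanded = stack.pop()
            if expanded:
                yield node
            else:
                stack.append((node, True))
                for child in reversed(node.children):
                    stack.append((child, False))

    def leaves(self) -> list["PhyloNode"]:
        """Leaves in deterministic (postorder = left-to-right) order."""
        return [n for n in self.postorder() if n.is_leaf]

    def copy(self) -> "PhyloNode":
        """Deep copy of the subtree rooted here."""
        return PhyloNode(
            self.name, self.length, [c.copy() for c in self.children]
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, PhyloNode):
            return NotImplemented
        return (
            self.name == other.name
            and self.length == other.length
            and self.children == other.children
        )


class EnvironmentTable:
    """Mapping from leaf name to per-sample abundance counts.

    Counts are strictly positive integers: the expand transform creates one
    discrete unit-count leaf per individual, so fractional abundances are
    rejected outright.

    Parameters
    ----------
    entries : mapping of str to mapping of str to int
        ``{leaf_name: {sample_name: count}}``.
    """

    def __init__(self, entries: Mapping[str, Mapping[str, int]]):
        clean: dict[str, dict[str, int]] = {}
        for leaf, bundle in entries.items():
            clean_bundle: dict[str, int] = {}
            for sample, count in bundle.items():
                if isinstance(count, bool) or not isinstance(count, int):
                    raise InvalidCountError(
                        f"count for leaf {leaf!r}, sample {sample!r} must be "
                        f"a positive integer, got {count!r}"
                    )
                if count < 1:
                    raise InvalidCountError(
                        f"count for leaf {leaf!r}, sample {sample!r} must be "
                        f">= 1, got {count}"
                    )
                clean_bundle[sample] = count
            if clean_bundle:
                clean[leaf] = clean_bundle
        if not clean:
            raise InvalidCountError("environment table is empty")
        self._entries = clean

    @property
    def entries(self) -> dict[str, dict[str, int]]:
        return self._entries

    def samples(self) -> list[str]:
        """Distinct sample names, sorted for determinism."""
        seen: set[str] = set()
        for bundle in self._entries.values():
            seen.update(bundle)
        return sorted(seen)

    def total(self, sample: str) -> int:
        """Total abundance of one sample summed over all leaves."""
        return sum(
            bundle.get(sample, 0) for bundle in self._entries.values()
        )

    def bundle(self, leaf: str) -> dict[str, int]:
        """The (possibly empty) sample:count bundle attached to one leaf."""
        return dict(self._entries.get(leaf, {}))

    def restrict(self, samples: list[str]) -> "EnvironmentTable":
        """New table keeping only the given samples' counts."""
        keep = set(samples)
        out = {
            leaf: {s: c for s, c in bundle.items() if s in keep}
            for leaf, bundle in self._entries.items()
        }
        return EnvironmentTable({k: v for k, v in out.items() if v})

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, EnvironmentTable):
            return NotImplemented
        return self._entries == other._entries

    def __contains__(self, leaf: str) -> bool:
        return leaf in self._entries

    def __iter__(self) -> Iterator[str]:
        return iter(self._entries)

    def __repr__(self) -> str:
        return f"EnvironmentTable({self._entries!r})"


@dataclass
class LabeledTree:
    """A validated tree + environment pair. Construct via :func:`validate`."""

    root: PhyloNode
    env: EnvironmentTable
    samples: list[str]

    def copy(self) -> "LabeledTree":
        return LabeledTree(
            self.root.copy(),
            EnvironmentTable(self.env.entries),
            list(self.samples),
        )

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabeledTree):
            return NotImplemented
        return (
            self.root == other.root
            and self.env == other.env
            and self.samples == other.samples
        )


def validate(
    tree: PhyloNode,
    env: EnvironmentTable,
    strict: bool = True,
) -> LabeledTree:
    """Join a tree with an environment table, checking every invariant.

    Parameters
    ----------
    tree : PhyloNode
        Root of the tree. Leaf names must be unique and non-empty; branch
        lengths non-negative (the root's own length is ignored).
    env : EnvironmentTable
        Per-leaf sample counts. Every referenced leaf must exist in the tree.
    strict : bool
        If True (default), every leaf of the tree must have an environment
        entry. If False, unlabeled leaves are kept in the topology but carry
        no counts; a warning is logged. The permutation-test discrepancy is
        sensitive to which leaves carry counts, so strict is the default.

    Returns
    -------
    LabeledTree

    Raises
    ------
    TreeFormatError
        Duplicate or empty leaf name, or negative branch length.
    JoinError
        Environment references an unknown leaf, or (strict mode) a tree
        leaf has no environment entry.
    """
    leaf_names: list[str] = []
    for node in tree.postorder():
        if node is not tree and node.length < 0:
            raise TreeFormatError(
                f"negative branch length {node.length} on node {node.name!r}"
            )
        if node.is_leaf:
            if not node.name:
                raise TreeFormatError("tree contains an unnamed leaf")
            leaf_names.append(node.name)
    seen: set[str] = set()
    for name in leaf_names:
        if name in seen:
            raise TreeFormatError(f"duplicate leaf name {name!r}")
        seen.add(name)

    unknown = [leaf for leaf in env if leaf not in seen]
    if unknown:
        raise JoinError(
            f"environment references leaves not in the tree: {sorted(unknown)}"
        )
    unlabeled = [name for name in leaf_names if name not in env]
    if unlabeled:
        if strict:
            raise JoinError(
                f"tree leaves without environment entries: {sorted(unlabeled)}"
                " (use strict=False to keep them without counts)"
            )
        logger.warning(
            "keeping %d unlabeled leaves without counts: %s",
            len(unlabeled),
            sorted(unlabeled),
        )

    samples = env.samples()
    for sample in samples:
        if env.total(sample) < 1:
            raise InvalidCountError(f"sample {sample!r} has zero total count")
    return LabeledTree(tree, env, samples)


def leaf_depths(tree: PhyloNode) -> dict[str, float]:
    """Root-to-leaf path length for every leaf.

    The root's own branch length is ignored. Depths are accumulated
    top-down, so ``depth(child) = depth(parent) + child.length`` holds
    exactly in floating point.
    """
    depths: dict[str, float] = {}
    stack: list[tuple[PhyloNode, float]] = [(tree, 0.0)]
    while stack:
        node, depth = stack.pop()
        if node.is_leaf and node is not tree:
            depths[node.name] = depth
        elif node.is_leaf:  # single-node tree
            depths[node.name] = 0.0
        for child in reversed(node.children):
            stack.append((child, depth + child.length))
    return depths
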