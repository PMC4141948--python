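"""The invertible compact <-> expanded tree transform.

A *compact* tree annotates leaves with sample labels carrying abundance
counts; the *expanded* tree replaces every such leaf by one unit-count leaf
per individual, attached by a branch of length exactly 0. Because a distance
of zero means identity (the coincidence axiom), the two forms are
semantically the same object — yet permutation tests that shuffle leaf
annotations treat them very differently, which is exactly what this package
lets you measure.

``expand`` is idempotent and ``collapse(expand(t)) == t`` whenever ``t`` is
in canonical compact form (contains no all-zero pre-terminal node itself).

The zero test on branch lengths is exact (``== 0``) by default: an implicit
epsilon would silently change which trees count as equivalent. Pass
``tol`` to ``collapse`` to opt into a tolerance explicitly.
"""

from __future__ import annotations

from dataclasses import dataclass

from .errors import JoinError, TreeFormatError
from .tree import EnvironmentTable, LabeledTree, PhyloNode, validate

__all__ = ["PreTerminalNode", "expand", "collapse", "find_pre_terminals"]


@dataclass
class PreTerminalNode:
    """An internal node all of whose children are leaves.

    ``all_zero`` is True iff every child branch length is exactly 0 —
    the condition under which the node may be collapsed back into a
    count-annotated leaf.
    """

    node: PhyloNode
    all_zero: bool


def find_pre_terminals(root: PhyloNode, tol: float = 0.0) -> list[PreTerminalNode]:
    """All pre-terminal nodes of the tree, in postorder."""
    out = []
    for node in root.postorder():
        if node.children and all(c.is_leaf for c in node.children):
            out.append(
                PreTerminalNode(
                    node, all(c.length <= tol for c in node.children)
                )
            )
    return out


def _child_name(parent: str, sample: str, k: int) -> str:
    return f"{parent}__{sample}__{k}"


def expand(lt: LabeledTree) -> LabeledTree:
    """Expand a labeled tree so every individual is its own unit-count leaf.

    Every leaf whose total count exceeds 1, or which carries more than one
    sample label, becomes an interior node: for each of its sample labels
    with count N, N new leaves are attached by branches of length exactly 0,
    each labeled with that sample at count 1. Leaves already carrying a
    single label with count 1 are left untouched, so the operation is
    idempotent. Generated leaf names follow ``<parent>__<sample>__<k>``
    (k = 1..N) — deterministic and reversible; a clash with an existing
    leaf name is an error rather than silently renamed.

    Returns a new LabeledTree; the input is not modified.
    """
    root = lt.root.copy()
    existing = {leaf.name for leaf in root.leaves()}
    new_entries: dict[str, dict[str, int]] = {}

    for node in root.postorder():
        if not node.is_leaf:
            continue
        bundle = lt.env.bundle(node.name)
        if not bundle:
            continue  # unlabeled leaf (lenient join): nothing to expand
        total = sum(bundle.values())
        if total == 1 and len(bundle) == 1:
            new_entries[node.name] = bundle
            continue
        for sample in bundle:  # insertion order: deterministic
            for k in range(1, bundle[sample] + 1):
                child_name = _child_name(node.name, sample, k)
                if child_name in existing:
                    raise TreeFormatError(
                        f"generated leaf name {child_name!r} collides with an "
                        "existing leaf; rename the input leaves"
                    )
                existing.add(child_name)
                node.children.append(PhyloNode(child_name, 0.0))
                new_entries[child_name] = {sample: 1}
    return validate(root, EnvironmentTable(new_entries), strict=False)


def collapse(lt: LabeledTree, tol: float = 0.0) -> LabeledTree:
    """Collapse every all-zero pre-terminal node into a count-annotated leaf.

    For each pre-terminal node T whose children all sit on branches of
    length 0 (or <= ``tol`` if given), T absorbs its children: it becomes a
    leaf whose environment entry maps each child sample label to the number
    of individuals (summed counts) bearing that label. Collapsing proceeds
    bottom-up to a fixed point, so stacked zero-length levels fully
    collapse. Subtrees with any non-zero child branch are untouched.

    Raises
    ------
    JoinError
        A child of a qualifying node has no environment entry.
    TreeFormatError
        A qualifying node is anonymous (the resulting leaf would have no
        name to hold the counts).
    """
    root = lt.root.copy()
    entries = {leaf: lt.env.bundle(leaf) for leaf in lt.env}

    def visit(node: PhyloNode) -> None:
        for child in node.children:
            visit(child)
        if not node.children or not all(c.is_leaf for c in node.children):
            return
        if not all(c.length <= tol for c in node.children):
            return
        if not node.name:
            raise TreeFormatError(
                "cannot collapse an anonymous pre-terminal node: the "
                "resulting leaf needs a name to carry its counts"
            )
        merged: dict[str, int] = {}
        for child in node.children:
            bundle = entries.pop(child.name, None)
            if bundle is None:
                raise JoinError(
                    f"child {child.name!r} of collapsible node {node.name!r} "
                    "has no environment entry"
                )
            for sample, count in bundle.items():
                merged[sample] = merged.get(sample, 0) + count
        node.children = []
        entries[node.name] = merged

    visit(root)
    return validate(root, EnvironmentTable(entries), strict=False)
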