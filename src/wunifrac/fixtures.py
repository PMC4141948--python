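"""Reference inputs and a random fixture generator.

``figure_fixtures`` builds the canonical minimal examples on which the
compact/expanded p-value discrepancy is demonstrated:

* ``fig1`` — two leaves A, B at branch length 0.1, one individual each
  (Sample1 at A, Sample2 at B): the no-abundance-counts case.
* ``fig2`` — the same topology with abundance counts of 4 at each leaf:
  the compact form.
* ``fig3`` — the expansion of ``fig2``: eight unit-count leaves on
  zero-length branches, four per sample.
* ``fig2_scaled`` — the compact form pushed to the extreme: counts of
  10,000 at branch lengths 0.9, two large disjoint communities far apart,
  for which compact-semantics testing still returns p = 1.0.

``gen_labeled_tree`` produces random valid labeled trees for property
tests: random recursive bifurcation with occasional multifurcation,
branch lengths uniform in a range with an optional fraction forced to
exactly 0, counts uniform positive integers, every sample on >= 1 leaf.
Deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import InvalidCountError
from .io import parse_newick
from .transform import expand
from .tree import EnvironmentTable, LabeledTree, PhyloNode, validate

__all__ = ["FixtureSpec", "gen_labeled_tree", "figure_fixtures"]


@dataclass
class FixtureSpec:
    """Parameters of one random labeled tree."""

    n_leaves: int = 8
    n_samples: int = 2
    max_count: int = 5
    branch_length_range: tuple[float, float] = (0.01, 1.0)
    zero_branch_fraction: float = 0.0
    multi_label_fraction: float = 0.15
    multifurcation_prob: float = 0.15
    seed: int = 0


def gen_labeled_tree(spec: FixtureSpec) -> LabeledTree:
    """Random valid LabeledTree; identical output for identical spec."""
    if spec.n_leaves < 2 or spec.n_samples < 2:
        raise InvalidCountError("need n_leaves >= 2 and n_samples >= 2")
    if spec.n_samples > spec.n_leaves:
        raise InvalidCountError(
            f"cannot place {spec.n_samples} samples on {spec.n_leaves} leaves "
            "with every sample represented"
        )
    rng = np.random.default_rng(spec.seed)
    lo, hi = spec.branch_length_range
    if lo < 0 or hi < lo:
        raise InvalidCountError("branch_length_range must satisfy 0 <= lo <= hi")

    def draw_length() -> float:
        if rng.random() < spec.zero_branch_fraction:
            return 0.0
        return float(rng.uniform(lo, hi))

    nodes = [
        PhyloNode(f"L{i + 1}", draw_length()) for i in range(spec.n_leaves)
    ]
    # random recursive agglomeration; occasional 3-way merge below the
    # root (the root itself stays bifurcating, the conventional rooted shape)
    while len(nodes) > 1:
        k = 3 if (len(nodes) > 3 and rng.random() < spec.multifurcation_prob) else 2
        picks = sorted(rng.choice(len(nodes), size=k, replace=False))
        children = [nodes[i] for i in picks]
        for i in reversed(picks):
            nodes.pop(i)
        nodes.append(PhyloNode("", draw_length(), children))
    root = nodes[0]
    root.length = 0.0

    samples = [f"S{i + 1}" for i in range(spec.n_samples)]
    leaf_names = [leaf.name for leaf in root.leaves()]
    # first n_samples leaves (shuffled) guarantee coverage; rest are random
    primary = list(rng.permutation(leaf_names))
    entries: dict[str, dict[str, int]] = {}
    for i, leaf in enumerate(primary):
        sample = samples[i] if i < spec.n_samples else samples[rng.integers(spec.n_samples)]
        entries[leaf] = {sample: int(rng.integers(1, spec.max_count + 1))}
    for leaf in leaf_names:
        if rng.random() < spec.multi_label_fraction:
            extra = samples[rng.integers(spec.n_samples)]
            if extra not in entries[leaf]:
                entries[leaf][extra] = int(rng.integers(1, spec.max_count + 1))
    return validate(root, EnvironmentTable(entries))


def figure_fixtures() -> dict[str, LabeledTree]:
    """The four canonical minimal inputs (see module docstring)."""
    two_leaf = "(A:0.1,B:0.1);"
    fig1 = validate(
        parse_newick(two_leaf),
        EnvironmentTable({"A": {"Sample1": 1}, "B": {"Sample2": 1}}),
    )
    fig2 = validate(
        parse_newick(two_leaf),
        EnvironmentTable({"A": {"Sample1": 4}, "B": {"Sample2": 4}}),
    )
    fig3 = expand(fig2)
    fig2_scaled = validate(
        parse_newick("(A:0.9,B:0.9);"),
        EnvironmentTable({"A": {"Sample1": 10000}, "B": {"Sample2": 10000}}),
    )
    return {"fig1": fig1, "fig2": fig2, "fig3": fig3, "fig2_scaled": fig2_scaled}
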