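"""Readers and writers for Newick trees and UniFrac environment files.

The Newick dialect here is deliberately literal-minded, because leaf-name
identity is what joins the tree to the environment table and the zero-length
branch semantics drive the compact/expanded equivalence:

* labels are taken byte-for-byte — no quoting rules, no underscore-to-space
  conversion;
* a branch without an explicit ``:length`` is a hard error unless the caller
  supplies ``default_length`` explicitly (a silent default of 0 would blur
  exactly the zero-length semantics the transform depends on);
* parse errors report the character offset.

The environment file is the UniFrac web-service format: one record per line,
``leaf_name  sample_name  [count]``, whitespace-delimited, count defaulting
to 1. Writers guarantee exact round-trips.
"""

from __future__ import annotations

import logging

from .errors import EnvFormatError, TreeFormatError
from .tree import EnvironmentTable, PhyloNode

logger = logging.getLogger(__name__)

__all__ = ["parse_newick", "write_newick", "parse_env", "write_env"]

_SPECIAL = set("(),:;")


class _NewickScanner:
    def __init__(self, text: str):
        self.text = text
        self.pos = 0

    def skip_ws(self) -> None:
        while self.pos < len(self.text) and self.text[self.pos].isspace():
            self.pos += 1

    def peek(self) -> str:
        self.skip_ws()
        if self.pos >= len(self.text):
            return ""
        return self.text[self.pos]

    def take(self) -> str:
        ch = self.peek()
        self.pos += 1
        return ch

    def label(self) -> str:
        """Longest run of non-special, non-whitespace characters, literally."""
        self.skip_ws()
        start = self.pos
        while (
            self.pos < len(self.text)
            and self.text[self.pos] not in _SPECIAL
            and not self.text[self.pos].isspace()
        ):
            self.pos += 1
        return self.text[start : self.pos]

    def fail(self, message: str) -> TreeFormatError:
        return TreeFormatError(message, offset=min(self.pos, len(self.text)))


def parse_newick(text: str, default_length: float | None = None) -> PhyloNode:
    """Parse a single Newick statement into a rooted tree.

    Parameters
    ----------
    text : str
        One Newick statement ending in ``;``.
    default_length : float, optional
        If given, substituted for branches that carry no explicit
        ``:length``. By default a missing length is an error.

    Returns
    -------
    PhyloNode
        Root of the tree. A root-level ``:length`` is parsed but recorded
        as 0 — the rooted topology below the root is what the distance
        operates on.

    Raises
    ------
    TreeFormatError
        On unbalanced parentheses, a missing ``;`` terminator, an empty
        leaf name, or a missing/invalid branch length; the error carries
        the character offset.
    """
    scanner = _NewickScanner(text)
    root = _parse_clade(scanner, default_length, at_root=True)
    if scanner.peek() != ";":
        raise scanner.fail("expected ';' terminator")
    scanner.take()
    if scanner.peek() != "":
        raise scanner.fail("trailing content after ';'")
    root.length = 0.0
    return root


def _parse_clade(
    scanner: _NewickScanner, default_length: float | None, at_root: bool = False
) -> PhyloNode:
    node = PhyloNode()
    if scanner.peek() == "(":
        scanner.take()
        while True:
            node.children.append(_parse_clade(scanner, default_length))
            ch = scanner.peek()
            if ch == ",":
                scanner.take()
                continue
            if ch == ")":
                scanner.take()
                break
            raise scanner.fail("expected ',' or ')'")
        node.name = scanner.label()  # optional internal label
    else:
        node.name = scanner.label()
        if not node.name:
            raise scanner.fail("empty leaf name")
    if scanner.peek() == ":":
        scanner.take()
        raw = scanner.label()
        try:
            node.length = float(raw)
        except ValueError:
            raise scanner.fail(f"invalid branch length {raw!r}") from None
    elif not at_root:
        if default_length is None:
            raise scanner.fail(
                f"missing branch length on {node.name or 'internal node'!r}; "
                "pass default_length to substitute one explicitly"
            )
        node.length = default_length
    return node


def _format_length(value: float) -> str:
    # repr round-trips float64 exactly; strip a trailing ".0" for integers
    text = repr(float(value))
    return text[:-2] if text.endswith(".0") else text


def _write_clade(node: PhyloNode, out: list[str], at_root: bool) -> None:
    if node.children:
        out.append("(")
        for i, child in enumerate(node.children):
            if i:
                out.append(",")
            _write_clade(child, out, at_root=False)
        out.append(")")
        out.append(node.name)
    else:
        out.append(node.name)
    if not at_root:
        out.append(f":{_format_length(node.length)}")


def write_newick(tree: PhyloNode) -> str:
    """Serialize a tree to Newick with exactly round-tripping branch lengths."""
    out: list[str] = []
    _write_clade(tree, out, at_root=True)
    out.append(";")
    return "".join(out)


def parse_env(text: str, merge_duplicates: bool = False) -> EnvironmentTable:
    """Parse an environment file.

    Each non-blank line is ``leaf_name sample_name [count]``, split on any
    run of tabs/spaces; a missing count means 1.

    Parameters
    ----------
    text : str
    merge_duplicates : bool
        Repeated (leaf, sample) lines are an error by default, because
        silently summing them changes p-values; pass True to sum them with
        a logged warning.

    Raises
    ------
    EnvFormatError
        Wrong field count, non-integer or non-positive count, or a repeated
        (leaf, sample) pair; the error carries the 1-based line number.
    """
    entries: dict[str, dict[str, int]] = {}
    any_line = False
    for lineno, line in enumerate(text.splitlines(), start=1):
        fields = line.split()
        if not fields:
            continue
        any_line = True
        if len(fields) == 2:
            leaf, sample = fields
            count = 1
        elif len(fields) == 3:
            leaf, sample, raw = fields
            try:
                count = int(raw)
            except ValueError:
                raise EnvFormatError(
                    f"count {raw!r} is not an integer", line=lineno
                ) from None
            if count < 1:
                raise EnvFormatError(
                    f"count must be >= 1, got {count}", line=lineno
                )
        else:
            raise EnvFormatError(
                f"expected 2 or 3 fields, got {len(fields)}", line=lineno
            )
        bundle = entries.setdefault(leaf, {})
        if sample in bundle:
            if not merge_duplicates:
                raise EnvFormatError(
                    f"repeated (leaf, sample) pair ({leaf!r}, {sample!r}); "
                    "pass merge_duplicates=True to sum counts",
                    line=lineno,
                )
            logger.warning(
                "merging duplicate entry (%s, %s): %d + %d",
                leaf, sample, bundle[sample], count,
            )
            bundle[sample] += count
        else:
            bundle[sample] = count
    if not any_line:
        raise EnvFormatError("environment file is empty")
    return EnvironmentTable(entries)


def write_env(env: EnvironmentTable) -> str:
    """Serialize an environment table: one tab-delimited record per line,
    sorted by leaf then sample, counts always written."""
    lines = []
    for leaf in sorted(env.entries):
        for sample in sorted(env.entries[leaf]):
            lines.append(f"{leaf}\t{sample}\t{env.entries[leaf][sample]}")
    return "\n".join(lines) + "\n"
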