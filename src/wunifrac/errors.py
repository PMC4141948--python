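"""Exception hierarchy.

All package-specific failures derive from :class:`WunifracError` so callers
(and the CLI) can distinguish data problems (exit code 2) from usage errors
(exit code 1).
"""


class WunifracError(Exception):
    """Base class for all errors raised by this package."""


class TreeFormatError(WunifracError, ValueError):
    """Malformed tree structure or Newick text.

    Parameters
    ----------
    message : str
    offset : int, optional
        0-based character offset into the Newick source where the problem
        was detected.
    """

    def __init__(self, message: str, offset: int | None = None):
        self.offset = offset
        if offset is not None:
            message = f"{message} (at character {offset})"
        super().__init__(message)


class EnvFormatError(WunifracError, ValueError):
    """Malformed environment-file text.

    Carries the 1-based line number where the problem was found.
    """

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class JoinError(WunifracError, ValueError):
    """Leaf names in the tree and the environment table do not match up."""


class InvalidCountError(WunifracError, ValueError):
    """Abundance count is not a positive integer."""


class DegenerateInputError(WunifracError, ValueError):
    """Input is structurally valid but the requested quantity is undefined
    (e.g. normalization denominator of zero because every individual sits
    at depth 0)."""


class EnumerationCapError(WunifracError, ValueError):
    """The number of distinct label assignments exceeds the enumeration cap;
    use the Monte-Carlo estimator instead."""


class ContractError(WunifracError, ValueError):
    """An operation was called on data violating its precondition
    (e.g. expanded-semantics shuffling on a tree not in expanded form)."""
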