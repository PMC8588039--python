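"""Exception hierarchy shared across the package."""


class HvlForestError(Exception):
    """Base class for all package-specific errors."""


class InputError(HvlForestError, ValueError):
    """Raised when user-supplied data violates an operation's contract."""


class LeafContractError(HvlForestError):
    """A terminal leaf holds fewer member outputs than required (min two)."""

    def __init__(self, tree: int, leaf: int, count: int):
        self.tree = tree
        self.leaf = leaf
        self.count = count
        super().__init__(
            f"leaf {leaf} of tree {tree} has only {count} member output(s); "
            "at least 2 are required to form a standard deviation"
        )


class ConsistencyError(HvlForestError):
    """A leaf assignment refers to a (tree, leaf) absent from the leaf table."""

    def __init__(self, tree: int, leaf: int):
        self.tree = tree
        self.leaf = leaf
        super().__init__(f"no leaf-table record for leaf {leaf} of tree {tree}")


class CapabilityError(HvlForestError):
    """A required optional backend (e.g. chemistry toolkit) is unavailable."""
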