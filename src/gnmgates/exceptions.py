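"""Exception hierarchy.

Errors are grouped so the command line can map them onto distinct exit
codes: input/output problems, validation of user-supplied values, and
numerical degeneracies detected during the computation.
"""


class GNMGatesError(Exception):
    """Base class for all package errors."""


class InputError(GNMGatesError):
    """A file could not be read or written."""


class ChainNotFoundError(InputError):
    """A requested chain is absent from the structure."""

    def __init__(self, missing, available):
        self.missing = sorted(missing)
        self.available = sorted(available)
        super().__init__(
            f"chain(s) not found: {', '.join(self.missing)}; "
            f"available chains: {', '.join(self.available) or '(none)'}"
        )


class StructureTooSmallError(InputError):
    """Fewer than two alpha-carbon records survive filtering."""


class ValidationError(GNMGatesError):
    """An argument violates the operation's contract."""


class NumericalError(GNMGatesError):
    """A numerically degenerate situation that has no meaningful result."""
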