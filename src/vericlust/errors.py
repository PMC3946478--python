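"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`VericlustError`, so callers (and the CLI) can distinguish user-input
problems from genuine bugs.
"""


class VericlustError(Exception):
    """Base class for all errors raised by vericlust."""


class InputError(VericlustError, ValueError):
    """Invalid user-supplied data (shape mismatch, bad parameter, ...)."""


class TraceSchemaError(VericlustError, ValueError):
    """An iteration-trace document violates the trace JSON schema.

    The message names the offending field and, where applicable, the
    zero-based record index.
    """


class CTLSyntaxError(VericlustError, ValueError):
    """A CTL formula string failed to parse; carries the character position."""

    def __init__(self, message: str, position: int | None = None):
        self.position = position
        if position is not None:
            message = f"{message} (at position {position})"
        super().__init__(message)


class CTLError(VericlustError, ValueError):
    """Semantic model-checking error (unknown atom, non-total system)."""


class StateBoundError(VericlustError, RuntimeError):
    """Unfolding a program graph exceeded the configured state cap."""
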