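"""Exception hierarchy shared by all cleavekit modules."""


class CleavekitError(Exception):
    """Base class for all cleavekit errors."""


class FormatError(CleavekitError):
    """Input file malformed (missing column, bad value, unparsable field)."""


class ValidationError(CleavekitError):
    """Data violates a lineage/record invariant (names embryo and cell)."""


class StructureError(CleavekitError):
    """Lineage tree violates the binary-division structure."""


class ArgumentError(CleavekitError, ValueError):
    """Invalid argument to an analysis operation."""
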