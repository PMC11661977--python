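"""Exception hierarchy shared across the package."""


class GlycoplotError(Exception):
    """Base class for all package-specific errors."""


class FormatError(GlycoplotError, ValueError):
    """Malformed text input (formula, composition, config line)."""


class ValidationError(GlycoplotError, ValueError):
    """Semantically invalid in-memory object or argument."""


class SchemaError(GlycoplotError, ValueError):
    """Tabular input missing mandatory columns."""


class UnsupportedStructureError(GlycoplotError, ValueError):
    """Glycan encoding outside the supported subset (repeats, ambiguity, cycles)."""
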