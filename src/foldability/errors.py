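"""Exception hierarchy shared across the package."""


class FoldabilityError(Exception):
    """Base class for all package errors."""


class ValidationError(FoldabilityError):
    """Input violates a documented contract (bad residue letter, range, ...)."""


class FormatError(FoldabilityError):
    """A file could not be parsed under the expected dialect."""


class EmptyStructureError(FoldabilityError):
    """A structure selection produced no atoms."""


class DegenerateGeometryError(FoldabilityError):
    """Too few or geometrically degenerate points for a rigid superposition."""
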