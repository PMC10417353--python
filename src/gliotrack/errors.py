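"""Package exception hierarchy."""


class GliotrackError(Exception):
    """Base class for all package errors."""


class ParameterError(GliotrackError, ValueError):
    """A parameter violates its documented constraints."""


class ValidationError(GliotrackError, ValueError):
    """Inputs are mutually inconsistent (shape/grid/binary mismatches)."""


class DegenerateInputError(GliotrackError, ValueError):
    """Input is valid in form but degenerate for the requested operation."""
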