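"""Exception hierarchy shared across the package."""


class BioESNError(Exception):
    """Base class for all package-specific errors."""


class FormatError(BioESNError, ValueError):
    """A file could not be parsed as a connectome (non-square, empty, malformed)."""


class ValidationError(BioESNError, ValueError):
    """Data violated an invariant (negative weight, shape mismatch, bad parameter)."""


class DegenerateInputError(BioESNError, ValueError):
    """Input is structurally valid but degenerate for the requested operation
    (no links, zero spectral radius, too few time steps, ...)."""
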