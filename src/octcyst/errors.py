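"""Exception types shared across the package."""


class ParameterError(ValueError):
    """An argument violates a documented precondition (invalid spec, bad range)."""


class DimensionError(ValueError):
    """Array shapes are incompatible with the requested operation."""


class DegenerateError(ValueError):
    """Input is degenerate for the operation (single class, all-zero vector, ...)."""


class DecodingError(RuntimeError):
    """Viterbi decoding failed (all path scores impossible)."""


class ManifestError(ValueError):
    """A manifest CSV is malformed or inconsistent."""


class RegistryError(KeyError):
    """Requested feature method is not registered."""
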