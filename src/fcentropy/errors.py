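"""Exception types shared across the package."""


class FCEntropyError(ValueError):
    """Base class for all package-raised errors."""


class FormatError(FCEntropyError):
    """A file could not be parsed into the expected shape."""


class ValidationError(FCEntropyError):
    """Parsed data violates a structural invariant (symmetry, sign, range...)."""


class ParameterError(FCEntropyError):
    """An argument is outside its admissible set."""
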