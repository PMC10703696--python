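"""Exception types shared across the package."""


class FormatError(ValueError):
    """A text input file violates its expected format."""


class ConfigurationError(ValueError):
    """An analysis configuration is internally inconsistent."""


class GenomeExhaustedError(RuntimeError):
    """No admissible placement exists for a requested random region."""


class FitError(RuntimeError):
    """A model fit failed to converge or is degenerate."""
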