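"""Package-level exception types."""


class ConfigurationError(ValueError):
    """Raised when a spec/config object fails validation."""


class InputError(ValueError):
    """Raised when runtime inputs (arrays, shapes, indices) are invalid."""


class NumericalError(ArithmeticError):
    """Raised when a computation produces non-finite values."""
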