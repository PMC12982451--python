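"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Raised when constraints or configuration make a request infeasible."""


class ValidationError(ValueError):
    """Raised when a stimulus, geometry, or argument violates its invariants."""
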