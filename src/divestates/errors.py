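"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """A configuration object violates one of its invariants."""


class InputError(ValueError):
    """Input data violates a precondition (unsorted, overlapping, ...)."""


class DataError(ValueError):
    """Data is internally inconsistent (e.g. overlapping dives)."""


class ValidationError(RuntimeError):
    """The resolution-validation comparison cannot be carried out."""
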