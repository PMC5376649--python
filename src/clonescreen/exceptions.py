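"""Exception hierarchy shared across the package."""


class CloneScreenError(Exception):
    """Base class for all package-specific errors."""


class FormatError(CloneScreenError):
    """A file does not conform to the expected layout (missing columns, bad header)."""


class ValidationError(CloneScreenError):
    """Data violates an invariant (duplicate ids, malformed barcode, negative count)."""


class ConfigurationError(CloneScreenError):
    """An analysis was configured inconsistently (unpaired samples, bad parameters)."""
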