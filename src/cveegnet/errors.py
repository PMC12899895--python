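"""Exception types shared across the package."""


class DimensionError(ValueError):
    """Array shapes incompatible with the requested operation."""


class ConfigurationError(ValueError):
    """Inconsistent layer/model/generator configuration."""


class DegenerateBatchError(ValueError):
    """Batch statistics requested on a batch too small to define them."""


class ProtocolError(ValueError):
    """Violation of the trial-level train/test protocol."""


class FormatError(KeyError):
    """A recording container is missing an expected key."""


class ValidationError(ValueError):
    """Loaded data contradicts the declared layout (channels, rate, ...)."""
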