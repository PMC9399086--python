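"""Exception types shared across the package."""


class ConfigurationError(ValueError):
    """Invalid design, population, or run configuration."""


class DesignError(ValueError):
    """A session or choice set violates the task structure."""


class CodingError(ValueError):
    """Unknown condition/group label in indicator coding."""


class DataValidationError(ValueError):
    """A trial table fails schema or value checks."""


class InitializationError(RuntimeError):
    """The sampler could not find a finite starting point."""


class AlignmentError(ValueError):
    """Truth and posterior parameter registries do not match."""
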