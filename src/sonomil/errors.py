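"""Exception types shared across the package."""


class SonomilError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(SonomilError, ValueError):
    """An invalid configuration value; the message names the offending field."""


class DataIntegrityError(SonomilError, ValueError):
    """Input data violates a structural contract (e.g. conflicting bag labels)."""


class CapabilityError(SonomilError, RuntimeError):
    """A requested capability (e.g. a pretrained backbone) is unavailable."""


class DivergenceError(SonomilError, RuntimeError):
    """Training produced a non-finite loss; message carries the epoch index."""


class StratificationError(SonomilError, ValueError):
    """A stratified split was requested but a class has too few bags."""


class EmptyBagError(SonomilError, ValueError):
    """An operation that requires at least one instance received an empty bag."""
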