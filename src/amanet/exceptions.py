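"""Exception hierarchy shared across the package."""


class AmanetError(Exception):
    """Base class for all package-specific errors."""


class SpecError(AmanetError, ValueError):
    """A synthetic-data or run specification violates its invariants."""


class ConfigurationError(AmanetError, ValueError):
    """A model/augmentation configuration is internally inconsistent."""


class SegmentationError(AmanetError, ValueError):
    """Sliding-window segmentation is impossible for the given lengths."""


class DimensionError(AmanetError, ValueError):
    """An array does not have the shape an operation requires."""


class InsufficientDataError(AmanetError, ValueError):
    """Not enough samples per class to fit an estimator."""


class NumericalError(AmanetError, ArithmeticError):
    """A numerical routine failed (singular matrix, NaN loss, ...)."""


class SchemaError(AmanetError, KeyError):
    """A data container is missing a required array or attribute."""
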