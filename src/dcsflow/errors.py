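"""Exception hierarchy for dcsflow."""


class DcsflowError(Exception):
    """Base class for all dcsflow errors."""


class InvalidParameterError(DcsflowError, ValueError):
    """A physical or configuration parameter violates its domain."""


class NumericalRangeError(DcsflowError, FloatingPointError):
    """An intermediate quantity left the representable floating-point range."""


class ConvergenceError(DcsflowError, RuntimeError):
    """A quadrature or iterative solve failed its convergence check."""


class DegenerateCurveError(DcsflowError, ValueError):
    """A correlation curve carries no usable decay information."""


class DimensionError(DcsflowError, ValueError):
    """Array shapes are inconsistent with the model dimensions."""


class FormatError(DcsflowError, ValueError):
    """A serialized artifact (dataset, curve, model) is malformed."""


class InvalidConfigError(DcsflowError, ValueError):
    """A run configuration contains unknown or invalid entries."""
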