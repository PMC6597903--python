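"""Exception types shared across the pipeline stages."""


class DualomicsError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(DualomicsError):
    """Invalid simulation or pipeline configuration."""


class ConsistencyError(DualomicsError):
    """Inputs that should describe the same features/samples disagree."""


class EstimationError(DualomicsError):
    """A statistical estimator cannot be computed from the given data."""


class ValidationError(DualomicsError):
    """A value violates a documented precondition (e.g. p outside [0, 1])."""


class ParseError(DualomicsError):
    """A file does not conform to its declared format."""
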