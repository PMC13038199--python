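"""Exception hierarchy shared across pipeline stages."""


class PipelineError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(PipelineError, ValueError):
    """Invalid parameter or configuration value."""


class ValidationError(PipelineError, ValueError):
    """Input values violate a documented contract (e.g. p outside [0, 1])."""


class StructuralError(PipelineError, ValueError):
    """Input has the wrong shape/pairing structure (e.g. missing control replicate)."""


class DataError(PipelineError, ValueError):
    """Input values make an operation undefined (e.g. a column with no positive entry)."""


class CoverageError(PipelineError, ValueError):
    """Too few of the requested identifiers are present in the data."""


class EstimationError(PipelineError, ValueError):
    """Not enough usable data to estimate hyperparameters."""


class RegionError(PipelineError, ValueError):
    """A requested sequence region is absent or too short."""
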