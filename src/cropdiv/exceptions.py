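"""Exception hierarchy shared across the package."""


class CropDivError(Exception):
    """Base class for all package-specific errors."""


class ConfigurationError(CropDivError):
    """A configuration value (column mapping, valid-country set, ...) is unusable."""


class EmptyInputError(CropDivError):
    """An operation received or produced no usable records."""


class ValidationError(CropDivError):
    """Input data violates a precondition (negative areas, unordered years, ...)."""


class FitNotConverged(CropDivError):
    """A model fit did not converge; downstream consumers must skip it explicitly."""


class PipelineError(CropDivError):
    """A pipeline stage failed; carries the stage name and the underlying cause."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
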