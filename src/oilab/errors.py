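"""Exception hierarchy for the oilab pipeline."""


class OilabError(Exception):
    """Base class for all package errors."""


class ConfigurationError(OilabError, ValueError):
    """A configuration object violates its invariants."""


class InputError(OilabError, ValueError):
    """Invalid arguments to an operation (bad indices, duplicate ids, ...)."""


class SchemaError(OilabError, ValueError):
    """A table does not conform to one of the CSV schemas."""


class EstimationError(OilabError, ValueError):
    """An estimator cannot be computed from the data it was given."""


class DataError(OilabError, ValueError):
    """Data are structurally valid but unusable (zero variance, missing subject, ...)."""


class IngestionError(OilabError, ValueError):
    """External data could not be mapped into the internal schemas."""


class PipelineError(OilabError, RuntimeError):
    """A pipeline stage failed; carries the stage name and offending artifact."""

    def __init__(self, stage: str, message: str, artifact: str | None = None):
        self.stage = stage
        self.artifact = artifact
        suffix = f" [artifact: {artifact}]" if artifact else ""
        super().__init__(f"stage '{stage}': {message}{suffix}")
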