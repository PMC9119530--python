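"""Package exception hierarchy."""


class ChemovarError(Exception):
    """Base class for all package errors."""


class ConfigError(ChemovarError):
    """Invalid configuration value; the message names the offending field."""


class SchemaError(ChemovarError):
    """Input table is missing required columns or violates the schema."""


class UnitError(ChemovarError):
    """Unknown or unsupported measurement unit."""


class PanelError(ChemovarError):
    """Compound-panel harmonization failure (e.g. empty intersection)."""


class PipelineStageError(ChemovarError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
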