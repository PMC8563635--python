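"""Exception hierarchy for the burden-estimation pipeline."""


class T1DBurdenError(Exception):
    """Base class for all package errors."""


class FormatError(T1DBurdenError):
    """A file does not conform to the expected layout (e.g. missing CSV column)."""


class ValidationError(T1DBurdenError):
    """A record or table violates a model invariant."""


class ReferenceError_(T1DBurdenError):
    """A donor/foreign-key reference cannot be resolved."""


class ChainingError(T1DBurdenError):
    """A donor country is itself extrapolated; donor chains are refused."""


class GenerationError(T1DBurdenError):
    """The synthetic generator cannot satisfy its constraints."""


class CalibrationError(T1DBurdenError):
    """A survival schedule cannot be calibrated to the requested expectancy."""


class StructuralError(T1DBurdenError):
    """Band structures of two inputs do not match."""


class ScenarioError(T1DBurdenError):
    """A sensitivity-scenario specification is invalid or conflicting."""


class PipelineError(T1DBurdenError):
    """A pipeline stage failed; carries stage and country context."""

    def __init__(self, stage: str, message: str, country_id: str | None = None):
        self.stage = stage
        self.country_id = country_id
        where = f"stage '{stage}'" + (f", country '{country_id}'" if country_id else "")
        super().__init__(f"{where}: {message}")
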