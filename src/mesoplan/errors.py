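"""Exception hierarchy for mesoplan.

All library errors derive from :class:`MesoplanError` so callers can catch
one base class; each subclass also derives from the closest builtin so that
generic ``except ValueError`` handling keeps working.
"""


class MesoplanError(Exception):
    """Base class for all mesoplan errors."""


class InvalidSpecificationError(MesoplanError, ValueError):
    """An experiment descriptor violates its physical constraints
    (non-positive volume, dilution factor < 1, negative mass, ...)."""


class UnderDeterminedError(MesoplanError, ValueError):
    """A calibration problem has no unique solution (e.g. all
    observations share the same dilution factor)."""


class TargetUnreachableError(MesoplanError, ValueError):
    """A requested hydration level cannot be reached with any dilution
    factor >= 1 for the given screen volume and monoolein mass."""


class InsufficientDataError(MesoplanError, ValueError):
    """Too few replicates / resamples for the requested statistic."""


class WorklistParseError(MesoplanError, ValueError):
    """A worklist CSV could not be parsed; carries the offending row."""

    def __init__(self, message: str, row: int | None = None):
        self.row = row
        if row is not None:
            message = f"row {row}: {message}"
        super().__init__(message)


class PlateValidationError(MesoplanError, ValueError):
    """A plate layout is internally inconsistent; message lists wells."""


class PipelineError(MesoplanError, RuntimeError):
    """A pipeline stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage '{stage}': {message}")
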