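"""Exception hierarchy shared across the pipeline."""


class CyclogaitError(Exception):
    """Base class for all package errors."""


class InputError(CyclogaitError):
    """Invalid user-supplied data (negative pressures, unknown sensors, ...)."""


class ConfigError(CyclogaitError):
    """Missing or inconsistent configuration (insole lengths, paths, ...)."""


class ParseError(CyclogaitError):
    """Malformed input file; carries a line number where known."""

    def __init__(self, message: str, line: int | None = None):
        self.line = line
        if line is not None:
            message = f"{message} (line {line})"
        super().__init__(message)


class MarkerError(CyclogaitError):
    """A stride's markers could not be extracted (short stance, no COP)."""


class StepValidationError(CyclogaitError):
    """Step validation rejected every gait cycle, or too few to validate."""


class ClusteringError(CyclogaitError):
    """A marker cluster is missing or too small for statistics."""


class DegenerateROCError(CyclogaitError):
    """ROC sweep impossible: all pooled scores identical."""


class CalibrationError(CyclogaitError):
    """Balance-index scale calibration failed (degenerate separation)."""


class GenerationError(CyclogaitError):
    """Synthetic-data generation failed (invalid template or spec)."""
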