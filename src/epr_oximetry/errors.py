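"""Exception types shared across the package."""


class ValidationError(ValueError):
    """An input object or parameter violates a documented invariant."""


class OutOfSweepWindowError(ValidationError):
    """A probe's resonance field lies outside the swept field window."""


class ParseError(ValueError):
    """A spectrum file could not be parsed.

    Carries the 1-based line number at which parsing failed.
    """

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"{message} (line {line_number})"
        super().__init__(message)


class CalibrationError(ValueError):
    """A calibration curve is invalid or cannot be fitted."""


class AnalysisQualityError(RuntimeError):
    """Analysis produced no usable result (e.g. every spectrum flagged)."""
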