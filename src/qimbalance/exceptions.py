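"""Exception types shared across the package."""


class QimbalanceError(Exception):
    """Base class for package-specific errors."""


class DegenerateInputError(QimbalanceError, ValueError):
    """Input is structurally valid but statistically degenerate.

    Raised instead of silently returning 0 when, e.g., all P_low values are
    identical or a group has too few samples for a correlation: a zero QI on
    such input would misclassify a broken dataset as quality-balanced.
    """


class CalibrationError(QimbalanceError, ValueError):
    """A requested simulation target cannot be reached.

    Carries the achievable bound so callers can adjust their request.
    """

    def __init__(self, message: str, achievable: float | None = None):
        super().__init__(message)
        self.achievable = achievable


class PipelineError(QimbalanceError, RuntimeError):
    """A pipeline stage failed; the message names the stage and input."""
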