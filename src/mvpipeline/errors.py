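"""Exception types shared across the pipeline."""


class MVError(Exception):
    """Base class for all pipeline errors."""


class ValidationError(MVError, ValueError):
    """Invalid input value; the message names the offending field."""

    def __init__(self, message: str, field: str | None = None):
        super().__init__(message)
        self.field = field


class DegenerateInputError(MVError, ValueError):
    """Input is structurally valid but statistically degenerate
    (single-class labels, zero-variance scores, empty cohort)."""
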