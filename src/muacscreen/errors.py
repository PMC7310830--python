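"""Exception hierarchy shared across the pipeline."""


class MuacScreenError(Exception):
    """Base class for all errors raised by this package."""


class ValidationError(MuacScreenError, ValueError):
    """Input failed a precondition (wrong shape, out-of-range value...)."""


class FlaggedRecordError(ValidationError):
    """A subject's replicate measurements disagree beyond the repeat
    threshold and no repeat pair is available; carries the subject id."""

    def __init__(self, message: str, subject_id=None):
        super().__init__(message)
        self.subject_id = subject_id


class OneClassError(ValidationError):
    """An operation requiring both diseased and non-diseased subjects
    received a single-class sample."""


class SeparationError(MuacScreenError):
    """Logistic maximum likelihood does not exist because the marker
    (quasi-)perfectly separates the outcome classes."""


class UndefinedMetricError(MuacScreenError):
    """A metric's denominator (or variance) is zero so no finite
    estimate or interval exists."""
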