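"""Exception hierarchy for d50track."""


class D50TrackError(Exception):
    """Base class for all d50track errors."""


class InsufficientDataError(D50TrackError, ValueError):
    """Fewer observations than the model minimum (two ALSFRS-R assessments)."""


class IllPosedFitError(D50TrackError, ValueError):
    """The trajectory carries no decline signal (e.g. all scores at 48)."""


class InvalidArgumentError(D50TrackError, ValueError):
    """An argument violates a documented precondition."""


class InvalidDesignError(D50TrackError, ValueError):
    """A statistical comparison was requested on a degenerate design."""


class SchemaError(D50TrackError, ValueError):
    """Input table fails validation; carries row-level messages."""

    def __init__(self, message, row_errors=None):
        self.row_errors = list(row_errors or [])
        if self.row_errors:
            message = message + "\n" + "\n".join(self.row_errors)
        super().__init__(message)


class ConfigError(D50TrackError, ValueError):
    """A simulation or pipeline configuration violates its invariants."""


class PreOnsetLossWarning(UserWarning):
    """Fitted curve implies substantial functional loss before symptom onset."""
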