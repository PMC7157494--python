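"""Exception hierarchy shared across the pipeline."""


class MrtModError(Exception):
    """Base class for all package errors."""


class ConfigurationError(MrtModError):
    """Invalid design, truth, or analysis configuration."""


class DataError(MrtModError):
    """Input data violate a documented precondition (bad labels, negatives under sqrt, ...)."""


class IntegrityError(DataError):
    """Structural inconsistency in a panel (duplicate keys, week/day mismatch)."""


class SchemaError(DataError):
    """A required column is absent or has the wrong name."""


class RankDeficiencyError(MrtModError):
    """Normal equations are singular; carries the names of collinear columns."""

    def __init__(self, columns):
        self.columns = list(columns)
        super().__init__(
            "design matrix is rank deficient; collinear columns: "
            + ", ".join(self.columns)
        )


class InferenceError(MrtModError):
    """Inference is impossible (e.g. a single cluster)."""


class UsageError(MrtModError):
    """API misuse: unknown coefficient selector, mismatched lengths, ..."""
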