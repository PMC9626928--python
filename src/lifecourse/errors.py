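"""Exception hierarchy shared across the pipeline stages."""


class LifecourseError(Exception):
    """Base class for all package-specific errors."""


class SchemaMismatchError(LifecourseError):
    """A deficit schema references source variables absent from the data."""


class DegenerateDecadeError(LifecourseError):
    """A decade's ward deprivation values have zero spread and cannot be z-scored."""


class DegenerateOutcomeError(LifecourseError):
    """The outcome vector is constant; no selection path exists."""


class RankDeficiencyError(LifecourseError):
    """A design or confounder matrix is rank deficient; carries aliased column names."""

    def __init__(self, message: str, aliased: list[str] | None = None):
        super().__init__(message)
        self.aliased = aliased or []


class ConvergenceError(LifecourseError):
    """An iterative fit failed to converge; carries optimizer diagnostics."""


class SeparationError(LifecourseError):
    """Perfect separation in a logistic fit."""


class EmptyStratumError(LifecourseError):
    """A requested analysis stratum contains no rows."""
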