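"""Exception hierarchy for prodshift.

Every error raised by the package derives from :class:`ProdshiftError`, so
callers can catch one type at a pipeline boundary.  Subclasses mark the stage
that failed (I/O schema, covariate construction, fitting, selection).
"""


class ProdshiftError(Exception):
    """Base class for all prodshift errors."""


class SchemaError(ProdshiftError):
    """An input file is missing a required column or has an unparseable field."""


class ValidationError(ProdshiftError):
    """A parsed table violates a structural invariant (e.g. duplicate years)."""


class EmptySeriesError(ProdshiftError):
    """No usable records remain after filtering."""


class AlignmentError(ProdshiftError):
    """Response and covariate year sets do not overlap."""


class CovariateError(ProdshiftError):
    """A covariate cannot be constructed as requested."""


class GapError(CovariateError):
    """A monthly series is missing a month inside a requested window."""


class DegenerateCovariateError(CovariateError):
    """A covariate has zero variance over the fit years and cannot be z-scored."""


class InsufficientDataError(ProdshiftError):
    """Too few observations to estimate the requested parameters."""


class SingularDesignError(ProdshiftError):
    """The design matrix is rank deficient (e.g. covariate collinear with spawners)."""


class DegenerateLikelihoodError(ProdshiftError):
    """The residual standard deviation is zero; the Gaussian likelihood diverges."""


class CorrectionUndefinedError(ProdshiftError):
    """AICc small-sample correction undefined because n <= k + 1."""


class IncomparableModelsError(ProdshiftError):
    """Candidate fits use different data, so information criteria cannot be compared."""


class SuiteError(ProdshiftError):
    """A hypothesis-suite candidate references an unavailable covariate."""


class SimulationConfigError(ProdshiftError):
    """A synthetic-data configuration is invalid (nonstationary AR(1), bad spawners)."""


class EffectError(ProdshiftError):
    """An effect-size or diagnostic computation is undefined for the given inputs."""
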