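"""Exception hierarchy for the heatcase pipeline.

Every stage raises a subclass of :class:`HeatcaseError` so that the
orchestrator can attribute a failure to a stage without string matching.
"""


class HeatcaseError(Exception):
    """Base class for all package errors."""


class ConfigurationError(HeatcaseError):
    """Invalid or internally inconsistent configuration."""


class GenerationError(HeatcaseError):
    """The synthetic generator produced (or would produce) invalid data."""


class EmptyCohortError(HeatcaseError):
    """All records were removed by the exclusion cascade."""


class LinkageError(HeatcaseError):
    """Exposure or confounder linkage failed (missing cell/day, point outside extent)."""


class DesignError(HeatcaseError):
    """Case-crossover stratum or design-matrix construction failed."""


class DataError(HeatcaseError):
    """A design matrix violates a structural requirement (e.g. not one case per stratum)."""


class ConvergenceError(HeatcaseError):
    """Posterior mode finding did not converge."""
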