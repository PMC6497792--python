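"""Exception hierarchy for phenoscreen.

Every stage raises a subclass of :class:`PhenoscreenError` so callers can
catch pipeline failures without masking programming errors.
"""


class PhenoscreenError(Exception):
    """Base class for all phenoscreen errors."""


class SchemaError(PhenoscreenError):
    """Input table is missing required columns or has unusable labels."""


class DuplicateRecordError(PhenoscreenError):
    """Two records share the same (genotype, environment, replicate, trait, day) key."""


class EmptyTableError(PhenoscreenError):
    """An operation that needs data received an empty table."""


class UnbalancedDesignError(PhenoscreenError):
    """Balanced ANOVA requested on a design that cannot be balanced."""


class InsufficientReplicationError(PhenoscreenError):
    """Fewer than two replicates per cell after the missing-data policy."""


class DesignMismatchError(PhenoscreenError):
    """Supplied design constants (s, r) disagree with the ANOVA degrees of freedom."""


class UndefinedBaselineError(PhenoscreenError):
    """A ratio or percent-change baseline is zero or non-positive."""


class InvalidFluorescenceError(PhenoscreenError):
    """Fluorescence inputs violate 0 <= F_ground <= F_max, F_max > 0."""


class InvalidProteinError(PhenoscreenError):
    """Protein amount for fluorescence normalization must be positive."""


class EmptyGroupError(PhenoscreenError):
    """ROC comparison received an empty control or stressed group."""


class UnknownTraitError(PhenoscreenError):
    """A requested trait is absent from the table."""


class WeightError(PhenoscreenError):
    """Composite-score weights are negative or do not sum to one."""


class CoverageError(PhenoscreenError):
    """Score inputs do not cover the same trait set."""


class ParameterError(PhenoscreenError):
    """A numeric parameter is outside its valid range."""


class NormalizationError(PhenoscreenError):
    """A qPCR cell lacks the housekeeping-gene measurement."""


class CalibratorError(PhenoscreenError):
    """A qPCR cell lacks its untreated calibrator."""


class CatalogueError(PhenoscreenError):
    """Trait catalogue is malformed (e.g. duplicate trait names)."""
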