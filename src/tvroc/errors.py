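"""Exception hierarchy for the tvroc pipeline.

Every data-quality failure is loud: the readers and estimators raise rather
than silently dropping rows, and exclusions that *are* allowed (missing
marker values at a risk-set time) are counted and reported by the callers.
"""


class TvrocError(Exception):
    """Base class for all package errors."""


class SchemaError(TvrocError):
    """An input table is missing a required column."""


class ParseError(TvrocError):
    """A cell could not be parsed (non-numeric value/day); carries row context."""


class ReferentialError(TvrocError):
    """Cross-table integrity violation: orphan measurement or observation after exit."""


class ConfigurationError(TvrocError):
    """Unknown marker, missing marker config, or an invalid analysis option."""


class UndefinedStatisticError(TvrocError):
    """A statistic is undefined on the given data (e.g. an empty case or
    control group); bootstrap resamples catching this count it as failed."""


class UndefinedAUCError(UndefinedStatisticError):
    """AUC requested with an empty case or control group."""


class CalibrationError(TvrocError):
    """The synthetic-cohort mortality calibration could not reach the target."""


class DegenerateBootstrapError(TvrocError):
    """The statistic was undefined on more than half of the bootstrap resamples."""
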