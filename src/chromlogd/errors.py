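"""Exception hierarchy for the chromlogd pipeline.

Every contracted failure mode raises a subclass of :class:`ChromlogdError`,
so callers can catch pipeline failures without masking programming errors.
"""


class ChromlogdError(Exception):
    """Base class for all chromlogd domain errors."""


class InvalidArgumentError(ChromlogdError, ValueError):
    """A numeric argument was non-finite or outside its admissible range."""


class NotComputableError(ChromlogdError):
    """A quantity cannot be computed because a required input is missing
    (e.g. logD of a sample compound without a literature logP)."""


class DegenerateAnchorError(ChromlogdError):
    """The two observed anchor times coincide; the retention-time
    correction map is undefined."""


class NonRetainedSoluteError(ChromlogdError):
    """Retention time at or before the dead time: the retention factor is
    not positive and its logarithm undefined."""


class InsufficientDataError(ChromlogdError):
    """Fewer data points (or compounds) than the fit requires."""


class DegenerateDesignError(ChromlogdError):
    """The regression design has no variance in a predictor."""


class CollinearityError(ChromlogdError):
    """Rank-deficient regression design.

    Attributes
    ----------
    terms : tuple of str
        Names of the offending design columns.
    """

    def __init__(self, terms):
        self.terms = tuple(terms)
        super().__init__(f"collinear design; offending terms: {', '.join(self.terms)}")


class ParseError(ChromlogdError):
    """A CSV cell could not be parsed; the message carries row and column."""


class DuplicateRecordError(ChromlogdError):
    """Two input records share an identifier that must be unique."""


class InvalidConfigError(ChromlogdError, ValueError):
    """A generator or pipeline configuration violates its invariants."""
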