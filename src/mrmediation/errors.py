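"""Exception hierarchy for the MR pipeline.

Every stage raises a subclass of :class:`MRError` so callers (and the
pipeline driver) can attribute failures to a stage without string matching.
"""


class MRError(Exception):
    """Base class for all package errors."""


class SumstatsFormatError(MRError):
    """A summary-statistics or LD file does not have the expected shape."""


class SumstatsValidationError(MRError):
    """A row or matrix entry violates a domain invariant."""


class SnpLookupError(MRError):
    """A SNP required by an operation is absent from its input."""


class NoInstrumentsError(MRError):
    """Instrument selection produced an empty set."""


class InsufficientInstrumentsError(MRError):
    """An estimator was given fewer SNPs than its minimum."""


class UndefinedProportionError(MRError):
    """Proportion mediated is undefined because the total effect is zero."""


class ParameterizationError(MRError):
    """A simulation configuration is internally infeasible."""


class StageError(MRError):
    """Wraps an error raised inside a named pipeline stage."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        self.cause = cause
        super().__init__(f"stage '{stage}' failed: {cause}")
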