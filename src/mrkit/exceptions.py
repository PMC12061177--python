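"""Exception hierarchy shared across mrkit modules."""


class MRKitError(Exception):
    """Base class for all mrkit errors."""


class ColumnMappingError(MRKitError):
    """A mandatory summary-statistic column is absent from the input file."""


class EmptyInputError(MRKitError):
    """An input file yielded zero valid SNP records."""


class EmptyInstrumentError(MRKitError):
    """No instruments survived harmonization/filtering.

    Carries the exclusion log so callers can report why every SNP was lost.
    """

    def __init__(self, message: str, exclusion_log=None):
        super().__init__(message)
        self.exclusion_log = list(exclusion_log or [])


class InsufficientInstrumentsError(MRKitError):
    """An estimator was given fewer instruments than it requires."""


class EstimationError(MRKitError):
    """An estimator failed to produce a usable estimate."""
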