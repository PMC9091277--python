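"""Exception hierarchy for the selv toolkit."""


class SelvError(Exception):
    """Base class for all toolkit errors."""


class DomainError(SelvError, ValueError):
    """A numeric input lies outside its mathematical domain."""


class DuplicateRecordError(SelvError, ValueError):
    """The same (contig, position, ref, alt, population) key was seen twice."""


class BuildMismatchError(SelvError, ValueError):
    """Query variants and a locus table carry different genome-build tags."""


class UnknownStratumError(SelvError, KeyError):
    """A population stratum was requested that the table does not contain."""


class SingleClassError(SelvError, ValueError):
    """A metric requiring both classes received labels of only one class."""


class DegenerateComparisonError(SelvError, ValueError):
    """An AUC comparison has zero variance but unequal AUCs."""


class MissingCalibrationError(SelvError, KeyError):
    """Variants carry genomic contexts with no available calibration."""


class FormatError(SelvError, ValueError):
    """An input file violates its declared format."""
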