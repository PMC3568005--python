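"""Exception hierarchy for mixture-QSPR pipelines.

Every error raised on bad user input derives from :class:`MixQSPRError` so
callers (and the CLI) can catch one base class.
"""


class MixQSPRError(Exception):
    """Base class for all package errors."""


class StructureError(MixQSPRError):
    """A chemical structure could not be parsed or canonicalized."""


class DomainError(MixQSPRError):
    """A numeric argument is outside its admissible range (e.g. molar fraction)."""


class IncompleteRecordError(MixQSPRError):
    """A mixture row lacks a mandatory field (e.g. second component with x1 < 1)."""


class SchemaError(MixQSPRError):
    """An input table is missing a mandatory column."""


class AugmentationError(MixQSPRError):
    """Pure-compound augmentation could not supply values for some compounds."""


class CoverageError(MixQSPRError):
    """A descriptor matrix does not cover every compound of a dataset."""


class BackendError(MixQSPRError):
    """A descriptor backend failed on one or more compounds."""


class SelectionError(MixQSPRError):
    """A requested descriptor name is absent from the matrix."""


class ConfigError(MixQSPRError):
    """Inconsistent configuration (unknown method, k > n, ...)."""


class SplitError(MixQSPRError):
    """A fold plan satisfying the protocol guarantee could not be built."""


class DimensionError(MixQSPRError):
    """Component descriptor vectors have mismatched lengths."""


class UndefinedMetricError(MixQSPRError):
    """A metric is undefined on the given inputs (constant truth, absent class)."""


class LeakageError(MixQSPRError):
    """A fold plan failed its leakage audit during cross-validation."""
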