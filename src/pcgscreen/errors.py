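"""Exception hierarchy for the screening pipeline.

Exit-code mapping used by the CLI: configuration/usage problems exit 1,
data problems exit 2.
"""


class PCGScreenError(Exception):
    """Base class for all package errors."""


class InvalidConfigError(PCGScreenError):
    """A parameter or configuration value is out of its valid range."""


class InvalidInputError(PCGScreenError):
    """An input object violates a precondition (wrong length, wrong type...)."""


class DataError(PCGScreenError):
    """Base class for problems with the data itself."""


class RecordRejectedError(DataError):
    """A recording fails an inclusion rule (e.g. shorter than the 30-s window)."""


class DegenerateSignalError(DataError):
    """A signal carries no usable information (constant samples, empty spectrum)."""


class InvalidFeatureError(DataError):
    """A computed feature is non-finite; the message names the offender."""


class DegenerateTrainingError(DataError):
    """A training partition contains a single class."""


class LeakageError(PCGScreenError):
    """A fold plan places a subject on both sides of a train/test split."""
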