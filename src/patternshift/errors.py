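"""Exception types raised across the pipeline."""


class PatternShiftError(ValueError):
    """Base class for validation and analysis errors."""


class SchemaError(PatternShiftError):
    """Questionnaire schema is inconsistent or an item is unknown."""


class SeriesError(PatternShiftError):
    """A process series violates its structural contract."""


class CategoryError(PatternShiftError):
    """A diary-category timeline violates its contract."""


class DegenerateInputError(PatternShiftError):
    """The input carries no usable signal (e.g. constant channel, empty null)."""
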