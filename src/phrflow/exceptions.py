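"""Package-wide exception types."""


class PhrflowError(Exception):
    """Base class for all phrflow errors."""


class ConfigurationError(PhrflowError):
    """A spec/config object violates its invariants (bad rule, bad rate, ...)."""


class SchemaError(PhrflowError):
    """Input table columns do not match what a fitted object expects."""


class ProtocolViolationError(PhrflowError):
    """The semi-supervised contract was broken (affected rows at fit time)."""


class TrainingDivergedError(PhrflowError):
    """Optimization produced a non-finite loss."""
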