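"""Exception hierarchy for the echokin pipeline."""


class EchokinError(Exception):
    """Base class for all echokin errors."""


class FormatError(EchokinError):
    """A file is unreadable or not in a supported format."""


class SchemaError(EchokinError):
    """A trial bundle is missing a mandatory variable or violates an invariant."""


class ValidationError(EchokinError):
    """An in-memory object violates its type invariants."""


class ParameterError(EchokinError):
    """An operation was called with out-of-range parameters."""


class InsufficientDataError(EchokinError):
    """Not enough data points to compute the requested statistic."""


class EmptyTraceError(EchokinError):
    """No valid echo could be extracted from an echogram."""


class EstimationError(EchokinError):
    """A latency estimator was given a degenerate input."""
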