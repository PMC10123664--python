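"""Exception hierarchy shared across the pipeline."""


class UltracatError(Exception):
    """Base class for all package-specific errors."""


class HierarchyFormatError(UltracatError):
    """Malformed hierarchy input (bad line, cyclic edge relation, ...)."""


class MissingNodeError(UltracatError, KeyError):
    """A synset or leaf label is absent from the hierarchy."""

    def __str__(self) -> str:  # KeyError quotes its argument; keep the message readable
        return Exception.__str__(self)


class CapacityError(UltracatError):
    """An image source or label pool cannot supply the requested quantity."""


class TaskUndefinedError(UltracatError):
    """A target or distractor label pool is empty, so the task is undefinable."""


class WeightMismatchError(UltracatError):
    """Externally supplied weights do not match the model's layer shapes."""


class AlignmentError(UltracatError):
    """Two response-record sets do not cover the same image identifiers."""


class UndefinedMetricError(UltracatError):
    """A metric is requested on an empty evaluation."""
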