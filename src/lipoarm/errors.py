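"""Exception hierarchy.

Every error raised on a documented failure path derives from
:class:`LipoarmError` so callers (and the CLI) can catch package failures
without swallowing programming errors.
"""


class LipoarmError(Exception):
    """Base class for all package errors."""


class TrajectoryFormatError(LipoarmError):
    """A trajectory file does not parse in the requested dialect."""


class SelectionError(LipoarmError):
    """An atom selection is empty, overlapping, or out of range."""


class TopologyError(LipoarmError):
    """Topology metadata is inconsistent (e.g. a hydrogen with no donor)."""


class DegenerateGeometryError(LipoarmError):
    """Too few or collinear atoms for a rigid superposition."""


class ParameterError(LipoarmError):
    """A numeric parameter is outside its documented domain."""


class OutOfRangeError(LipoarmError):
    """Evaluation requested outside the landscape knot range."""


class UnknownVariantError(LipoarmError, KeyError):
    """Variant name not in the packaged schedule table."""


class ScheduleError(LipoarmError):
    """A state schedule violates its contiguity/ordering invariants."""


class NumericalError(LipoarmError):
    """A stochastic integration step produced a non-finite value."""


class WhamInputError(LipoarmError):
    """Umbrella-window input unusable for WHAM (empty window, bad bins)."""


class IntervalError(LipoarmError):
    """A barrier search interval contains no occupied bins."""


class StateDefinitionError(LipoarmError):
    """A state definition references atoms absent from the topology."""


class SampleSizeError(LipoarmError):
    """Too few matched variants for a correlation."""


class JoinError(LipoarmError):
    """Variant names do not match between two tables."""


class CompletenessError(LipoarmError):
    """A mandatory stage is missing from a run report."""
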