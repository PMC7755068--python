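"""Exception hierarchy for wheatgp.

All package-raised errors derive from :class:`WheatGPError` so callers can
catch one base class at pipeline boundaries.
"""


class WheatGPError(Exception):
    """Base class for all wheatgp errors."""


class InvalidConfigError(WheatGPError, ValueError):
    """A configuration value violates its documented constraints."""


class DimensionError(WheatGPError, ValueError):
    """Shapes or counts of two inputs do not agree."""


class ValidationError(WheatGPError, ValueError):
    """Input data violate a documented invariant."""


class MappingError(WheatGPError, KeyError):
    """An identifier cannot be mapped between two objects."""


class PedigreeCycleError(WheatGPError, ValueError):
    """The pedigree contains a cycle and cannot be ordered."""


class DegenerateKernelError(WheatGPError, ValueError):
    """A relationship matrix cannot be built (e.g. no polymorphic markers)."""


class StructureError(WheatGPError, ValueError):
    """The data lack the factor structure a model requires."""


class InsufficientOverlapError(WheatGPError, ValueError):
    """Too few shared lines between tables for a joint analysis."""


class PredictionError(WheatGPError, KeyError):
    """A record cannot be predicted (line unknown to every kernel)."""


class NumericalError(WheatGPError, ArithmeticError):
    """A linear system is singular or an optimization failed."""
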