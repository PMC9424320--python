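"""Exception hierarchy.

Every error raised on a contract violation derives from PathrankerError so
callers (and the CLI) can distinguish domain failures from programming bugs.
"""


class PathrankerError(Exception):
    """Base class for all domain errors."""


class ValidationError(PathrankerError):
    """A record violates one of its invariants."""


class StructuralError(PathrankerError):
    """A document is well-formed but missing required structure (e.g. a group)."""


class ParseError(PathrankerError):
    """Malformed input that cannot be parsed at all."""


class ConfigurationError(PathrankerError):
    """Required configuration (e.g. a biomass reaction) cannot be resolved."""


class LookupError_(PathrankerError):
    """An identifier is absent from a database it was expected in."""


class MergeError(PathrankerError):
    """Conflicting definitions for the same identifier during model merge."""


class SolverError(PathrankerError):
    """An optimisation problem is infeasible or the solver failed."""


class ThermodynamicsError(PathrankerError):
    """Intermediate cancellation is infeasible for a pathway."""


class FeatureError(PathrankerError):
    """A feature cannot be computed (e.g. structureless species)."""


class ScoringError(PathrankerError):
    """Model/feature mismatch or invalid scoring input."""


class TrainingError(PathrankerError):
    """Classifier training preconditions violated (e.g. single-class labels)."""


class ArgumentError(PathrankerError):
    """An argument is outside its documented domain."""


class SerializationError(PathrankerError):
    """Output cannot be serialised consistently (e.g. duplicate design ids)."""
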