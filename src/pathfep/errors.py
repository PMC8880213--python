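"""Exception hierarchy for pathfep."""


class PathFepError(Exception):
    """Base class for all package-specific errors."""


class InvalidInputError(PathFepError, ValueError):
    """Non-finite or otherwise invalid numeric input."""


class InvalidDistanceError(InvalidInputError):
    """A pair distance is non-positive."""


class InvalidGeometryError(PathFepError, ValueError):
    """Geometrically impossible configuration (e.g. coincident atoms)."""


class ShapeError(PathFepError, ValueError):
    """Array dimensionalities do not match."""


class DegenerateTangentError(PathFepError, ValueError):
    """Two neighboring images coincide; the tangent is undefined."""


class InvalidTangentError(PathFepError, ValueError):
    """Tangent vector is not normalized."""


class DegeneratePathError(PathFepError, ValueError):
    """Path has zero total arc length."""


class NumericalFailureError(PathFepError, RuntimeError):
    """A gradient or energy evaluation produced non-finite values."""


class OptimizationFailureError(PathFepError, RuntimeError):
    """Path optimization diverged; carries the last good path."""

    def __init__(self, message, last_path=None):
        super().__init__(message)
        self.last_path = last_path


class SamplingFailureError(PathFepError, RuntimeError):
    """Monte-Carlo sampling encountered a non-finite energy."""


class InsufficientSamplesError(PathFepError, ValueError):
    """Too few samples for the requested operation."""


class IllConditionedFitError(PathFepError, ValueError):
    """The ESP design matrix is rank deficient or badly conditioned."""

    def __init__(self, message, condition_number=None):
        super().__init__(message)
        self.condition_number = condition_number


class GroupingError(PathFepError, ValueError):
    """Atom groups overlap or fail to cover the active region."""


class GridMismatchError(PathFepError, ValueError):
    """Two profiles are defined on different sigma grids."""


class ParseError(PathFepError, ValueError):
    """A structured text file could not be parsed."""
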