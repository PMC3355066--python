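"""Exception hierarchy for mechinverse."""


class MechInverseError(Exception):
    """Base class for all package-specific errors."""


class ValidationError(MechInverseError):
    """A cell array violates a structural invariant (dangling ids, bad loops...)."""


class TopologyError(ValidationError):
    """Non-manifold or otherwise topologically inadmissible input."""


class GeometryError(MechInverseError):
    """Geometrically degenerate input (self-intersecting loop, zero-length edge...)."""


class DegenerateEdgeError(GeometryError):
    """An edge is shorter than the degeneracy threshold."""


class ConvergenceError(MechInverseError):
    """Quasi-static relaxation failed to reach the force-balance tolerance."""

    def __init__(self, message, residual_history=None):
        super().__init__(message)
        self.residual_history = residual_history if residual_history is not None else []


class SolverError(MechInverseError):
    """The inverse linear system could not be solved."""
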