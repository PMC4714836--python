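"""Exception hierarchy shared across the package."""


class FGScaffoldError(Exception):
    """Base class for all package errors."""


class ValidationError(FGScaffoldError, ValueError):
    """A configuration object or argument violates an invariant."""


class DomainError(FGScaffoldError, ValueError):
    """An evaluation point lies outside the admissible domain."""


class GeometryError(FGScaffoldError, RuntimeError):
    """A pore layout is infeasible (overlap or boundary breach)."""


class MeshingError(FGScaffoldError, RuntimeError):
    """Triangulation failed or produced a degenerate mesh."""


class SolverError(FGScaffoldError, RuntimeError):
    """The coupled poroelastic system could not be solved."""


class OptimizationError(FGScaffoldError, RuntimeError):
    """Every candidate evaluation failed during an optimization run."""
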