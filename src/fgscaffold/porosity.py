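"""Porosity distribution laws for functionally graded scaffolds.

A porosity law maps the height coordinate ``y`` (μm) to the pore radius
``A`` (μm).  Four piecewise-linear families are supported — constant,
linear, bi-linear and tri-linear — with 1, 2, 3 and 4 free coefficients
``A_i`` respectively.  The coefficients are the radii at the segment
breakpoints, so every law is continuous by construction and the segment
gradients are ``m_j = (A_{j+1} - A_j) / (y_{j+1} - y_j)``.

Coordinate convention: ``y = 0`` is the loaded (top) face of the scaffold
and ``y = y_max`` the clamped face.  Interior breakpoints default to an
equal partition of ``[y_min, y_max]`` (halves for the bi-linear law,
thirds for the tri-linear one) and may be overridden.

All radii are bounded by the admissible design interval
``[A_LOWER, A_UPPER] = [5, 300]`` μm.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError

__all__ = [
    "A_LOWER",
    "A_UPPER",
    "LawKind",
    "PorosityLaw",
    "evaluate_radius",
    "gradient",
    "coefficients_to_vector",
    "vector_to_coefficients",
    "radius_profile",
]

#: Admissible pore-radius bounds (μm).
A_LOWER = 5.0
A_UPPER = 300.0


class LawKind(str, enum.Enum):
    """Family of the porosity distribution law."""

    CONSTANT = "constant"
    LINEAR = "linear"
    BILINEAR = "bilinear"
    TRILINEAR = "trilinear"

    @property
    def n_coefficients(self) -> int:
        return _N_COEFFS[self]


_N_COEFFS = {
    LawKind.CONSTANT: 1,
    LawKind.LINEAR: 2,
    LawKind.BILINEAR: 3,
    LawKind.TRILINEAR: 4,
}


def _default_interior(kind: LawKind, y_min: float, y_max: float) -> tuple[float, ...]:
    n_seg = kind.n_coefficients - 1
    if n_seg <= 1:
        return ()
    return tuple(y_min + (y_max - y_min) * j / n_seg for j in range(1, n_seg))


@dataclass(frozen=True)
class PorosityLaw:
    """A piecewise-linear pore-radius-vs-height law.

    Parameters
    ----------
    kind
        Law family; fixes the number of coefficients.
    coefficients
        Radii ``A_i`` (μm) at the breakpoints, ordered from ``y_min`` to
        ``y_max``.  Each must lie in ``[A_LOWER, A_UPPER]``.
    y_min, y_max
        Height interval (μm) on which the law is defined.
    interior_breakpoints
        Interior breakpoint heights (``y_int`` for bi-linear,
        ``(y_int1, y_int2)`` for tri-linear).  Defaults to an equal
        partition of ``[y_min, y_max]``.
    """

    kind: LawKind
    coefficients: tuple[float, ...]
    y_min: float = 0.0
    y_max: float = 3822.0
    interior_breakpoints: tuple[float, ...] | None = field(default=None)

    def __post_init__(self) -> None:
        kind = LawKind(self.kind)
        object.__setattr__(self, "kind", kind)
        coeffs = tuple(float(a) for a in np.atleast_1d(self.coefficients))
        object.__setattr__(self, "coefficients", coeffs)
        if len(coeffs) != kind.n_coefficients:
            raise ValidationError(
                f"{kind.value} law needs {kind.n_coefficients} coefficients, "
                f"got {len(coeffs)}"
            )
        for a in coeffs:
            if not (A_LOWER <= a <= A_UPPER):
                raise ValidationError(
                    f"coefficient {a} μm outside admissible bounds "
                    f"[{A_LOWER}, {A_UPPER}] μm"
                )
        if not self.y_min < self.y_max:
            raise ValidationError("y_min must be strictly below y_max")
        interior = self.interior_breakpoints
        if interior is None:
            interior = _default_interior(kind, self.y_min, self.y_max)
        else:
            interior = tuple(float(b) for b in np.atleast_1d(interior))
        # constant: 0 interior; linear: 0; bilinear: 1; trilinear: 2
        expected = max(kind.n_coefficients - 2, 0)
        if len(interior) != expected:
            raise ValidationError(
                f"{kind.value} law needs {expected} interior breakpoints, "
                f"got {len(interior)}"
            )
        object.__setattr__(self, "interior_breakpoints", interior)
        bps = self.breakpoints
        if not np.all(np.diff(bps) > 0):
            raise ValidationError(f"breakpoints must be strictly increasing: {bps}")

    @property
    def breakpoints(self) -> np.ndarray:
        """All breakpoint heights, ``[y_min, *interior, y_max]`` (μm)."""
        if self.kind is LawKind.CONSTANT:
            return np.array([self.y_min, self.y_max])
        return np.array([self.y_min, *self.interior_breakpoints, self.y_max])

    @property
    def knot_radii(self) -> np.ndarray:
        """Radii at the breakpoints (μm); duplicated for the constant law."""
        if self.kind is LawKind.CONSTANT:
            return np.array([self.coefficients[0], self.coefficients[0]])
        return np.asarray(self.coefficients)

    def __call__(self, y):
        return evaluate_radius(self, y)


def _check_domain(law: PorosityLaw, y) -> np.ndarray:
    y = np.asarray(y, dtype=float)
    if np.any(y < law.y_min) or np.any(y > law.y_max):
        raise DomainError(
            f"height {y} μm outside law domain [{law.y_min}, {law.y_max}] μm"
        )
    return y


def evaluate_radius(law: PorosityLaw, y):
    """Pore radius ``A(y)`` (μm) of *law* at height(s) *y* (μm).

    Piecewise-linear interpolation between the breakpoint radii; exact at
    the breakpoints and continuous in between.
    """
    yv = _check_domain(law, y)
    out = np.interp(yv, law.breakpoints, law.knot_radii)
    return float(out) if np.isscalar(y) or np.ndim(y) == 0 else out


def gradient(law: PorosityLaw, y) -> float:
    """Slope ``m = dA/dy`` (μm/μm) of the segment active at height *y*.

    At an interior breakpoint the left segment's slope is returned (a
    deterministic convention; the law itself is continuous but not
    differentiable there).
    """
    yv = float(_check_domain(law, y))
    if law.kind is LawKind.CONSTANT:
        return 0.0
    bps = law.breakpoints
    radii = law.knot_radii
    # segment index such that bps[i] < y <= bps[i+1]  (left slope at knots)
    i = int(np.searchsorted(bps, yv, side="left")) - 1
    i = min(max(i, 0), len(bps) - 2)
    return float((radii[i + 1] - radii[i]) / (bps[i + 1] - bps[i]))


def coefficients_to_vector(law: PorosityLaw) -> np.ndarray:
    """Design vector (μm) seen by the optimizer: the coefficients A_i."""
    return np.asarray(law.coefficients, dtype=float)


def vector_to_coefficients(
    kind: LawKind | str,
    vector,
    y_min: float = 0.0,
    y_max: float = 3822.0,
    interior_breakpoints: tuple[float, ...] | None = None,
) -> PorosityLaw:
    """Inverse of :func:`coefficients_to_vector` (validates length/bounds)."""
    kind = LawKind(kind)
    vector = np.asarray(vector, dtype=float)
    if vector.ndim != 1 or vector.size != kind.n_coefficients:
        raise ValidationError(
            f"design vector for {kind.value} law must have length "
            f"{kind.n_coefficients}, got shape {vector.shape}"
        )
    return PorosityLaw(
        kind=kind,
        coefficients=tuple(vector),
        y_min=y_min,
        y_max=y_max,
        interior_breakpoints=interior_breakpoints,
    )


def radius_profile(law: PorosityLaw, n: int = 201) -> np.ndarray:
    """Sampled ``(y_μm, A_μm)`` profile, shape ``(n, 2)``, breakpoints included."""
    y = np.union1d(np.linspace(law.y_min, law.y_max, n), law.breakpoints)
    return np.column_stack([y, evaluate_radius(law, y)])
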