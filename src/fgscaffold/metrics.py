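"""Objective and summary metrics for scaffold optimization.

The objective is the (negated) percentage of the scaffold domain occupied
by predicted mature bone:

    V_BONE = Σ measures of granulation elements in the mature-bone band
    BO%    = 100 · V_BONE / V_TOT        (V_TOT = full prism measure t·t·h)
    Ω      = −BO%

The denominator is deliberately the full domain measure including the
scaffold solid, so BO% is capped below 100 for any porous geometry.  In 2D
plane-strain mode measures are areas × unit depth; the metrics are ratios,
so the depth cancels.

Two study-level summaries quantify the porosity grading:

    PVPD = 100 · (A_H − A_L) / A_L   (percent variation of pore dimension)
    iBO% = BO%_trilinear − BO%_constant
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .geometry import ScaffoldMesh
from .mechanoregulation import Phenotype, PhenotypeField
from .porosity import PorosityLaw

__all__ = [
    "ObjectiveResult",
    "bone_volume",
    "bone_occupancy",
    "objective",
    "objective_result",
    "pvpd",
    "ibo",
]


@dataclass(frozen=True)
class ObjectiveResult:
    """Bone volume, total measure and the derived objective values."""

    V_BONE: float
    V_TOT: float
    BO_percent: float
    Omega: float


def bone_volume(phenotypes: PhenotypeField, mesh: ScaffoldMesh) -> float:
    """Total measure of granulation elements predicted to form mature bone."""
    idx = np.asarray(phenotypes.element_indices)
    if len(idx) and idx.max() >= mesh.n_elements:
        raise ValidationError("phenotype field does not match the mesh")
    mature = idx[phenotypes.phenotype == Phenotype.MATURE_BONE]
    return float(mesh.measures[mature].sum())


def bone_occupancy(V_BONE: float, V_TOT: float) -> float:
    """BO% = 100 · V_BONE / V_TOT."""
    if V_TOT <= 0:
        raise ValidationError("V_TOT must be positive")
    if not (0.0 <= V_BONE <= V_TOT * (1 + 1e-12)):
        raise ValidationError("V_BONE must lie in [0, V_TOT]")
    return 100.0 * V_BONE / V_TOT


def objective(BO_percent: float) -> float:
    """Ω = −BO% (minimized by the optimizer)."""
    return -BO_percent


def domain_measure(mesh: ScaffoldMesh) -> float:
    """Full prism measure V_TOT: t·h (×unit depth) in 2D, t·t·h in 3D."""
    if mesh.spec is not None:
        t, h = mesh.spec.t, mesh.spec.h
        return t * h * (t if mesh.dim == 3 else 1.0)
    return mesh.total_measure


def objective_result(phenotypes: PhenotypeField, mesh: ScaffoldMesh) -> ObjectiveResult:
    vb = bone_volume(phenotypes, mesh)
    vt = domain_measure(mesh)
    bo = bone_occupancy(vb, vt)
    return ObjectiveResult(V_BONE=vb, V_TOT=vt, BO_percent=bo, Omega=objective(bo))


def pvpd(radius_profile) -> float:
    """Percent variation of the pore dimension, 100·(A_H − A_L)/A_L.

    Accepts a :class:`~fgscaffold.porosity.PorosityLaw` (extremes taken
    exactly from the breakpoint radii of the piecewise-linear law) or a
    sampled radius profile (array of radii, or ``(y, A)`` columns).
    """
    if isinstance(radius_profile, PorosityLaw):
        radii = np.asarray(radius_profile.knot_radii, dtype=float)
    else:
        radii = np.asarray(radius_profile, dtype=float)
        if radii.ndim == 2:
            radii = radii[:, -1]
    a_low = float(radii.min())
    a_high = float(radii.max())
    if a_low <= 0:
        raise ValidationError("pore radii must be positive")
    return 100.0 * (a_high - a_low) / a_low


def ibo(BO_trilinear: float, BO_constant: float) -> float:
    """iBO% — the BO% gain of the optimal tri-linear law over the optimal
    constant law; zero means grading brings nothing."""
    for v in (BO_trilinear, BO_constant):
        if not (0.0 <= v <= 100.0):
            raise ValidationError("BO% values must lie in [0, 100]")
    return BO_trilinear - BO_constant
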