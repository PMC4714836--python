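"""Mechano-regulation of tissue differentiation.

Mesenchymal stem cells occupying the scaffold pores are assumed to
differentiate according to the local biophysical stimulus

    S = γ/a + v/b,

where γ is the octahedral shear strain of the granulation tissue, v the
interstitial fluid flow (μm/s), and a = 3.75% and b = 3 μm/s empirical
constants.  The stimulus bands select the phenotype: resorption below
``n_resorb``, mature bone up to ``n_mature``, immature bone up to 1,
cartilage up to ``c`` and fibrous tissue above.

Band boundaries are half-open, closed on the lower edge (so S = n_mature
maps to immature bone and S = 0 to resorption) — a deterministic,
measure-zero convention for values that the strict inequalities of the
differentiation rules leave undefined.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np

from .errors import ValidationError
from .fem import PoroelasticSolution
from .geometry import ScaffoldMesh

__all__ = [
    "MechanoRegParams",
    "Phenotype",
    "PhenotypeField",
    "octahedral_shear_strain",
    "biophysical_stimulus",
    "classify",
    "stimulus_field",
]


@dataclass(frozen=True)
class MechanoRegParams:
    """Constants of the differentiation rule.

    ``a`` is stored as a fraction (3.75% → 0.0375) so that strains divide
    correctly; ``b`` is in μm/s.
    """

    a: float = 0.0375
    b: float = 3.0
    n_resorb: float = 0.01
    n_mature: float = 0.53
    c: float = 3.0

    def __post_init__(self) -> None:
        if self.a <= 0 or self.b <= 0:
            raise ValidationError("a and b must be positive")
        if not (0.0 < self.n_resorb < self.n_mature < 1.0 < self.c):
            raise ValidationError(
                "band boundaries must satisfy 0 < n_resorb < n_mature < 1 < c"
            )


class Phenotype(enum.IntEnum):
    RESORPTION = 0
    MATURE_BONE = 1
    IMMATURE_BONE = 2
    CARTILAGE = 3
    FIBROUS = 4


@dataclass
class PhenotypeField:
    """Per-element stimulus and phenotype on the granulation region only."""

    element_indices: np.ndarray  # indices into mesh.elements
    S: np.ndarray
    phenotype: np.ndarray  # Phenotype integer codes

    def __len__(self) -> int:
        return len(self.element_indices)


def octahedral_shear_strain(eps_I, eps_II, eps_III):
    """Octahedral shear strain
    γ = (2/3)·√[(ε_I−ε_II)² + (ε_II−ε_III)² + (ε_III−ε_I)²].

    Permutation-invariant in the principal strains, zero for hydrostatic
    states and positively homogeneous of degree one.
    """
    e1, e2, e3 = (np.asarray(e, dtype=float) for e in (eps_I, eps_II, eps_III))
    if not (
        np.all(np.isfinite(e1)) and np.all(np.isfinite(e2)) and np.all(np.isfinite(e3))
    ):
        raise ValidationError("principal strains must be finite")
    g = (2.0 / 3.0) * np.sqrt(
        (e1 - e2) ** 2 + (e2 - e3) ** 2 + (e3 - e1) ** 2
    )
    return float(g) if np.ndim(g) == 0 else g


def biophysical_stimulus(gamma, v, params: MechanoRegParams | None = None):
    """Stimulus S = γ/a + v/b (γ dimensionless strain, v in μm/s)."""
    params = params or MechanoRegParams()
    gamma = np.asarray(gamma, dtype=float)
    v = np.asarray(v, dtype=float)
    if np.any(gamma < 0) or np.any(v < 0):
        raise ValidationError("γ and v must be non-negative")
    s = gamma / params.a + v / params.b
    return float(s) if np.ndim(s) == 0 else s


def classify(S, params: MechanoRegParams | None = None):
    """Tissue phenotype for stimulus *S* (scalar or array).

    Bands (lower-closed): [0, n_resorb) resorption, [n_resorb, n_mature)
    mature bone, [n_mature, 1) immature bone, [1, c) cartilage,
    [c, ∞) fibrous.
    """
    params = params or MechanoRegParams()
    s = np.asarray(S, dtype=float)
    if np.any(s < 0):
        raise ValidationError("stimulus must be non-negative")
    out = np.select(
        [
            s < params.n_resorb,
            s < params.n_mature,
            s < 1.0,
            s < params.c,
        ],
        [
            Phenotype.RESORPTION,
            Phenotype.MATURE_BONE,
            Phenotype.IMMATURE_BONE,
            Phenotype.CARTILAGE,
        ],
        default=Phenotype.FIBROUS,
    )
    if np.ndim(S) == 0:
        return Phenotype(int(out))
    return out.astype(np.int8)


def stimulus_field(
    solution: PoroelasticSolution,
    mesh: ScaffoldMesh | None = None,
    params: MechanoRegParams | None = None,
) -> PhenotypeField:
    """Stimulus and phenotype for every granulation (pore) element.

    Scaffold elements are excluded: differentiation only happens in the
    tissue occupying the pores.
    """
    params = params or MechanoRegParams()
    mesh = mesh or solution.mesh
    if mesh is not solution.mesh and mesh.n_elements != solution.mesh.n_elements:
        raise ValidationError("solution was computed on a different mesh")
    idx = mesh.granulation_elements
    eps = solution.principal_strains[idx]
    gamma = octahedral_shear_strain(eps[:, 0], eps[:, 1], eps[:, 2])
    s = biophysical_stimulus(gamma, solution.flux[idx], params)
    return PhenotypeField(
        element_indices=idx,
        S=np.atleast_1d(s),
        phenotype=np.atleast_1d(classify(s, params)),
    )
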