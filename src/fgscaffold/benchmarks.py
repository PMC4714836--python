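"""Closed-form poroelastic benchmark solutions.

These classical results serve as independent oracles for the finite
element solver: the Terzaghi one-dimensional consolidation series and the
associated consolidation/undrained-response coefficients of linear Biot
theory.
"""

from __future__ import annotations

import numpy as np

from .fem import MaterialProperties

__all__ = [
    "consolidation_coefficient",
    "undrained_pressure_ratio",
    "terzaghi_pressure_ratio",
]


def consolidation_coefficient(material: MaterialProperties) -> float:
    """Consolidation coefficient c_v (m²/s) for 1D (oedometric) drainage.

    c_v = k / (1/M + α²/M_conf) with M the Biot modulus and M_conf the
    confined (oedometer) modulus.
    """
    m_conf = material.confined_modulus * 1e6  # Pa
    return material.k / (material.storage + material.biot_alpha**2 / m_conf)


def undrained_pressure_ratio(material: MaterialProperties) -> float:
    """Initial (undrained) pore pressure per unit applied axial stress,
    p₀/σ = α / (α² + M_conf/M)."""
    m_conf = material.confined_modulus * 1e6
    a = material.biot_alpha
    return a / (a**2 + m_conf * material.storage)


def terzaghi_pressure_ratio(
    z_over_H, T_v: float, n_terms: int = 200
) -> np.ndarray:
    """Normalized excess pore pressure p/p₀ of Terzaghi's 1D consolidation.

    ``z_over_H`` is depth from the drained surface over the drainage path
    length H (single drainage: impermeable base at z/H = 1), ``T_v`` the
    dimensionless time factor c_v·t/H².

    p/p₀ = Σ_{m≥0} 4/(π(2m+1)) · sin((2m+1)πz/2H) · exp(−((2m+1)π/2)² T_v)
    """
    z = np.atleast_1d(np.asarray(z_over_H, dtype=float))
    m = np.arange(n_terms)[:, None]
    lam = (2 * m + 1) * np.pi / 2.0
    series = (2.0 / lam) * np.sin(lam * z[None, :]) * np.exp(-(lam**2) * T_v)
    out = series.sum(axis=0)
    return out if np.ndim(z_over_H) else float(out[0])
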