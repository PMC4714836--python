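"""Quasi-static Biot poroelasticity on scaffold meshes (2D plane strain).

The solver plays the role of the finite-element stage of the pipeline:
ramped compression/shear/mixed loading applied through a rigid plate tied
to the top face, a clamped bottom face, zero pore pressure on drained
boundaries, and implicit (backward-Euler) time stepping through the load
ramp.  It returns per-element principal strains, Darcy flux magnitude and
pore pressure at the evaluation time.

Discretization: Taylor–Hood triangles — quadratic displacements, linear
pressure — which are inf-sup stable for the coupled u–p problem, with a
three-point quadrature rule that integrates every bilinear form exactly.

Units: the API speaks μm and MPa (and permeability in m⁴ N⁻¹ s⁻¹, the
field's customary unit); internally everything is converted to SI
(m, Pa, s).  Fluxes are reported in μm/s so they are directly comparable
with the mechano-regulation constant ``b = 3 μm/s``.

Biot coefficient and storage follow the standard relations
``α = 1 − K_drained/K_grain`` and
``1/M = (α − n)/K_grain + n/K_fluid``.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp
from scipy.sparse.linalg import splu

from .errors import SolverError, ValidationError
from .geometry import ScaffoldMesh, REGION_NAMES

__all__ = [
    "MaterialProperties",
    "GRANULATION_TISSUE",
    "scaffold_material",
    "LoadKind",
    "LoadCase",
    "PoroelasticSolution",
    "solve",
    "principal_strains",
    "darcy_flux_magnitude",
]

_UM = 1e-6  # m per μm
_MPA = 1e6  # Pa per MPa


@dataclass(frozen=True)
class MaterialProperties:
    """Poroelastic material: stiffness, transport and constituent moduli.

    Parameters
    ----------
    E : float
        Young's modulus, MPa.
    nu : float
        Poisson ratio (0 < ν < 0.5).
    k : float
        Permeability, m⁴ N⁻¹ s⁻¹ (Darcy conductivity ``v = −k ∇p``).
    n : float
        Porosity (fluid volume fraction).
    K_grain, K_fluid : float
        Bulk moduli of the solid grains and the pore fluid, MPa.
    """

    E: float
    nu: float
    k: float = 1e-14
    n: float = 0.8
    K_grain: float = 2300.0
    K_fluid: float = 2300.0

    def __post_init__(self) -> None:
        if self.E <= 0:
            raise ValidationError("Young's modulus must be positive")
        if not (0.0 <= self.nu < 0.5):
            raise ValidationError("Poisson ratio must lie in [0, 0.5)")
        if self.k <= 0:
            raise ValidationError("permeability must be positive")
        if not (0.0 < self.n < 1.0):
            raise ValidationError("porosity must lie in (0, 1)")

    @property
    def drained_bulk_modulus(self) -> float:
        """K_d = E / 3(1 − 2ν), MPa."""
        return self.E / (3.0 * (1.0 - 2.0 * self.nu))

    @property
    def biot_alpha(self) -> float:
        """α = 1 − K_d / K_grain."""
        return 1.0 - self.drained_bulk_modulus / self.K_grain

    @property
    def storage(self) -> float:
        """Specific storage 1/M = (α − n)/K_grain + n/K_fluid, 1/Pa."""
        a = self.biot_alpha
        return (a - self.n) / (self.K_grain * _MPA) + self.n / (
            self.K_fluid * _MPA
        )

    @property
    def confined_modulus(self) -> float:
        """Oedometer modulus E(1−ν)/((1+ν)(1−2ν)), MPa."""
        return (
            self.E
            * (1.0 - self.nu)
            / ((1.0 + self.nu) * (1.0 - 2.0 * self.nu))
        )


#: Granulation tissue filling the pores (reference soft-tissue properties).
GRANULATION_TISSUE = MaterialProperties(
    E=0.2, nu=0.167, k=1e-14, n=0.8, K_grain=2300.0, K_fluid=2300.0
)


def scaffold_material(E: float = 1000.0) -> MaterialProperties:
    """Scaffold solid phase with Young's modulus *E* (MPa).

    Transport properties (ν = 0.3, k = 1e-14 m⁴/N/s, n = 0.5, constituent
    bulk moduli 2300 MPa) are typical values for biphasic scaffold models.
    """
    return MaterialProperties(
        E=E, nu=0.3, k=1e-14, n=0.5, K_grain=2300.0, K_fluid=2300.0
    )


class LoadKind(str, enum.Enum):
    COMPRESSION = "compression"
    SHEAR = "shear"
    MIXED = "mixed"


@dataclass(frozen=True)
class LoadCase:
    """Ramped plate loading.

    ``compressive_traction`` is the vertical distributed load F_V/(t·t)
    (default 1 MPa) and ``shear_traction`` the horizontal one F_H/(t·t)
    (default 0.5 MPa); the mixed case is their vector sum.  The load ramps
    linearly from zero over ``ramp`` seconds (default 1 s) and the stimulus
    is evaluated at the end of the ramp.
    """

    kind: LoadKind = LoadKind.COMPRESSION
    compressive_traction: float = 1.0
    shear_traction: float = 0.5
    ramp: float = 1.0
    n_steps: int = 10

    def __post_init__(self) -> None:
        object.__setattr__(self, "kind", LoadKind(self.kind))
        if self.compressive_traction < 0 or self.shear_traction < 0:
            raise ValidationError("tractions must be non-negative")
        if self.ramp <= 0:
            raise ValidationError("ramp duration must be positive")
        if self.n_steps < 1:
            raise ValidationError("need at least one time step")

    def tractions(self) -> tuple[float, float]:
        """Active (vertical, horizontal) tractions in MPa."""
        if self.kind is LoadKind.COMPRESSION:
            return self.compressive_traction, 0.0
        if self.kind is LoadKind.SHEAR:
            return 0.0, self.shear_traction
        return self.compressive_traction, self.shear_traction


@dataclass
class PoroelasticSolution:
    """Element-wise poroelastic state at the evaluation time.

    ``principal_strains`` holds (ε_I ≥ ε_II ≥ ε_III) per element (the
    out-of-plane strain is identically zero in plane strain),
    ``flux`` the Darcy flux magnitude in μm/s, pressures in MPa and
    vertex displacements in μm.
    """

    mesh: ScaffoldMesh
    principal_strains: np.ndarray
    strain_tensors: np.ndarray  # (n_el, 3): ε_xx, ε_yy, ε_xy
    flux: np.ndarray
    pressure_elem: np.ndarray
    pressure_nodal: np.ndarray
    displacement: np.ndarray
    time: float
    pressure_history: dict[float, np.ndarray] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# P2/P1 reference element

# quadrature: 3 interior points, exact for quadratics
_QP = np.array([[2 / 3, 1 / 6, 1 / 6], [1 / 6, 2 / 3, 1 / 6], [1 / 6, 1 / 6, 2 / 3]])
_QW = np.array([1 / 3, 1 / 3, 1 / 3])  # of reference area 1/2

_DL_P1 = np.array([[-1.0, -1.0], [1.0, 0.0], [0.0, 1.0]])  # ∇(L1,L2,L3) in (ξ,η)


def _p2_shape(bary: np.ndarray) -> np.ndarray:
    l1, l2, l3 = bary
    return np.array(
        [
            l1 * (2 * l1 - 1),
            l2 * (2 * l2 - 1),
            l3 * (2 * l3 - 1),
            4 * l1 * l2,
            4 * l2 * l3,
            4 * l3 * l1,
        ]
    )


def _p2_grad_ref(bary: np.ndarray) -> np.ndarray:
    """Gradient of the six P2 shape functions w.r.t. (ξ, η)."""
    l1, l2, l3 = bary
    return np.array(
        [
            [-(4 * l1 - 1), -(4 * l1 - 1)],
            [4 * l2 - 1, 0.0],
            [0.0, 4 * l3 - 1],
            [4 * (l1 - l2), -4 * l2],
            [4 * l3, 4 * l2],
            [-4 * l3, 4 * (l1 - l3)],
        ]
    )


def _build_p2(points: np.ndarray, tris: np.ndarray):
    """Edge midnodes and 6-node connectivity for a triangle mesh."""
    e_local = np.concatenate(
        [tris[:, [0, 1]], tris[:, [1, 2]], tris[:, [2, 0]]], axis=0
    )
    e_sorted = np.sort(e_local, axis=1)
    edges, inverse = np.unique(e_sorted, axis=0, return_inverse=True)
    ne = len(tris)
    mid = len(points) + inverse.reshape(3, ne).T  # midnodes m01, m12, m20
    tri6 = np.concatenate([tris, mid], axis=1)
    midpoints = 0.5 * (points[edges[:, 0]] + points[edges[:, 1]])
    p2_points = np.vstack([points, midpoints])
    return p2_points, tri6, edges


def _extended_tag(tag_vertices: np.ndarray, edges: np.ndarray, n_vert: int):
    """P2 node ids on a tagged boundary: its vertices plus midnodes of
    edges whose both endpoints are tagged."""
    mask = np.zeros(n_vert, dtype=bool)
    mask[tag_vertices] = True
    on = mask[edges[:, 0]] & mask[edges[:, 1]]
    return np.concatenate([tag_vertices, n_vert + np.flatnonzero(on)])


# ---------------------------------------------------------------------------
# assembly


def _elastic_D(E: np.ndarray, nu: np.ndarray) -> np.ndarray:
    """Plane-strain constitutive matrices, (n_el, 3, 3), Voigt with
    engineering shear."""
    c = E / ((1 + nu) * (1 - 2 * nu))
    D = np.zeros((len(E), 3, 3))
    D[:, 0, 0] = D[:, 1, 1] = c * (1 - nu)
    D[:, 0, 1] = D[:, 1, 0] = c * nu
    D[:, 2, 2] = c * (1 - 2 * nu) / 2
    return D


def _material_arrays(mesh: ScaffoldMesh, materials):
    if isinstance(materials, MaterialProperties):
        materials = {name: materials for name in REGION_NAMES}
    ne = mesh.n_elements
    E = np.empty(ne)
    nu = np.empty(ne)
    k = np.empty(ne)
    alpha = np.empty(ne)
    storage = np.empty(ne)
    for code, name in enumerate(REGION_NAMES):
        sel = mesh.region == code
        if not sel.any():
            continue
        if name not in materials:
            raise ValidationError(f"no material given for region '{name}'")
        m = materials[name]
        E[sel] = m.E * _MPA
        nu[sel] = m.nu
        k[sel] = m.k
        alpha[sel] = m.biot_alpha
        storage[sel] = m.storage
    return E, nu, k, alpha, storage


def _assemble(mesh: ScaffoldMesh, materials):
    points = mesh.points * _UM  # μm -> m
    tris = mesh.elements
    ne = len(tris)
    p2_points, tri6, edges = _build_p2(points, tris)
    nn2 = len(p2_points)
    nv = len(points)

    E, nu, k, alpha, storage = _material_arrays(mesh, materials)
    D = _elastic_D(E, nu)

    verts = points[tris]  # (ne, 3, 2)
    J = np.stack(
        [verts[:, 1] - verts[:, 0], verts[:, 2] - verts[:, 0]], axis=2
    )  # columns d x/d(ξ,η)
    detJ = J[:, 0, 0] * J[:, 1, 1] - J[:, 0, 1] * J[:, 1, 0]
    if np.any(detJ <= 0):
        raise SolverError("mesh contains inverted or degenerate triangles")
    Jinv = np.empty_like(J)
    Jinv[:, 0, 0] = J[:, 1, 1]
    Jinv[:, 1, 1] = J[:, 0, 0]
    Jinv[:, 0, 1] = -J[:, 0, 1]
    Jinv[:, 1, 0] = -J[:, 1, 0]
    Jinv /= detJ[:, None, None]

    Ke = np.zeros((ne, 12, 12))
    Qe = np.zeros((ne, 12, 3))
    Ce = np.zeros((ne, 3, 3))

    for q in range(len(_QW)):
        w = _QW[q] * 0.5 * detJ  # (ne,)
        dref = _p2_grad_ref(_QP[q])  # (6, 2)
        dphys = np.einsum("ak,ekj->eaj", dref, Jinv)  # (ne, 6, 2)
        B = np.zeros((ne, 3, 12))
        B[:, 0, 0::2] = dphys[:, :, 0]
        B[:, 1, 1::2] = dphys[:, :, 1]
        B[:, 2, 0::2] = dphys[:, :, 1]
        B[:, 2, 1::2] = dphys[:, :, 0]
        Ke += np.einsum("e,eki,ekl,elj->eij", w, B, D, B, optimize=True)
        div = np.zeros((ne, 12))
        div[:, 0::2] = dphys[:, :, 0]
        div[:, 1::2] = dphys[:, :, 1]
        L = _QP[q]
        Qe += (w * alpha)[:, None, None] * div[:, :, None] * L[None, None, :]
        Ce += (w * storage)[:, None, None] * np.outer(L, L)[None]

    # conduction (P1, constant gradients)
    gradL = np.einsum("ak,ekj->eaj", _DL_P1, Jinv)  # (ne, 3, 2)
    He = (
        (0.5 * detJ * k)[:, None, None]
        * np.einsum("eaj,ebj->eab", gradL, gradL)
    )

    udof = np.empty((ne, 12), dtype=np.int64)
    udof[:, 0::2] = 2 * tri6
    udof[:, 1::2] = 2 * tri6 + 1
    pdof = tris

    def coo(vals, rows, cols, shape):
        m = sp.coo_matrix(
            (
                vals.ravel(),
                (
                    np.broadcast_to(rows[:, :, None], vals.shape).ravel(),
                    np.broadcast_to(cols[:, None, :], vals.shape).ravel(),
                ),
            ),
            shape=shape,
        )
        return m.tocsr()

    nu_dof = 2 * nn2
    K = coo(Ke, udof, udof, (nu_dof, nu_dof))
    Q = coo(Qe, udof, pdof, (nu_dof, nv))
    C = coo(Ce, pdof, pdof, (nv, nv))
    H = coo(He, pdof, pdof, (nv, nv))
    return K, Q, C, H, p2_points, tri6, edges, Jinv, detJ


def _constraint_map(
    mesh: ScaffoldMesh,
    edges: np.ndarray,
    nn2: int,
    p2_x: np.ndarray,
    *,
    lateral_roller: bool,
    drained_tags: tuple[str, ...],
    drain_all: bool,
    plate_rotation: bool,
):
    """Build the reduction matrix T (full dofs × reduced dofs).

    Clamped and drained dofs are eliminated (zero value); top-face
    displacement dofs are tied to rigid-plate master dofs: two
    translations and, when ``plate_rotation`` is on, a moment-free tilt
    (``u_y = U_Y + θ·(x − x_c)`` along the plate).  A force-loaded rigid
    plate leaves its rotation free, which is what lets shear loading
    produce the bending-driven stimulus gradient along the height.
    """
    nv = len(mesh.points)
    ndof = 2 * nn2 + nv

    fixed = np.zeros(ndof, dtype=bool)
    clamped = _extended_tag(mesh.boundary_tags["bottom_clamped"], edges, nv)
    fixed[2 * clamped] = True
    fixed[2 * clamped + 1] = True
    if lateral_roller:
        fixed[0 : 2 * nn2 : 2] = True  # u_x = 0 everywhere (1D column mode)
    if drain_all:
        fixed[2 * nn2 :] = True
    else:
        for tag in drained_tags:
            fixed[2 * nn2 + mesh.boundary_tags[tag]] = True

    top = _extended_tag(mesh.boundary_tags["top_loaded"], edges, nv)
    tie_x = 2 * top[~fixed[2 * top]]
    tie_y = 2 * top[~fixed[2 * top + 1]] + 1
    tied = np.zeros(ndof, dtype=bool)
    tied[tie_x] = True
    tied[tie_y] = True

    free = ~(fixed | tied)
    n_free = int(free.sum())
    col = np.full(ndof, -1, dtype=np.int64)
    col[free] = np.arange(n_free)
    nred = n_free
    mx = my = None
    if len(tie_x):  # a master dof only exists if something is tied to it
        mx = nred
        col[tie_x] = mx
        nred += 1
    if len(tie_y):
        my = nred
        col[tie_y] = my
        nred += 1
    rows = np.flatnonzero(col >= 0).tolist()
    cols = col[rows].tolist()
    vals = [1.0] * len(rows)
    if plate_rotation and len(tie_y) > 1:
        x_tied = p2_x[tie_y // 2]
        xc = x_tied.mean()
        rot = nred
        nred += 1
        rows.extend(tie_y.tolist())
        cols.extend([rot] * len(tie_y))
        vals.extend((x_tied - xc).tolist())
    T = sp.coo_matrix((vals, (rows, cols)), shape=(ndof, nred)).tocsr()
    return T, mx, my


def solve(
    mesh: ScaffoldMesh,
    materials,
    load: LoadCase | None = None,
    *,
    times: np.ndarray | None = None,
    drained: bool = False,
    lateral_roller: bool = False,
    drained_tags: tuple[str, ...] = ("outer_drained",),
    plate_rotation: bool = True,
    record_pressure: bool = False,
) -> PoroelasticSolution:
    """Time-step the coupled Biot problem and return the end-state fields.

    Parameters
    ----------
    mesh
        A 2D :class:`~fgscaffold.geometry.ScaffoldMesh`.
    materials
        A single :class:`MaterialProperties` or a mapping
        ``{"scaffold": ..., "granulation": ...}``.
    load
        The :class:`LoadCase`; defaults to 1 MPa ramped compression.
    times
        Optional strictly increasing solution times (s) overriding the
        uniform ramp discretization; the final entry is the evaluation
        time.  Use this for consolidation benchmarks with a hold phase.
    drained
        Solve the fully drained (elastic) limit in a single static step
        with the pore pressure fixed at zero everywhere.
    lateral_roller
        Constrain all horizontal displacements (1D consolidation mode).
    drained_tags
        Boundary tags whose vertex pressures are fixed at 0 MPa.
    plate_rotation
        Leave the rigid plate's tilt free (moment-free), as a force-loaded
        rigid-plate tie does; switch off to force a purely translating
        plate.
    record_pressure
        Keep nodal pressure snapshots for every solution time.
    """
    if mesh.dim != 2:
        raise SolverError(
            "the poroelastic solver operates on 2D plane-strain meshes; "
            "coarse_3d meshes are supported for geometry bookkeeping only"
        )
    load = load or LoadCase()
    K, Q, C, H, p2_points, tri6, edges, Jinv, detJ = _assemble(mesh, materials)
    nn2 = len(p2_points)
    nv = len(mesh.points)
    T, mx, my = _constraint_map(
        mesh,
        edges,
        nn2,
        p2_points[:, 0],
        lateral_roller=lateral_roller,
        drained_tags=drained_tags,
        drain_all=drained,
        plate_rotation=plate_rotation,
    )

    sigma_v, sigma_h = load.tractions()  # MPa
    width = float(mesh.points[:, 0].max() - mesh.points[:, 0].min()) * _UM
    # total plate force per unit depth (N/m); compression presses into the
    # domain (+y, the loaded face is at y = 0), shear acts along +x
    Fy = sigma_v * _MPA * width
    Fx = sigma_h * _MPA * width

    nred = T.shape[1]

    def factorize(dt):
        """LU of the reduced system with symmetric Jacobi equilibration
        (the u- and p-blocks differ by many orders of magnitude in SI
        units; scaling keeps the factorization accurate)."""
        A = sp.bmat([[K, -Q], [Q.T, C + dt * H]], format="csr")
        Ar = (T.T @ A @ T).tocsc()
        d = 1.0 / np.sqrt(np.abs(Ar.diagonal()))
        Dm = sp.diags(d)
        lu = splu((Dm @ Ar @ Dm).tocsc())

        def solve_scaled(rhs):
            return d * lu.solve(d * rhs)

        return solve_scaled

    x_full = np.zeros(2 * nn2 + nv)
    history: dict[float, np.ndarray] = {}

    if drained:
        f = np.zeros(nred)
        if mx is not None:
            f[mx] += Fx
        if my is not None:
            f[my] += Fy
        try:
            x = factorize(1.0)(f)
        except RuntimeError as exc:
            raise SolverError(f"singular drained system: {exc}") from exc
        x_full = T @ x
        t_eval = load.ramp
    else:
        if times is None:
            times = np.linspace(0.0, load.ramp, load.n_steps + 1)[1:]
        times = np.asarray(times, dtype=float)
        if np.any(np.diff(times) <= 0) or times[0] <= 0:
            raise ValidationError("times must be positive and increasing")
        u_prev = np.zeros(2 * nn2)
        p_prev = np.zeros(nv)
        t_prev = 0.0
        lu = None
        dt_prev = None
        for t in times:
            dt = t - t_prev
            if lu is None or not np.isclose(dt, dt_prev):
                try:
                    lu = factorize(dt)
                except RuntimeError as exc:
                    raise SolverError(
                        f"singular poroelastic system at t = {t} s: {exc}"
                    ) from exc
                dt_prev = dt
            scale = min(t / load.ramp, 1.0)
            rhs_full = np.concatenate([np.zeros(2 * nn2), Q.T @ u_prev + C @ p_prev])
            f = T.T @ rhs_full
            if mx is not None:
                f[mx] += Fx * scale
            if my is not None:
                f[my] += Fy * scale
            x = lu(f)
            x_full = T @ x
            u_prev = x_full[: 2 * nn2]
            p_prev = x_full[2 * nn2 :]
            if record_pressure:
                history[float(t)] = p_prev.copy() / _MPA
            t_prev = t
        t_eval = float(times[-1])

    u = x_full[: 2 * nn2]
    p = x_full[2 * nn2 :]

    # strains at element centroids from the quadratic displacement field
    dref = _p2_grad_ref(np.array([1 / 3, 1 / 3, 1 / 3]))
    dphys = np.einsum("ak,ekj->eaj", dref, Jinv)
    ue = u[(2 * tri6)[:, :, None] + np.array([0, 1])[None, None, :]]  # (ne,6,2)
    grad_u = np.einsum("eai,eaj->eij", ue, dphys)  # du_i/dx_j
    eps_xx = grad_u[:, 0, 0]
    eps_yy = grad_u[:, 1, 1]
    eps_xy = 0.5 * (grad_u[:, 0, 1] + grad_u[:, 1, 0])
    strain_tensors = np.column_stack([eps_xx, eps_yy, eps_xy])

    mean = 0.5 * (eps_xx + eps_yy)
    rad = np.sqrt((0.5 * (eps_xx - eps_yy)) ** 2 + eps_xy**2)
    principal = np.sort(
        np.column_stack([mean + rad, mean - rad, np.zeros_like(mean)]), axis=1
    )[:, ::-1]

    gradL = np.einsum("ak,ekj->eaj", _DL_P1, Jinv)
    grad_p = np.einsum("ea,eaj->ej", p[mesh.elements], gradL)  # Pa/m
    _, _, k_el, _, _ = _material_arrays(mesh, materials)
    flux = k_el * np.linalg.norm(grad_p, axis=1) / _UM  # m/s -> μm/s

    return PoroelasticSolution(
        mesh=mesh,
        principal_strains=principal,
        strain_tensors=strain_tensors,
        flux=flux,
        pressure_elem=p[mesh.elements].mean(axis=1) / _MPA,
        pressure_nodal=p / _MPA,
        displacement=u[: 2 * nv].reshape(-1, 2) / _UM,
        time=t_eval,
        pressure_history=history,
    )


def principal_strains(strain_tensor: np.ndarray) -> tuple[float, float, float]:
    """Principal strains (ε_I ≥ ε_II ≥ ε_III) of a symmetric small-strain
    tensor (2×2 tensors are embedded in plane strain with ε_zz = 0)."""
    t = np.asarray(strain_tensor, dtype=float)
    if t.shape not in ((2, 2), (3, 3)):
        raise ValidationError("strain tensor must be 2x2 or 3x3")
    if not np.allclose(t, t.T, atol=1e-12 + 1e-9 * np.abs(t).max()):
        raise ValidationError("strain tensor must be symmetric")
    if t.shape == (2, 2):
        full = np.zeros((3, 3))
        full[:2, :2] = t
        t = full
    vals = np.linalg.eigvalsh(t)[::-1]
    return tuple(float(v) for v in vals)


def darcy_flux_magnitude(solution: PoroelasticSolution, element: int) -> float:
    """Darcy flux magnitude ‖−k ∇p‖ (μm/s) at an element centroid."""
    return float(solution.flux[element])
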