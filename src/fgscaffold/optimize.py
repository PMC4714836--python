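"""Bound-constrained SQP optimization of the porosity-law coefficients.

One design evaluation composes the whole pipeline: design vector →
porosity law → two-phase mesh → poroelastic solve → stimulus/phenotype
field → bone occupancy BO% → objective Ω = −BO%.  A sequential quadratic
programming loop (SciPy's SLSQP) minimizes Ω over the coefficients A_i in
[5, 300] μm, terminating on a function tolerance, a step tolerance or an
iteration cap.  Because every candidate geometry is remeshed, the
objective carries mesh noise; gradients are finite differences with a
step (default 5 μm) large relative to that noise, and multiple starts
mitigate local optima.

``run_study`` enumerates the full factorial study — scaffold Young's
modulus × loading condition × law family (3 × 3 × 4 = 36 runs by default)
— seeding every richer law with the optima of the poorer ones (a constant
law is exactly representable by every richer family, so the best graded
BO% can never fall below the best homogeneous one).
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .errors import GeometryError, OptimizationError, ValidationError
from .fem import (
    GRANULATION_TISSUE,
    LoadCase,
    LoadKind,
    MaterialProperties,
    scaffold_material,
    solve,
)
from .geometry import ScaffoldSpec, build_scaffold_mesh
from .mechanoregulation import MechanoRegParams, stimulus_field
from .metrics import ibo, objective_result, pvpd
from .porosity import (
    A_LOWER,
    A_UPPER,
    LawKind,
    PorosityLaw,
    evaluate_radius,
    vector_to_coefficients,
)

__all__ = [
    "EvaluationContext",
    "OptimizationConfig",
    "OptimizationRecord",
    "StudyConfig",
    "evaluate_design",
    "optimize",
    "enumerate_study",
    "run_study",
]

logger = logging.getLogger(__name__)

#: Objective value substituted for infeasible geometries during line search.
GEOMETRY_PENALTY = 1e6


@dataclass
class EvaluationContext:
    """Everything a design evaluation needs besides the design vector."""

    spec: ScaffoldSpec
    load: LoadCase
    materials: dict[str, MaterialProperties]
    law_kind: LawKind = LawKind.CONSTANT
    mechreg: MechanoRegParams = field(default_factory=MechanoRegParams)
    seed: int = 0
    _cache: dict = field(default_factory=dict, repr=False)

    def make_law(self, vector: np.ndarray) -> PorosityLaw:
        return vector_to_coefficients(
            self.law_kind, vector, y_min=0.0, y_max=self.spec.h
        )


def evaluate_design(vector, context: EvaluationContext) -> tuple[float, float]:
    """(Ω, BO%) of a design vector; deterministic for a fixed context.

    Infeasible pore layouts (overlap / boundary breach) return the large
    penalty objective instead of raising, so the SQP line search can back
    off; the event is logged.
    """
    vector = np.asarray(vector, dtype=float)
    key = tuple(np.round(vector, 9))
    if key in context._cache:
        return context._cache[key]
    try:
        law = context.make_law(vector)
        mesh = build_scaffold_mesh(context.spec, law, seed=context.seed)
        sol = solve(mesh, context.materials, context.load)
        phen = stimulus_field(sol, mesh, context.mechreg)
        res = objective_result(phen, mesh)
        out = (res.Omega, res.BO_percent)
    except GeometryError as exc:
        logger.warning("infeasible geometry for %s: %s", vector, exc)
        out = (GEOMETRY_PENALTY, 0.0)
    context._cache[key] = out
    return out


@dataclass(frozen=True)
class OptimizationConfig:
    """SQP settings for one optimization run."""

    law_kind: LawKind = LawKind.CONSTANT
    initial: tuple[float, ...] | None = None  # default: all 150 μm
    bounds: tuple[float, float] = (A_LOWER, A_UPPER)
    ftol: float = 1e-2  # BO% points
    step_tol: float = 1.0  # μm
    max_iterations: int = 50
    fd_step: float = 5.0  # μm
    multistart: tuple[float, ...] = (50.0, 150.0, 250.0)
    seed: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "law_kind", LawKind(self.law_kind))
        lo, hi = self.bounds
        if not lo < hi:
            raise ValidationError("lower bound must be below upper bound")
        if self.ftol <= 0 or self.step_tol <= 0 or self.fd_step <= 0:
            raise ValidationError("tolerances and FD step must be positive")
        if self.initial is not None:
            vec = np.asarray(self.initial, dtype=float)
            if vec.size != self.law_kind.n_coefficients:
                raise ValidationError("initial vector length mismatches law kind")
            if np.any(vec < lo) or np.any(vec > hi):
                raise ValidationError("initial values must fall within the bounds")

    def start_vectors(self, extra_starts=()) -> list[np.ndarray]:
        n = self.law_kind.n_coefficients
        starts = []
        if self.initial is not None:
            starts.append(np.asarray(self.initial, dtype=float))
        starts.extend(np.full(n, level) for level in self.multistart)
        starts.extend(np.asarray(s, dtype=float) for s in extra_starts)
        lo, hi = self.bounds
        uniq, seen = [], set()
        for s in starts:
            s = np.clip(s, lo, hi)
            key = tuple(np.round(s, 6))
            if key not in seen:
                seen.add(key)
                uniq.append(s)
        return uniq


@dataclass
class OptimizationRecord:
    """Evaluation history and the best design found."""

    law_kind: LawKind
    vectors: np.ndarray  # (n_eval, n_coeff)
    omegas: np.ndarray
    bo_percents: np.ndarray
    best_vector: np.ndarray
    best_omega: float
    best_bo_percent: float
    termination: str
    evaluations: int
    best_law: PorosityLaw | None = None


class _StepConverged(Exception):
    pass


def optimize(
    config: OptimizationConfig,
    context: EvaluationContext | None = None,
    objective_fn=None,
    extra_starts=(),
) -> OptimizationRecord:
    """Minimize Ω over the law coefficients with bound-constrained SLSQP.

    ``objective_fn`` (vector → Ω) replaces the full pipeline evaluation,
    e.g. for closed-form surrogate objectives; otherwise *context* is
    required and :func:`evaluate_design` is used.
    """
    if objective_fn is None:
        if context is None:
            raise ValidationError("either a context or an objective_fn is needed")
        context = replace(context, law_kind=config.law_kind)

    lo, hi = config.bounds
    span = hi - lo  # SLSQP works in normalized coordinates z = (A - lo)/span
    n = config.law_kind.n_coefficients
    vectors: list[np.ndarray] = []
    omegas: list[float] = []
    bos: list[float] = []

    def fun(z: np.ndarray) -> float:
        x = np.clip(lo + np.asarray(z, dtype=float) * span, lo, hi)
        if objective_fn is not None:
            om = float(objective_fn(x))
            bo = np.nan
        else:
            om, bo = evaluate_design(x, context)
        vectors.append(x.copy())
        omegas.append(om)
        bos.append(bo)
        return om

    termination = "max_iterations"
    for x0 in config.start_vectors(extra_starts):
        z0 = (x0 - lo) / span
        last = {"z": z0.copy()}

        def callback(zk, _last=last):
            step = np.linalg.norm(zk - _last["z"]) * span
            _last["z"] = zk.copy()
            if step < config.step_tol:
                raise _StepConverged

        try:
            res = minimize(
                fun,
                z0,
                method="SLSQP",
                bounds=[(0.0, 1.0)] * n,
                options={
                    "ftol": config.ftol,
                    "maxiter": config.max_iterations,
                    "eps": config.fd_step / span,
                },
                callback=callback,
            )
            termination = "ftol" if res.success else res.message
        except _StepConverged:
            termination = "step_tol"

    if not vectors:
        raise OptimizationError("no design evaluations were performed")
    omegas_arr = np.asarray(omegas)
    finite = np.isfinite(omegas_arr)
    if not finite.any() or omegas_arr.min() >= GEOMETRY_PENALTY:
        raise OptimizationError("every candidate evaluation failed")
    best = int(np.argmin(omegas_arr))
    best_vec = vectors[best]
    record = OptimizationRecord(
        law_kind=config.law_kind,
        vectors=np.asarray(vectors),
        omegas=omegas_arr,
        bo_percents=np.asarray(bos),
        best_vector=best_vec,
        best_omega=float(omegas_arr[best]),
        best_bo_percent=float(bos[best]),
        termination=str(termination),
        evaluations=len(vectors),
        best_law=context.make_law(best_vec) if objective_fn is None else None,
    )
    return record


# ---------------------------------------------------------------------------
# full factorial study


@dataclass(frozen=True)
class StudyConfig:
    """Factor lists of the factorial design (defaults give 3 × 3 × 4 = 36)."""

    young_moduli: tuple[float, ...] = (500.0, 1000.0, 1500.0)
    load_kinds: tuple[LoadKind, ...] = (
        LoadKind.COMPRESSION,
        LoadKind.SHEAR,
        LoadKind.MIXED,
    )
    law_kinds: tuple[LawKind, ...] = (
        LawKind.CONSTANT,
        LawKind.LINEAR,
        LawKind.BILINEAR,
        LawKind.TRILINEAR,
    )

    def __post_init__(self) -> None:
        if not (self.young_moduli and self.load_kinds and self.law_kinds):
            raise ValidationError("every factor list must be non-empty")
        object.__setattr__(
            self, "load_kinds", tuple(LoadKind(k) for k in self.load_kinds)
        )
        object.__setattr__(
            self, "law_kinds", tuple(LawKind(k) for k in self.law_kinds)
        )


def enumerate_study(study: StudyConfig) -> list[tuple[float, LoadKind, LawKind]]:
    """The (E, load, law) combinations, laws ordered coarse → rich."""
    laws = sorted(study.law_kinds, key=lambda k: k.n_coefficients)
    return list(itertools.product(study.young_moduli, study.load_kinds, laws))


def _reseed(best_law: PorosityLaw, new_kind: LawKind, h: float) -> np.ndarray:
    """Expand a poorer law's optimum into a richer family's start vector by
    sampling it at the richer family's breakpoints."""
    template = vector_to_coefficients(
        new_kind, np.full(new_kind.n_coefficients, 150.0), y_max=h
    )
    return np.array([evaluate_radius(best_law, y) for y in template.breakpoints])


def run_study(
    study: StudyConfig,
    spec: ScaffoldSpec,
    optimizer: OptimizationConfig | None = None,
    load_template: LoadCase | None = None,
    mechreg: MechanoRegParams | None = None,
    granulation: MaterialProperties = GRANULATION_TISSUE,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run one optimization per factor combination.

    Returns ``(results, ibo_table)``: per-run metrics, and per-(E, load)
    iBO% rows whenever the study contains both the constant and the
    tri-linear family.  Individual run failures are recorded (BO% = NaN)
    and the study continues.
    """
    optimizer = optimizer or OptimizationConfig()
    load_template = load_template or LoadCase()
    mechreg = mechreg or MechanoRegParams()

    rows = []
    best_by_cell: dict[tuple[float, LoadKind], dict[LawKind, OptimizationRecord]] = {}
    for E, load_kind, law_kind in enumerate_study(study):
        load = replace(load_template, kind=load_kind)
        context = EvaluationContext(
            spec=spec,
            load=load,
            materials={
                "scaffold": scaffold_material(E),
                "granulation": granulation,
            },
            law_kind=law_kind,
            mechreg=mechreg,
            seed=seed,
        )
        cfg = replace(optimizer, law_kind=law_kind)
        cell = best_by_cell.setdefault((E, load_kind), {})
        extra = [
            _reseed(rec.best_law, law_kind, spec.h)
            for rec in cell.values()
            if rec.best_law is not None
        ]
        try:
            rec = optimize(cfg, context, extra_starts=extra)
            cell[law_kind] = rec
            rows.append(
                {
                    "E_MPa": E,
                    "load": load_kind.value,
                    "law": law_kind.value,
                    "coefficients_um": list(np.round(rec.best_vector, 3)),
                    "BO_percent": rec.best_bo_percent,
                    "Omega": rec.best_omega,
                    "PVPD_percent": pvpd(rec.best_law),
                    "evaluations": rec.evaluations,
                    "termination": rec.termination,
                }
            )
        except OptimizationError as exc:
            logger.error("run (E=%s, %s, %s) failed: %s", E, load_kind, law_kind, exc)
            rows.append(
                {
                    "E_MPa": E,
                    "load": load_kind.value,
                    "law": law_kind.value,
                    "coefficients_um": None,
                    "BO_percent": np.nan,
                    "Omega": np.nan,
                    "PVPD_percent": np.nan,
                    "evaluations": 0,
                    "termination": f"failed: {exc}",
                }
            )
    results = pd.DataFrame(rows)

    ibo_rows = []
    for (E, load_kind), cell in best_by_cell.items():
        if LawKind.CONSTANT in cell and LawKind.TRILINEAR in cell:
            ibo_rows.append(
                {
                    "E_MPa": E,
                    "load": load_kind.value,
                    "BO_constant": cell[LawKind.CONSTANT].best_bo_percent,
                    "BO_trilinear": cell[LawKind.TRILINEAR].best_bo_percent,
                    "iBO_percent": ibo(
                        cell[LawKind.TRILINEAR].best_bo_percent,
                        cell[LawKind.CONSTANT].best_bo_percent,
                    ),
                }
            )
    return results, pd.DataFrame(ibo_rows)
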