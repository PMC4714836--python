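"""Parametric two-phase scaffold geometry and meshing.

The scaffold is a prism of square base ``t × t`` and height ``h`` whose
circular pores (radius set by a :class:`~fgscaffold.porosity.PorosityLaw`)
are filled with granulation tissue.  Pores sit on a regular lattice, their
radius constant within a row and varying across rows with the law; the
radius of a row is the law evaluated at the row's center height.

Meshing is an unstructured Delaunay triangulation of a deterministic point
set: rectangle-boundary points, an interior grid, and rings of points on
every pore circle so triangle edges follow the pore boundaries.  Each
triangle is labelled ``scaffold`` or ``granulation`` by its centroid.  In
``coarse_3d`` mode the triangulation is extruded along ``z`` into a
conforming tetrahedral mesh (pores become channels, constant along ``z``).

Coordinates are in μm with ``y = 0`` at the loaded face and ``y = h`` at
the clamped face.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay
from shapely.geometry import Point, box
from shapely.ops import unary_union

from .errors import GeometryError, MeshingError, ValidationError
from .porosity import A_UPPER, PorosityLaw, evaluate_radius

__all__ = [
    "REGION_SCAFFOLD",
    "REGION_GRANULATION",
    "REGION_NAMES",
    "ScaffoldSpec",
    "ScaffoldMesh",
    "build_scaffold_mesh",
    "build_consolidation_column",
    "build_patch_block",
    "analytic_pore_area",
]

REGION_SCAFFOLD = 0
REGION_GRANULATION = 1
REGION_NAMES = ("scaffold", "granulation")

_DIMENSIONALITIES = ("plane_strain_2d", "coarse_3d")


@dataclass(frozen=True)
class ScaffoldSpec:
    """Scaffold dimensions, pore lattice and meshing targets (μm).

    Defaults follow the reference design: a 2548 μm square base, 3822 μm
    height and a 40 μm target element size.  The default 3 × 5 lattice is
    chosen so that even at the maximum admissible radius (300 μm) adjacent
    pores keep walls well above ``min_wall``.
    """

    t: float = 2548.0
    h: float = 3822.0
    pore_rows: int = 5
    pore_cols: int = 3
    dimensionality: str = "plane_strain_2d"
    element_size: float = 40.0
    min_wall: float = 10.0
    n_layers: int = 6  # extrusion layers in coarse_3d mode

    def __post_init__(self) -> None:
        if self.t <= 0 or self.h <= 0:
            raise ValidationError("t and h must be positive")
        if self.pore_rows < 1 or self.pore_cols < 1:
            raise ValidationError("pore lattice must have at least one pore")
        if self.dimensionality not in _DIMENSIONALITIES:
            raise ValidationError(
                f"dimensionality must be one of {_DIMENSIONALITIES}"
            )
        if self.element_size <= 0:
            raise ValidationError("element_size must be positive")

    @classmethod
    def desk(cls, element_size: float = 200.0, **kwargs) -> "ScaffoldSpec":
        """Coarse preset for interactive desk-scale runs."""
        return cls(element_size=element_size, **kwargs)

    @property
    def col_spacing(self) -> float:
        return self.t / self.pore_cols

    @property
    def row_spacing(self) -> float:
        return self.h / self.pore_rows

    def pore_centers(self) -> np.ndarray:
        """Lattice pore centers, shape ``(rows*cols, 2)`` as ``(x, y)`` μm."""
        xs = (np.arange(self.pore_cols) + 0.5) * self.col_spacing
        ys = (np.arange(self.pore_rows) + 0.5) * self.row_spacing
        gx, gy = np.meshgrid(xs, ys)
        return np.column_stack([gx.ravel(), gy.ravel()])

    def row_center_heights(self) -> np.ndarray:
        return (np.arange(self.pore_rows) + 0.5) * self.row_spacing

    def admissible_radius(self, row: int) -> float:
        """Largest pore radius for *row* keeping ≥ ``min_wall`` everywhere."""
        y_c = self.row_center_heights()[row]
        limits = [
            (self.col_spacing - self.min_wall) / 2.0,  # lateral neighbours
            (self.row_spacing - self.min_wall) / 2.0,  # vertical neighbours
            self.col_spacing / 2.0 - self.min_wall,  # x boundary
            min(y_c, self.h - y_c) - self.min_wall,  # y boundary
        ]
        return min(limits)

    def admits_radius(self, radius: float) -> bool:
        return all(
            radius <= self.admissible_radius(i) for i in range(self.pore_rows)
        )


@dataclass
class ScaffoldMesh:
    """Simplicial two-region mesh.

    ``points`` are node coordinates in μm (``(n, 2)`` triangles in 2D,
    ``(n, 3)`` tetrahedra in 3D), ``region`` holds per-element labels
    (``REGION_SCAFFOLD`` / ``REGION_GRANULATION``) and ``measures`` the
    per-element measure — area × unit depth (μm²·μm implied) in 2D, volume
    (μm³) in 3D.  ``boundary_tags`` maps tag names to vertex-node indices.
    """

    points: np.ndarray
    elements: np.ndarray
    region: np.ndarray
    measures: np.ndarray
    boundary_tags: dict[str, np.ndarray]
    dim: int
    spec: ScaffoldSpec | None = None
    law: PorosityLaw | None = None
    pore_layout: np.ndarray | None = field(default=None, repr=False)  # (x, y, r)

    @property
    def n_elements(self) -> int:
        return len(self.elements)

    @property
    def total_measure(self) -> float:
        return float(self.measures.sum())

    @property
    def granulation_measure(self) -> float:
        return float(self.measures[self.region == REGION_GRANULATION].sum())

    @property
    def granulation_elements(self) -> np.ndarray:
        return np.flatnonzero(self.region == REGION_GRANULATION)

    def centroids(self) -> np.ndarray:
        return self.points[self.elements].mean(axis=1)


# ---------------------------------------------------------------------------
# 2D triangulation helpers


def _triangle_areas(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    return 0.5 * np.abs(
        (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
        - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
    )


def _orient_ccw(points: np.ndarray, tris: np.ndarray) -> np.ndarray:
    p = points[tris]
    signed = (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
        p[:, 2, 0] - p[:, 0, 0]
    ) * (p[:, 1, 1] - p[:, 0, 1])
    flip = signed < 0
    tris = tris.copy()
    tris[flip] = tris[flip][:, [0, 2, 1]]
    return tris


def _triangulate(points: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    try:
        tri = Delaunay(points)
    except Exception as exc:  # pragma: no cover - qhull failure diagnostics
        raise MeshingError(f"Delaunay triangulation failed: {exc}") from exc
    tris = _orient_ccw(points, tri.simplices.astype(np.int64))
    areas = _triangle_areas(points, tris)
    keep = areas > 1e-9 * areas.max()
    return tris[keep], areas[keep]


def _rect_boundary_points(t: float, h: float, s: float) -> np.ndarray:
    nx = max(2, int(round(t / s)))
    ny = max(2, int(round(h / s)))
    xs = np.linspace(0.0, t, nx + 1)
    ys = np.linspace(0.0, h, ny + 1)
    pts = [
        np.column_stack([xs, np.zeros_like(xs)]),
        np.column_stack([xs, np.full_like(xs, h)]),
        np.column_stack([np.zeros(ny - 1), ys[1:-1]]),
        np.column_stack([np.full(ny - 1, t), ys[1:-1]]),
    ]
    return np.vstack(pts)


def _interior_grid(t: float, h: float, s: float) -> np.ndarray:
    nx = max(2, int(round(t / s)))
    ny = max(2, int(round(h / s)))
    xs = np.linspace(0.0, t, nx + 1)[1:-1]
    ys = np.linspace(0.0, h, ny + 1)[1:-1]
    gx, gy = np.meshgrid(xs, ys)
    return np.column_stack([gx.ravel(), gy.ravel()])


def _circle_points(cx: float, cy: float, r: float, s: float) -> np.ndarray:
    # ring spacing of a quarter element size: the meshed pore boundary is the
    # inscribed polygon, whose area deficit ~(2π)²/6n² vanishes on refinement
    n = max(16, int(math.ceil(2.0 * math.pi * r / (0.25 * s))))
    theta = 2.0 * math.pi * np.arange(n) / n
    return np.column_stack([cx + r * np.cos(theta), cy + r * np.sin(theta)])


def _check_layout(spec: ScaffoldSpec, radii_by_row: np.ndarray) -> None:
    """Raise :class:`GeometryError` naming the first infeasible pore row."""
    heights = spec.row_center_heights()
    for i, (y_c, r) in enumerate(zip(heights, radii_by_row)):
        if r > spec.admissible_radius(i):
            raise GeometryError(
                f"pore row {i} (y_c = {y_c:.1f} μm): radius {r:.1f} μm leaves "
                f"a wall below the {spec.min_wall:.1f} μm minimum "
                f"(admissible radius {spec.admissible_radius(i):.1f} μm)"
            )


def pore_layout(spec: ScaffoldSpec, law: PorosityLaw) -> np.ndarray:
    """Feasible pore layout ``(x, y, r)`` per pore; validates wall thickness."""
    heights = spec.row_center_heights()
    radii = np.array([evaluate_radius(law, y) for y in heights])
    _check_layout(spec, radii)
    centers = spec.pore_centers()
    r = np.repeat(radii, spec.pore_cols)
    return np.column_stack([centers, r])


def analytic_pore_area(spec: ScaffoldSpec, law: PorosityLaw) -> float:
    """Exact granulation cross-section area (μm²) from the disc union."""
    layout = pore_layout(spec, law)
    discs = [Point(x, y).buffer(r, quad_segs=256) for x, y, r in layout]
    domain = box(0.0, 0.0, spec.t, spec.h)
    return float(unary_union(discs).intersection(domain).area)


def _boundary_tags_2d(points: np.ndarray, t: float, h: float) -> dict[str, np.ndarray]:
    tol = 1e-6 * max(t, h)
    return {
        "top_loaded": np.flatnonzero(points[:, 1] < tol),
        "bottom_clamped": np.flatnonzero(points[:, 1] > h - tol),
        "outer_drained": np.flatnonzero(
            (points[:, 0] < tol) | (points[:, 0] > t - tol)
        ),
    }


def build_scaffold_mesh(
    spec: ScaffoldSpec, law: PorosityLaw, seed: int = 0
) -> ScaffoldMesh:
    """Mesh the two-phase scaffold geometry for *spec* under *law*.

    Fully deterministic for fixed inputs (the ``seed`` argument is recorded
    for provenance; the construction itself uses no randomness).
    """
    layout = pore_layout(spec, law)
    s = spec.element_size

    pts = [_rect_boundary_points(spec.t, spec.h, s)]
    for x, y, r in layout:
        pts.append(_circle_points(x, y, r, s))
    grid = _interior_grid(spec.t, spec.h, s)
    # drop grid points hugging a pore boundary (slivers); keep deep interior
    keep = np.ones(len(grid), dtype=bool)
    for x, y, r in layout:
        d = np.hypot(grid[:, 0] - x, grid[:, 1] - y)
        keep &= np.abs(d - r) > 0.55 * s
    pts.append(grid[keep])
    points = np.vstack(pts)

    tris, areas = _triangulate(points)
    centroids = points[tris].mean(axis=1)
    region = np.full(len(tris), REGION_SCAFFOLD, dtype=np.int8)
    for x, y, r in layout:
        inside = np.hypot(centroids[:, 0] - x, centroids[:, 1] - y) < r
        region[inside] = REGION_GRANULATION

    mesh2d = ScaffoldMesh(
        points=points,
        elements=tris,
        region=region,
        measures=areas,
        boundary_tags=_boundary_tags_2d(points, spec.t, spec.h),
        dim=2,
        spec=spec,
        law=law,
        pore_layout=layout,
    )
    if spec.dimensionality == "coarse_3d":
        return _extrude(mesh2d, depth=spec.t, n_layers=spec.n_layers)
    return mesh2d


# ---------------------------------------------------------------------------
# 3D extrusion (pores become channels along z, constant along x and z)


def _tet_volumes(points: np.ndarray, tets: np.ndarray) -> np.ndarray:
    p = points[tets]
    a = p[:, 1] - p[:, 0]
    b = p[:, 2] - p[:, 0]
    c = p[:, 3] - p[:, 0]
    return np.abs(np.einsum("ij,ij->i", a, np.cross(b, c))) / 6.0


def _extrude(
    mesh2d: ScaffoldMesh,
    depth: float,
    n_layers: int,
    extents: tuple[float, float] | None = None,
) -> ScaffoldMesh:
    np2 = len(mesh2d.points)
    zs = np.linspace(0.0, depth, n_layers + 1)
    points = np.vstack(
        [np.column_stack([mesh2d.points, np.full(np2, z)]) for z in zs]
    )
    # sort each triangle's vertices by global id so shared quad faces get
    # matching diagonals: standard conforming 3-tet prism split
    tris = np.sort(mesh2d.elements, axis=1)
    tets, region = [], []
    for k in range(n_layers):
        lo, hi = k * np2, (k + 1) * np2
        v0, v1, v2 = tris[:, 0] + lo, tris[:, 1] + lo, tris[:, 2] + lo
        w0, w1, w2 = tris[:, 0] + hi, tris[:, 1] + hi, tris[:, 2] + hi
        tets.append(np.column_stack([v0, v1, v2, w2]))
        tets.append(np.column_stack([v0, v1, w2, w1]))
        tets.append(np.column_stack([v0, w1, w2, w0]))
        region.extend([mesh2d.region] * 3)
    tets = np.vstack(tets)
    region = np.concatenate(region)

    spec = mesh2d.spec
    if extents is not None:
        t, h = extents
    else:
        t, h = spec.t, spec.h
    tol = 1e-6 * max(t, h)
    tags = {
        "top_loaded": np.flatnonzero(points[:, 1] < tol),
        "bottom_clamped": np.flatnonzero(points[:, 1] > h - tol),
        "outer_drained": np.flatnonzero(
            (points[:, 0] < tol)
            | (points[:, 0] > t - tol)
            | (points[:, 2] < tol)
            | (points[:, 2] > depth - tol)
        ),
    }
    return ScaffoldMesh(
        points=points,
        elements=tets,
        region=region,
        measures=_tet_volumes(points, tets),
        boundary_tags=tags,
        dim=3,
        spec=spec,
        law=mesh2d.law,
        pore_layout=mesh2d.pore_layout,
    )


# ---------------------------------------------------------------------------
# Analytical-oracle fixture meshes


def _structured_rectangle(
    width: float, height: float, nx: int, ny: int
) -> tuple[np.ndarray, np.ndarray]:
    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    gx, gy = np.meshgrid(xs, ys)
    points = np.column_stack([gx.ravel(), gy.ravel()])

    def nid(i: int, j: int) -> int:
        return i * (nx + 1) + j

    tris = []
    for i in range(ny):
        for j in range(nx):
            a, b = nid(i, j), nid(i, j + 1)
            c, d = nid(i + 1, j + 1), nid(i + 1, j)
            tris.append([a, b, c])
            tris.append([a, c, d])
    return points, np.asarray(tris, dtype=np.int64)


def build_consolidation_column(
    n_elements: int, length: float, width: float | None = None, nx: int = 2
) -> ScaffoldMesh:
    """Terzaghi benchmark column: drained + loaded at ``y = 0``, supported
    and impermeable at ``y = length`` (μm); a thin 2D strip meant to be run
    with lateral rollers so it behaves one-dimensionally."""
    if n_elements < 2:
        raise ValidationError("consolidation column needs n_elements >= 2")
    if length <= 0:
        raise ValidationError("column length must be positive")
    if width is None:
        width = length / n_elements * nx
    points, tris = _structured_rectangle(width, length, nx, n_elements)
    areas = _triangle_areas(points, tris)
    tol = 1e-9 * length
    tags = {
        "top_loaded": np.flatnonzero(points[:, 1] < tol),
        "bottom_clamped": np.flatnonzero(points[:, 1] > length - tol),
        "outer_drained": np.asarray([], dtype=np.int64),  # sealed sides
    }
    return ScaffoldMesh(
        points=points,
        elements=_orient_ccw(points, tris),
        region=np.zeros(len(tris), dtype=np.int8),
        measures=areas,
        boundary_tags=tags,
        dim=2,
    )


def build_patch_block(
    t: float = 2548.0,
    h: float = 3822.0,
    nx: int = 4,
    ny: int = 6,
    dimensionality: str = "plane_strain_2d",
    n_layers: int = 4,
) -> ScaffoldMesh:
    """Homogeneous pore-free block with scaffold boundary tags (patch test).

    In ``coarse_3d`` mode the block is extruded to depth ``t``, so the total
    measure equals the full prism volume ``t·t·h``.
    """
    points, tris = _structured_rectangle(t, h, nx, ny)
    mesh = ScaffoldMesh(
        points=points,
        elements=_orient_ccw(points, tris),
        region=np.zeros(len(tris), dtype=np.int8),
        measures=_triangle_areas(points, tris),
        boundary_tags=_boundary_tags_2d(points, t, h),
        dim=2,
    )
    if dimensionality == "coarse_3d":
        return _extrude(mesh, depth=t, n_layers=n_layers, extents=(t, h))
    return mesh
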