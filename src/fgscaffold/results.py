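"""Result serialization: VTK fields, CSV tables, INP export and manifests.

Every run writes a ``manifest.json`` referencing all emitted artifacts
along with the configuration snapshot, package version and seed, so a run
can be reproduced exactly; all table contents are deterministic given the
configuration and seed (only the manifest timestamps differ between
re-runs).
"""

from __future__ import annotations

import json
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .geometry import REGION_NAMES, ScaffoldMesh
from .mechanoregulation import Phenotype, PhenotypeField
from .porosity import PorosityLaw, radius_profile

__all__ = [
    "write_vtk",
    "write_inp",
    "write_profile_csv",
    "write_phenotype_legend",
    "write_results",
    "RunManifest",
]

_VTK_CELL_TYPE = {2: 5, 3: 10}  # triangle, tetrahedron


def write_vtk(mesh: ScaffoldMesh, path: str | Path, cell_data: dict | None = None):
    """Write the mesh and per-element fields as a legacy-ASCII VTK file.

    The region label is always included; pass additional per-element
    arrays (ε_I..III, v, p, S, phenotype, ...) via *cell_data*.
    """
    path = Path(path)
    pts = np.asarray(mesh.points, dtype=float)
    if pts.shape[1] == 2:
        pts = np.column_stack([pts, np.zeros(len(pts))])
    cells = mesh.elements
    k = cells.shape[1]
    data = {"region": mesh.region.astype(float)}
    data.update(cell_data or {})
    with open(path, "w") as fh:
        fh.write("# vtk DataFile Version 3.0\n")
        fh.write("fgscaffold fields (lengths in um)\n")
        fh.write("ASCII\nDATASET UNSTRUCTURED_GRID\n")
        fh.write(f"POINTS {len(pts)} float\n")
        np.savetxt(fh, pts, fmt="%.8g")
        fh.write(f"CELLS {len(cells)} {len(cells) * (k + 1)}\n")
        np.savetxt(
            fh,
            np.column_stack([np.full(len(cells), k), cells]),
            fmt="%d",
        )
        fh.write(f"CELL_TYPES {len(cells)}\n")
        np.savetxt(fh, np.full(len(cells), _VTK_CELL_TYPE[mesh.dim]), fmt="%d")
        fh.write(f"CELL_DATA {len(cells)}\n")
        for name, values in data.items():
            fh.write(f"SCALARS {name} float 1\nLOOKUP_TABLE default\n")
            np.savetxt(fh, np.asarray(values, dtype=float), fmt="%.8g")
    return path


def write_inp(mesh: ScaffoldMesh, path: str | Path):
    """Minimal Abaqus-INP dialect export (nodes, elements, region sets),
    for cross-checking geometries in external solvers."""
    path = Path(path)
    eltype = "CPE3" if mesh.dim == 2 else "C3D4"
    with open(path, "w") as fh:
        fh.write("*HEADING\nfgscaffold mesh export (um)\n*NODE\n")
        for i, p in enumerate(mesh.points, start=1):
            coords = ", ".join(f"{c:.6f}" for c in p)
            fh.write(f"{i}, {coords}\n")
        fh.write(f"*ELEMENT, TYPE={eltype}\n")
        for i, el in enumerate(mesh.elements + 1, start=1):
            fh.write(f"{i}, " + ", ".join(str(v) for v in el) + "\n")
        for code, name in enumerate(REGION_NAMES):
            ids = np.flatnonzero(mesh.region == code) + 1
            if not len(ids):
                continue
            fh.write(f"*ELSET, ELSET={name.upper()}\n")
            for start in range(0, len(ids), 16):
                fh.write(", ".join(map(str, ids[start : start + 16])) + "\n")
    return path


def write_profile_csv(law: PorosityLaw, path: str | Path, n: int = 201):
    """Two-column (y_um, A_um) radius profile of a law."""
    prof = radius_profile(law, n)
    pd.DataFrame(prof, columns=["y_um", "A_um"]).to_csv(path, index=False)
    return Path(path)


def write_phenotype_legend(path: str | Path):
    """CSV legend mapping phenotype integer codes to tissue names."""
    rows = [{"code": int(p), "phenotype": p.name.lower()} for p in Phenotype]
    pd.DataFrame(rows).to_csv(path, index=False)
    return Path(path)


def phenotype_cell_data(mesh: ScaffoldMesh, field: PhenotypeField) -> dict:
    """Full-mesh per-element S and phenotype arrays for VTK export
    (scaffold elements get S = NaN sentinel −1 and phenotype −1)."""
    S = np.full(mesh.n_elements, -1.0)
    ph = np.full(mesh.n_elements, -1.0)
    S[field.element_indices] = field.S
    ph[field.element_indices] = field.phenotype
    return {"S": S, "phenotype": ph}


class RunManifest:
    """Collects artifact paths and per-stage status for one run."""

    def __init__(self, out_dir: str | Path, config_snapshot: dict, seed: int):
        self.out_dir = Path(out_dir)
        self.out_dir.mkdir(parents=True, exist_ok=True)
        self.data = {
            "software": {"name": "fgscaffold", "version": __version__},
            "seed": seed,
            "config": config_snapshot,
            "created_utc": datetime.now(timezone.utc).isoformat(),
            "stages": {},
            "files": [],
        }

    def record_stage(self, name: str, status: str = "ok") -> None:
        self.data["stages"][name] = status

    def add_file(self, path: str | Path) -> Path:
        path = Path(path)
        rel = str(path.relative_to(self.out_dir))
        if rel not in self.data["files"]:
            self.data["files"].append(rel)
        return path

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        self.data["written_utc"] = datetime.now(timezone.utc).isoformat()
        with open(path, "w") as fh:
            json.dump(self.data, fh, indent=2, default=str)
        return path


def write_results(result, out_dir: str | Path, config_snapshot: dict | None = None, seed: int = 0) -> Path:
    """Serialize a completed run to *out_dir* and write its manifest.

    *result* is either a single-run
    :class:`~fgscaffold.optimize.OptimizationRecord` or the
    ``(results, ibo_table)`` DataFrame pair returned by
    :func:`~fgscaffold.optimize.run_study`.  File contents are
    deterministic for a fixed configuration and seed.
    """
    from .optimize import OptimizationRecord  # local: avoids import cycle risk

    manifest = RunManifest(out_dir, config_snapshot or {}, seed)
    out = manifest.out_dir
    if isinstance(result, OptimizationRecord):
        row = {
            "law": result.law_kind.value,
            "coefficients_um": list(np.round(result.best_vector, 6)),
            "BO_percent": result.best_bo_percent,
            "Omega": result.best_omega,
            "evaluations": result.evaluations,
            "termination": result.termination,
        }
        pd.DataFrame([row]).to_csv(manifest.add_file(out / "metrics.csv"), index=False)
        iter_df = pd.DataFrame(
            result.vectors,
            columns=[f"A{i + 1}_um" for i in range(result.vectors.shape[1])],
        )
        iter_df["Omega"] = result.omegas
        iter_df["BO_percent"] = result.bo_percents
        iter_df.to_csv(manifest.add_file(out / "iterates.csv"), index=False)
        if result.best_law is not None:
            write_profile_csv(
                result.best_law, manifest.add_file(out / "radius_profile.csv")
            )
        manifest.record_stage("optimization")
    else:
        results_df, ibo_df = result
        results_df.to_csv(
            manifest.add_file(out / "study_results.csv"), index=False
        )
        ibo_df.to_csv(manifest.add_file(out / "ibo.csv"), index=False)
        manifest.record_stage("study")
    write_phenotype_legend(manifest.add_file(out / "phenotype_legend.csv"))
    manifest.write()
    return out / "manifest.json"
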