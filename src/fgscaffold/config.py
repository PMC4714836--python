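"""Structured-text (YAML) run configuration.

A run configuration bundles every domain object of the pipeline —
scaffold spec, per-region materials, load case, porosity law, optimizer
and study settings — with a single seed.  Any omitted block falls back to
the reference defaults (granulation E = 0.2 MPa, ν = 0.167, 1 MPa
compression ramped over 1 s, [5, 300] μm coefficient bounds, ...), so a
minimal file naming only the law kind and the load is complete.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .errors import ValidationError
from .fem import GRANULATION_TISSUE, LoadCase, MaterialProperties, scaffold_material
from .geometry import ScaffoldSpec
from .mechanoregulation import MechanoRegParams
from .optimize import OptimizationConfig, StudyConfig
from .porosity import LawKind, PorosityLaw

__all__ = ["RunConfig", "load_config", "dump_config"]


@dataclass
class RunConfig:
    """Validated full configuration of a single run or a study."""

    scaffold: ScaffoldSpec = field(default_factory=ScaffoldSpec)
    materials: dict[str, MaterialProperties] = field(
        default_factory=lambda: {
            "granulation": GRANULATION_TISSUE,
            "scaffold": scaffold_material(1000.0),
        }
    )
    load: LoadCase = field(default_factory=LoadCase)
    law: PorosityLaw = field(
        default_factory=lambda: PorosityLaw(LawKind.CONSTANT, (150.0,))
    )
    optimizer: OptimizationConfig = field(default_factory=OptimizationConfig)
    study: StudyConfig = field(default_factory=StudyConfig)
    mechanoregulation: MechanoRegParams = field(default_factory=MechanoRegParams)
    seed: int = 0

    def to_dict(self) -> dict:
        d = {
            "scaffold": dataclasses.asdict(self.scaffold),
            "materials": {
                name: dataclasses.asdict(m) for name, m in self.materials.items()
            },
            "load": {
                "kind": self.load.kind.value,
                "compressive_traction": self.load.compressive_traction,
                "shear_traction": self.load.shear_traction,
                "ramp": self.load.ramp,
                "n_steps": self.load.n_steps,
            },
            "law": {
                "kind": self.law.kind.value,
                "coefficients": list(self.law.coefficients),
                "y_min": self.law.y_min,
                "y_max": self.law.y_max,
                "interior_breakpoints": list(self.law.interior_breakpoints),
            },
            "optimizer": {
                "law_kind": self.optimizer.law_kind.value,
                "initial": None
                if self.optimizer.initial is None
                else list(self.optimizer.initial),
                "bounds": list(self.optimizer.bounds),
                "ftol": self.optimizer.ftol,
                "step_tol": self.optimizer.step_tol,
                "max_iterations": self.optimizer.max_iterations,
                "fd_step": self.optimizer.fd_step,
                "multistart": list(self.optimizer.multistart),
            },
            "study": {
                "young_moduli": list(self.study.young_moduli),
                "load_kinds": [k.value for k in self.study.load_kinds],
                "law_kinds": [k.value for k in self.study.law_kinds],
            },
            "mechanoregulation": dataclasses.asdict(self.mechanoregulation),
            "seed": self.seed,
        }
        return d


def _build(cls, data: dict, what: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ValidationError(f"unknown {what} field(s): {sorted(unknown)}")
    try:
        return cls(**data)
    except TypeError as exc:
        raise ValidationError(f"invalid {what} block: {exc}") from exc


def config_from_dict(data: dict) -> RunConfig:
    data = dict(data or {})
    known = {
        "scaffold",
        "materials",
        "load",
        "law",
        "optimizer",
        "study",
        "mechanoregulation",
        "seed",
    }
    unknown = set(data) - known
    if unknown:
        raise ValidationError(f"unknown top-level config field(s): {sorted(unknown)}")

    scaffold = _build(ScaffoldSpec, data.get("scaffold", {}), "scaffold")

    mats = dict(data.get("materials", {}))
    materials: dict[str, MaterialProperties] = {}
    for region, default in (
        ("granulation", GRANULATION_TISSUE),
        ("scaffold", scaffold_material(1000.0)),
    ):
        block = mats.pop(region, None)
        if block is None:
            materials[region] = default
        else:
            merged = {**dataclasses.asdict(default), **block}
            materials[region] = _build(
                MaterialProperties, merged, f"materials.{region}"
            )
    if mats:
        raise ValidationError(f"unknown material region(s): {sorted(mats)}")

    load = _build(LoadCase, data.get("load", {}), "load")

    law_block = dict(data.get("law", {}))
    kind = LawKind(law_block.pop("kind", "constant"))
    coeffs = law_block.pop("coefficients", None)
    if coeffs is None:
        coeffs = [150.0] * kind.n_coefficients
    law = PorosityLaw(
        kind,
        tuple(coeffs),
        y_min=law_block.pop("y_min", 0.0),
        y_max=law_block.pop("y_max", scaffold.h),
        interior_breakpoints=law_block.pop("interior_breakpoints", None),
    )
    if law_block:
        raise ValidationError(f"unknown law field(s): {sorted(law_block)}")

    opt_block = dict(data.get("optimizer", {}))
    opt_block.setdefault("law_kind", kind.value)
    if "bounds" in opt_block:
        opt_block["bounds"] = tuple(opt_block["bounds"])
    if opt_block.get("initial") is not None:
        opt_block["initial"] = tuple(opt_block["initial"])
    if "multistart" in opt_block:
        opt_block["multistart"] = tuple(opt_block["multistart"])
    optimizer = _build(OptimizationConfig, opt_block, "optimizer")

    study_block = dict(data.get("study", {}))
    for key in ("young_moduli", "load_kinds", "law_kinds"):
        if key in study_block:
            study_block[key] = tuple(study_block[key])
    study = _build(StudyConfig, study_block, "study")

    mech = _build(
        MechanoRegParams, data.get("mechanoregulation", {}), "mechanoregulation"
    )
    return RunConfig(
        scaffold=scaffold,
        materials=materials,
        load=load,
        law=law,
        optimizer=optimizer,
        study=study,
        mechanoregulation=mech,
        seed=int(data.get("seed", 0)),
    )


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML run configuration, filling defaults."""
    path = Path(path)
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return config_from_dict(data or {})


def dump_config(config: RunConfig, path: str | Path) -> None:
    """Serialize a configuration back to YAML (round-trip stable)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
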