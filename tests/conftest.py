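import numpy as np
import pytest

import fgscaffold as fg


@pytest.fixture(scope="session")
def desk_spec():
    """Coarse 2D spec used throughout the suite (fast, ~1k elements)."""
    return fg.ScaffoldSpec.desk(element_size=200.0)


@pytest.fixture(scope="session")
def materials():
    return {
        "scaffold": fg.scaffold_material(1000.0),
        "granulation": fg.GRANULATION_TISSUE,
    }


@pytest.fixture(scope="session")
def const_law(desk_spec):
    return fg.PorosityLaw("constant", (200.0,), 0.0, desk_spec.h)


@pytest.fixture(scope="session")
def const_mesh(desk_spec, const_law):
    return fg.build_scaffold_mesh(desk_spec, const_law)


@pytest.fixture(scope="session")
def compression_solution(const_mesh, materials):
    return fg.solve(const_mesh, materials, fg.LoadCase("compression"))


@pytest.fixture(scope="session")
def shear_solution(const_mesh, materials):
    return fg.solve(const_mesh, materials, fg.LoadCase("shear"))


@pytest.fixture(scope="session")
def mixed_solution(const_mesh, materials):
    return fg.solve(const_mesh, materials, fg.LoadCase("mixed"))


@pytest.fixture(scope="session")
def scaled_study_tables(desk_spec):
    """Scaled-down factorial slice at E = 1000 MPa: constant vs tri-linear
    laws under all three loads (shared by ordering tests)."""
    study = fg.StudyConfig(
        young_moduli=(1000.0,),
        load_kinds=("compression", "shear", "mixed"),
        law_kinds=("constant", "trilinear"),
    )
    opt = fg.OptimizationConfig(max_iterations=15)
    return fg.run_study(study, desk_spec, optimizer=opt, seed=1)
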