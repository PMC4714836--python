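from functools import lru_cache

import numpy as np
import pytest

import fgscaffold as fg
from fgscaffold.benchmarks import (
    consolidation_coefficient,
    terzaghi_pressure_ratio,
    undrained_pressure_ratio,
)
from fgscaffold.errors import SolverError, ValidationError


@lru_cache(maxsize=2)
def run_terzaghi(n_elements=60, n_steps=240, record=True):
    """Shared Terzaghi column run; drainage and load at y = 0."""
    mat = fg.GRANULATION_TISSUE
    c_v = consolidation_coefficient(mat)
    length_um = 1000.0
    t_char = (length_um * 1e-6) ** 2 / c_v
    mesh = fg.build_consolidation_column(n_elements, length_um)
    load = fg.LoadCase("compression", 1.0, ramp=1e-6 * t_char, n_steps=1)
    targets = np.array([0.1, 0.5, 1.0]) * t_char
    times = np.unique(
        np.concatenate(
            [[1e-6 * t_char], np.geomspace(1e-4, 1.0, n_steps) * t_char, targets]
        )
    )
    sol = fg.solve(
        mesh,
        mat,
        load,
        times=times,
        lateral_roller=True,
        drained_tags=("top_loaded",),
        record_pressure=record,
    )
    return mesh, sol, t_char, undrained_pressure_ratio(mat)


class TestDrainedPatchTest:
    def test_uniaxial_closed_form(self):
        """Drained uniaxial compression of a homogeneous block with ν = 0:
        axial strain magnitude σ/E, zero flux (closed-form oracle)."""
        mesh = fg.build_patch_block(nx=4, ny=6)
        mat = fg.MaterialProperties(E=1000.0, nu=0.0)
        sol = fg.solve(mesh, mat, fg.LoadCase("compression", 1.0), drained=True)
        expected = -1.0 / 1000.0
        assert np.allclose(sol.principal_strains[:, 2], expected, rtol=1e-6)
        assert np.allclose(sol.principal_strains[:, 0], 0.0, atol=1e-9)
        assert np.all(sol.flux < 1e-12)

    def test_drained_limit_of_transient(self):
        """With very high permeability the end-of-ramp transient solution
        coincides with the static drained solution."""
        mesh = fg.build_patch_block(nx=4, ny=6)
        mat = fg.MaterialProperties(E=1000.0, nu=0.3, k=1e-6, n=0.5)
        st = fg.solve(mesh, mat, fg.LoadCase("compression", 1.0))
        dr = fg.solve(mesh, mat, fg.LoadCase("compression", 1.0), drained=True)
        scale = np.abs(dr.strain_tensors).max()
        assert np.allclose(st.strain_tensors, dr.strain_tensors, atol=1e-6 * scale)


class TestTerzaghiOracle:
    def test_isochrones_match_series(self):
        """Normalized pore-pressure isochrones at T_v = 0.1, 0.5, 1.0 match
        the analytical consolidation series within 2%."""
        mesh, sol, t_char, p0 = run_terzaghi()
        z = mesh.points[:, 1] / mesh.points[:, 1].max()
        recorded = np.array(sorted(sol.pressure_history))
        for T_v in (0.1, 0.5, 1.0):
            t = recorded[np.argmin(np.abs(recorded - T_v * t_char))]
            p_num = sol.pressure_history[t] / p0
            p_ana = terzaghi_pressure_ratio(z, T_v)
            assert np.max(np.abs(p_num - p_ana)) < 0.02

    def test_mid_depth_ratio_at_Tv_half(self):
        mesh, sol, t_char, p0 = run_terzaghi()
        z = mesh.points[:, 1] / mesh.points[:, 1].max()
        recorded = np.array(sorted(sol.pressure_history))
        t = recorded[np.argmin(np.abs(recorded - 0.5 * t_char))]
        mid = np.argmin(np.abs(z - 0.5))
        num = sol.pressure_history[t][mid]
        ana = terzaghi_pressure_ratio(0.5, 0.5) * p0
        assert num == pytest.approx(ana, rel=0.02)

    def test_undrained_initial_pressure(self):
        """Right after an effectively instantaneous load the mid-column
        pressure equals the undrained (Skempton-type) response."""
        mesh, sol, t_char, p0 = run_terzaghi()
        recorded = sorted(sol.pressure_history)
        z = mesh.points[:, 1] / mesh.points[:, 1].max()
        interior = (z > 0.3) & (z < 0.9)
        p_first = sol.pressure_history[recorded[1]]
        assert np.median(p_first[interior]) == pytest.approx(p0, rel=0.02)

    def test_flux_magnitude_against_series_gradient(self):
        """Darcy flux (μm/s, unit-converted) at mid-column at T_v = 0.5
        matches the differentiated consolidation series within 5%."""
        mat = fg.GRANULATION_TISSUE
        c_v = consolidation_coefficient(mat)
        p0 = undrained_pressure_ratio(mat)
        length_um = 1000.0
        H = length_um * 1e-6
        t_char = H**2 / c_v
        mesh = fg.build_consolidation_column(60, length_um)
        times = np.unique(
            np.concatenate(
                [[1e-6 * t_char], np.geomspace(1e-4, 0.5, 240) * t_char]
            )
        )
        sol = fg.solve(
            mesh,
            mat,
            fg.LoadCase("compression", 1.0, ramp=1e-6 * t_char, n_steps=1),
            times=times,
            lateral_roller=True,
            drained_tags=("top_loaded",),
        )
        cent = mesh.centroids()[:, 1] / length_um
        el = int(np.argmin(np.abs(cent - 0.5)))
        T_v = sol.time * c_v / H**2
        m = np.arange(200)
        lam = (2 * m + 1) * np.pi / 2
        dpdz = (p0 * 1e6 / H) * np.sum(
            2.0 * np.cos(lam * cent[el]) * np.exp(-(lam**2) * T_v)
        )
        expected = mat.k * abs(dpdz) / 1e-6  # μm/s
        assert fg.darcy_flux_magnitude(sol, el) == pytest.approx(expected, rel=0.05)


class TestLinearity:
    def test_zero_load_gives_null_fields(self, const_mesh, materials):
        sol = fg.solve(
            const_mesh,
            materials,
            fg.LoadCase("compression", 0.0, shear_traction=0.0),
        )
        assert np.abs(sol.strain_tensors).max() == 0.0
        assert sol.flux.max() == 0.0
        assert np.abs(sol.pressure_nodal).max() == 0.0

    def test_doubling_tractions_doubles_response(self, const_mesh, materials):
        s1 = fg.solve(const_mesh, materials, fg.LoadCase("compression", 1.0))
        s2 = fg.solve(const_mesh, materials, fg.LoadCase("compression", 2.0))
        assert np.allclose(s2.strain_tensors, 2 * s1.strain_tensors, rtol=1e-9)
        assert np.allclose(s2.pressure_nodal, 2 * s1.pressure_nodal, rtol=1e-9,
                           atol=1e-12)

    def test_superposition_of_compression_and_shear(
        self, compression_solution, shear_solution, mixed_solution
    ):
        """F_M = F_V + F_H: the mixed-load fields equal the sum of the pure
        compression and pure shear fields."""
        total = compression_solution.strain_tensors + shear_solution.strain_tensors
        scale = np.abs(mixed_solution.strain_tensors).max()
        assert np.allclose(
            mixed_solution.strain_tensors, total, atol=1e-9 * scale
        )
        p_total = compression_solution.pressure_nodal + shear_solution.pressure_nodal
        assert np.allclose(
            mixed_solution.pressure_nodal,
            p_total,
            atol=1e-9 * np.abs(mixed_solution.pressure_nodal).max(),
        )


class TestSolutionInvariants:
    def test_principal_strains_sorted_and_plane_strain(self, compression_solution):
        eps = compression_solution.principal_strains
        assert np.all(eps[:, 0] >= eps[:, 1])
        assert np.all(eps[:, 1] >= eps[:, 2])
        # the out-of-plane principal strain (identically zero) is present
        assert np.all(np.isclose(eps, 0.0, atol=1e-15).any(axis=1))

    def test_drained_boundary_pressure_is_zero(self, const_mesh, compression_solution):
        drained = const_mesh.boundary_tags["outer_drained"]
        assert np.abs(compression_solution.pressure_nodal[drained]).max() < 1e-12

    def test_flux_nonnegative(self, compression_solution):
        assert np.all(compression_solution.flux >= 0.0)

    def test_3d_mesh_rejected(self):
        spec = fg.ScaffoldSpec(
            dimensionality="coarse_3d", element_size=300.0, n_layers=2
        )
        law = fg.PorosityLaw("constant", (150.0,), 0.0, spec.h)
        mesh = fg.build_scaffold_mesh(spec, law)
        with pytest.raises(SolverError):
            fg.solve(mesh, fg.GRANULATION_TISSUE, fg.LoadCase())


class TestPrincipalStrainsOp:
    def test_diagonal_tensor(self):
        got = fg.principal_strains(np.diag([0.02, 0.01, -0.01]))
        assert got == pytest.approx((0.02, 0.01, -0.01))

    def test_pure_shear_closed_form(self):
        t = np.array([[0.0, 0.01], [0.01, 0.0]])
        assert fg.principal_strains(t) == pytest.approx((0.01, 0.0, -0.01))

    def test_rotation_invariance(self):
        rng = np.random.default_rng(42)
        a = rng.normal(size=(3, 3))
        tensor = 0.01 * (a + a.T)
        th = np.pi / 4
        R = np.array(
            [
                [np.cos(th), -np.sin(th), 0.0],
                [np.sin(th), np.cos(th), 0.0],
                [0.0, 0.0, 1.0],
            ]
        )
        rotated = R @ tensor @ R.T
        assert fg.principal_strains(rotated) == pytest.approx(
            fg.principal_strains(tensor)
        )

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValidationError):
            fg.principal_strains(np.array([[0.0, 1e-3], [0.0, 0.0]]))


class TestMaterialRelations:
    def test_biot_relations(self):
        """α and 1/M from the printed grain/fluid bulk moduli follow the
        standard Biot relations (hand-computed reference)."""
        m = fg.GRANULATION_TISSUE
        K_d = 0.2 / (3 * (1 - 2 * 0.167))
        assert m.biot_alpha == pytest.approx(1 - K_d / 2300.0)
        expected_storage = (m.biot_alpha - 0.8) / 2300e6 + 0.8 / 2300e6
        assert m.storage == pytest.approx(expected_storage)

    def test_material_validation(self):
        with pytest.raises(ValidationError):
            fg.MaterialProperties(E=-1.0, nu=0.3)
        with pytest.raises(ValidationError):
            fg.MaterialProperties(E=1.0, nu=0.6)
        with pytest.raises(ValidationError):
            fg.MaterialProperties(E=1.0, nu=0.3, n=1.5)

    def test_load_case_validation(self):
        with pytest.raises(ValidationError):
            fg.LoadCase("compression", -1.0)
        with pytest.raises(ValidationError):
            fg.LoadCase("compression", 1.0, ramp=0.0)
        assert fg.LoadCase("mixed").tractions() == (1.0, 0.5)
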