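import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import fgscaffold as fg
from fgscaffold.errors import ValidationError
from fgscaffold.mechanoregulation import Phenotype

P = fg.MechanoRegParams()

small = st.floats(min_value=-0.05, max_value=0.05)


class TestOctahedralShearStrain:
    @pytest.mark.parametrize(
        "eps, expected",
        [
            ((0.01, 0.01, 0.01), 0.0),  # hydrostatic
            # (2/3)·sqrt(2)·0.01, evaluated independently
            ((0.01, 0.0, 0.0), 0.0094280904),
            # (2/3)·sqrt(6)·0.01 closed form
            ((0.01, 0.0, -0.01), 0.0163299316),
        ],
    )
    def test_reference_values(self, eps, expected):
        assert fg.octahedral_shear_strain(*eps) == pytest.approx(expected, abs=1e-9)

    @settings(derandomize=True, max_examples=100)
    @given(e1=small, e2=small, e3=small)
    def test_permutation_invariance_and_nonnegativity(self, e1, e2, e3):
        base = fg.octahedral_shear_strain(e1, e2, e3)
        assert base >= 0.0
        for perm in [(e2, e1, e3), (e3, e2, e1), (e2, e3, e1)]:
            assert fg.octahedral_shear_strain(*perm) == pytest.approx(base)

    @settings(derandomize=True, max_examples=100)
    @given(e1=small, e2=small, e3=small, lam=st.floats(min_value=0.0, max_value=10.0))
    def test_scale_equivariance(self, e1, e2, e3, lam):
        g = fg.octahedral_shear_strain(e1, e2, e3)
        assert fg.octahedral_shear_strain(lam * e1, lam * e2, lam * e3) == (
            pytest.approx(lam * g, abs=1e-12)
        )

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            fg.octahedral_shear_strain(np.nan, 0.0, 0.0)


class TestBiophysicalStimulus:
    def test_boundary_cases(self):
        # γ = a or v = b alone each produce exactly S = 1
        assert fg.biophysical_stimulus(0.0375, 0.0) == pytest.approx(1.0)
        assert fg.biophysical_stimulus(0.0, 3.0) == pytest.approx(1.0)
        assert fg.biophysical_stimulus(0.0, 0.0) == 0.0

    def test_linearity(self):
        s = fg.biophysical_stimulus(0.0375, 3.0)
        assert s == pytest.approx(2.0)
        assert fg.biophysical_stimulus(2 * 0.0375, 2 * 3.0) == pytest.approx(2 * s)

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValidationError):
            fg.biophysical_stimulus(-0.01, 0.0)
        with pytest.raises(ValidationError):
            fg.biophysical_stimulus(0.0, -1.0)


class TestClassify:
    @pytest.mark.parametrize(
        "S, expected",
        [
            (0.005, Phenotype.RESORPTION),
            (0.3, Phenotype.MATURE_BONE),
            (0.8, Phenotype.IMMATURE_BONE),
            (2.0, Phenotype.CARTILAGE),
            (5.0, Phenotype.FIBROUS),
        ],
    )
    def test_band_interiors(self, S, expected):
        assert fg.classify(S) is expected

    def test_lower_closed_boundaries(self):
        assert fg.classify(0.0) is Phenotype.RESORPTION
        assert fg.classify(P.n_resorb) is Phenotype.MATURE_BONE
        assert fg.classify(P.n_mature) is Phenotype.IMMATURE_BONE
        assert fg.classify(1.0) is Phenotype.CARTILAGE
        assert fg.classify(P.c) is Phenotype.FIBROUS

    def test_bands_partition_dense_grid(self):
        """Every S ≥ 0 (dense grid plus boundary ± 1e-12) maps to exactly
        one phenotype, and band membership is monotone in S."""
        bounds = [P.n_resorb, P.n_mature, 1.0, P.c]
        grid = np.concatenate(
            [
                np.linspace(0.0, 4.0, 40001),
                [b + d for b in bounds for d in (-1e-12, 0.0, 1e-12)],
            ]
        )
        grid.sort()
        codes = fg.classify(grid)
        assert set(np.unique(codes)) == {int(p) for p in Phenotype}
        assert np.all(np.diff(codes.astype(int)) >= 0)  # monotone in S

    def test_negative_rejected(self):
        with pytest.raises(ValidationError):
            fg.classify(-0.1)

    def test_param_validation(self):
        with pytest.raises(ValidationError):
            fg.MechanoRegParams(n_resorb=0.6)  # above n_mature
        with pytest.raises(ValidationError):
            fg.MechanoRegParams(c=0.9)  # below 1


class TestStimulusField:
    def test_zero_load_all_resorption(self, const_mesh, materials):
        sol = fg.solve(
            const_mesh,
            materials,
            fg.LoadCase("compression", 0.0, shear_traction=0.0),
        )
        field = fg.stimulus_field(sol, const_mesh)
        assert np.all(field.S == 0.0)
        assert np.all(field.phenotype == Phenotype.RESORPTION)

    def test_field_covers_exactly_granulation(self, const_mesh, compression_solution):
        field = fg.stimulus_field(compression_solution, const_mesh)
        assert len(field) == len(const_mesh.granulation_elements)
        assert np.array_equal(field.element_indices, const_mesh.granulation_elements)

    def test_field_consistent_with_scalar_ops(self, const_mesh, compression_solution):
        """The vectorized field agrees with element-by-element evaluation of
        γ, S and the classification rule."""
        field = fg.stimulus_field(compression_solution, const_mesh)
        rng = np.random.default_rng(0)
        for j in rng.choice(len(field), size=10, replace=False):
            el = field.element_indices[j]
            eI, eII, eIII = compression_solution.principal_strains[el]
            g = fg.octahedral_shear_strain(eI, eII, eIII)
            v = fg.darcy_flux_magnitude(compression_solution, el)
            s = fg.biophysical_stimulus(g, v)
            assert field.S[j] == pytest.approx(s)
            assert field.phenotype[j] == fg.classify(s)

    def test_monotone_band_ordering_in_stimulus(self):
        """Raising γ or v never moves the phenotype toward lower-S bands."""
        gammas = np.linspace(0.0, 0.2, 50)
        codes = [int(fg.classify(fg.biophysical_stimulus(g, 0.0))) for g in gammas]
        assert np.all(np.diff(codes) >= 0)
        vs = np.linspace(0.0, 12.0, 50)
        codes = [int(fg.classify(fg.biophysical_stimulus(0.0, v))) for v in vs]
        assert np.all(np.diff(codes) >= 0)
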