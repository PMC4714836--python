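import numpy as np
import pytest

import fgscaffold as fg
from fgscaffold.errors import ValidationError
from fgscaffold.optimize import GEOMETRY_PENALTY, _reseed


def surrogate_config(kind, **kw):
    """Closed-form surrogates are smooth, so a small FD step is appropriate
    (the 5 μm default targets the remeshing noise of the FE objective)."""
    defaults = dict(law_kind=kind, fd_step=0.1, step_tol=0.5, ftol=1e-6,
                    max_iterations=80)
    defaults.update(kw)
    return fg.OptimizationConfig(**defaults)


class TestSurrogateOptima:
    def test_recovers_1d_quadratic_optimum(self):
        rec = fg.optimize(
            surrogate_config("constant"),
            objective_fn=lambda x: (x[0] - 150.0) ** 2,
        )
        assert rec.best_vector[0] == pytest.approx(150.0, abs=0.5)

    def test_recovers_separable_4d_quadratic(self):
        """Optima at 100/150/200/250 μm; a coarse brute-force grid confirms
        the same minimizer."""
        targets = np.array([100.0, 150.0, 200.0, 250.0])

        def f(x):
            return float(np.sum((np.asarray(x) - targets) ** 2))

        grid = np.arange(5.0, 301.0, 5.0)
        brute = np.array([grid[np.argmin((grid - t) ** 2)] for t in targets])
        assert np.allclose(brute, targets)

        rec = fg.optimize(surrogate_config("trilinear"), objective_fn=f)
        assert np.allclose(rec.best_vector, targets, atol=0.5)

    def test_exterior_optimum_returns_bound(self):
        rec = fg.optimize(
            surrogate_config("constant"),
            objective_fn=lambda x: (x[0] - 350.0) ** 2,
        )
        assert rec.best_vector[0] == pytest.approx(300.0, abs=1e-6)

    def test_bounds_never_violated_at_any_evaluation(self):
        rec = fg.optimize(
            surrogate_config("trilinear"),
            objective_fn=lambda x: float(np.sum((np.asarray(x) - 290.0) ** 2)),
        )
        assert np.all(rec.vectors >= 5.0 - 1e-12)
        assert np.all(rec.vectors <= 300.0 + 1e-12)

    def test_best_omega_is_minimum_of_history(self):
        rec = fg.optimize(
            surrogate_config("constant"),
            objective_fn=lambda x: (x[0] - 42.0) ** 2,
        )
        assert rec.best_omega <= rec.omegas.min() + 1e-15


class TestEvaluateDesign:
    def test_deterministic_repeat(self, desk_spec, materials):
        ctx = fg.EvaluationContext(
            spec=desk_spec,
            load=fg.LoadCase("compression"),
            materials=materials,
            law_kind=fg.LawKind.CONSTANT,
        )
        first = fg.evaluate_design([220.0], ctx)
        ctx_fresh = fg.EvaluationContext(
            spec=desk_spec,
            load=fg.LoadCase("compression"),
            materials=materials,
            law_kind=fg.LawKind.CONSTANT,
        )
        second = fg.evaluate_design([220.0], ctx_fresh)
        assert first == second

    def test_infeasible_geometry_is_penalized(self, materials):
        spec = fg.ScaffoldSpec(pore_cols=5, element_size=200.0)
        ctx = fg.EvaluationContext(
            spec=spec,
            load=fg.LoadCase("compression"),
            materials=materials,
            law_kind=fg.LawKind.CONSTANT,
        )
        omega, bo = fg.evaluate_design([300.0], ctx)
        assert omega == GEOMETRY_PENALTY
        assert bo == 0.0

    def test_omega_equals_negative_bo(self, desk_spec, materials):
        ctx = fg.EvaluationContext(
            spec=desk_spec,
            load=fg.LoadCase("shear"),
            materials=materials,
            law_kind=fg.LawKind.CONSTANT,
        )
        omega, bo = fg.evaluate_design([200.0], ctx)
        assert omega == -bo
        assert 0.0 < bo < 100.0


class TestConfigValidation:
    def test_initial_outside_bounds_rejected(self):
        with pytest.raises(ValidationError):
            fg.OptimizationConfig(law_kind="constant", initial=(400.0,))

    def test_initial_length_checked(self):
        with pytest.raises(ValidationError):
            fg.OptimizationConfig(law_kind="trilinear", initial=(100.0, 200.0))

    def test_empty_factor_list_rejected(self):
        with pytest.raises(ValidationError):
            fg.StudyConfig(young_moduli=())


class TestStudyEnumeration:
    def test_default_design_has_36_runs(self):
        assert len(fg.enumerate_study(fg.StudyConfig())) == 36

    def test_small_factorial(self):
        study = fg.StudyConfig(
            young_moduli=(1000.0,),
            load_kinds=("shear",),
            law_kinds=("constant", "trilinear"),
        )
        combos = fg.enumerate_study(study)
        assert len(combos) == 2
        # coarse family first, so richer laws can reuse its optimum
        assert [c[2] for c in combos] == [fg.LawKind.CONSTANT, fg.LawKind.TRILINEAR]

    def test_reseed_expands_constant_exactly(self):
        law = fg.PorosityLaw("constant", (123.0,), 0.0, 3822.0)
        vec = _reseed(law, fg.LawKind.TRILINEAR, 3822.0)
        assert np.allclose(vec, 123.0)

    def test_reseed_preserves_linear_profile(self):
        law = fg.PorosityLaw("linear", (100.0, 250.0), 0.0, 3822.0)
        vec = _reseed(law, fg.LawKind.TRILINEAR, 3822.0)
        rich = fg.vector_to_coefficients(fg.LawKind.TRILINEAR, vec, y_max=3822.0)
        y = np.linspace(0.0, 3822.0, 17)
        assert np.allclose(
            fg.evaluate_radius(rich, y), fg.evaluate_radius(law, y)
        )


class TestStudyTables:
    def test_study_rows_and_ibo(self, scaled_study_tables):
        results, ibo_table = scaled_study_tables
        assert len(results) == 6  # 1 E x 3 loads x 2 laws
        assert set(results["law"]) == {"constant", "trilinear"}
        assert len(ibo_table) == 3
        for _, row in ibo_table.iterrows():
            assert row["iBO_percent"] == pytest.approx(
                row["BO_trilinear"] - row["BO_constant"]
            )

    def test_all_coefficients_within_bounds(self, scaled_study_tables):
        results, _ = scaled_study_tables
        for coeffs in results["coefficients_um"]:
            assert np.all(np.asarray(coeffs) >= 5.0)
            assert np.all(np.asarray(coeffs) <= 300.0)
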