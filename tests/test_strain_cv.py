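"""Strain -> CV_T law: sigmoid factor, field evaluation, fitting,
discretization and mesh-to-mesh interpolation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from straincv.errors import FitError, ProjectionError, ValidationError
from straincv.geometry import build_fixture
from straincv.strain_cv import (CVField, StrainCVParams, StrainField,
                                cvt_field, discretize_cvt, fit_strain_cv,
                                g_strain, interpolate_field)

P = StrainCVParams()


class TestGStrain:
    def test_reference_strain_gives_reference_cv(self):
        assert g_strain(P.eps_ref, P) == pytest.approx(1.0)
        assert P.cvt_ref * g_strain(P.eps_ref, P) == pytest.approx(0.30)

    def test_zero_strain_limit(self):
        # 0.3 + 0.22 tanh(-20.6 * 0.1665) = 0.0805 m/s
        cv = P.cvt_ref * g_strain(0.0, P)
        assert cv == pytest.approx(0.3 + 0.22 * np.tanh(-20.6 * 0.1665))
        assert cv == pytest.approx(0.0805, abs=5e-4)

    def test_large_strain_asymptote(self):
        assert P.cvt_ref * g_strain(10.0, P) == pytest.approx(0.52, abs=1e-6)

    @given(st.floats(-0.5, 1.5), st.floats(-0.5, 1.5))
    def test_bounded(self, e1, e2):
        # open interval mathematically; tanh saturates to +/-1 in float64
        lo = 1.0 - P.cvt_var / (2 * P.cvt_ref)
        hi = 1.0 + P.cvt_var / (2 * P.cvt_ref)
        assert lo - 1e-12 <= g_strain(e1, P) <= hi + 1e-12

    @given(st.floats(-0.1, 0.45), st.floats(1e-6, 0.2))
    def test_strictly_monotone(self, e1, gap):
        # strict away from the float-saturated tails of tanh
        assert g_strain(e1, P) < g_strain(e1 + gap, P)

    def test_param_validation(self):
        with pytest.raises(ValidationError):
            StrainCVParams(cvt_ref=0.0)
        with pytest.raises(ValidationError):
            StrainCVParams(cvt_ref=0.1, cvt_var=0.44)  # negative lower bound
        with pytest.raises(ValidationError):
            StrainCVParams(alpha=-1.0)


class TestCVTField:
    def test_core_annihilation(self):
        f = cvt_field(StrainField(np.array([0.1, 0.1665, 0.3])),
                      np.array([0.0, 1.0, 0.0]), P)
        assert f.cvt[0] == 0.0 and f.cvt[2] == 0.0
        assert f.cvt[1] == pytest.approx(0.30)

    def test_linear_in_fact(self):
        f = cvt_field(StrainField(np.array([0.1665])), np.array([0.5]), P)
        assert f.cvt[0] == pytest.approx(0.15)

    def test_length_mismatch(self):
        with pytest.raises(ValidationError):
            cvt_field(StrainField(np.array([0.1, 0.2])), np.array([1.0]), P)

    def test_strain_field_validation(self):
        with pytest.raises(ValidationError):
            StrainField(np.array([0.1, -0.2]))
        with pytest.raises(ValidationError):
            StrainField(np.array([np.inf]))


class TestDiscretize:
    def test_uniform_unchanged(self):
        f = discretize_cvt(CVField(np.full(10, 0.3)), 9)
        np.testing.assert_array_equal(f.cvt, np.full(10, 0.3))

    def test_two_level_example(self):
        f = discretize_cvt(CVField(np.array([0.0, 0.1, 0.5])), 2)
        np.testing.assert_allclose(f.cvt, [0.0, 0.2, 0.4])

    def test_error_bounded_by_half_bin(self):
        rng = np.random.default_rng(3)
        vals = rng.uniform(0.05, 0.5, 500)
        f = discretize_cvt(CVField(vals), 9)
        width = (vals.max() - vals.min()) / 9
        assert np.max(np.abs(f.cvt - vals)) <= width / 2 + 1e-12

    def test_zeros_preserved_and_warning(self):
        f = discretize_cvt(CVField(np.array([0.0, 0.2, 0.4])), 4)
        assert f.cvt[0] == 0.0
        with pytest.warns(UserWarning):
            discretize_cvt(CVField(np.zeros(5)), 9)
        with pytest.raises(ValidationError):
            discretize_cvt(CVField(np.ones(5)), 0)


class TestFit:
    def test_noiseless_recovery(self):
        eps = np.linspace(0.08, 0.26, 40)
        cv = 0.30 + 0.22 * np.tanh(20.6 * (eps - 0.1665))
        params, diag = fit_strain_cv(eps, cv, objective="points")
        assert params.alpha == pytest.approx(20.6, rel=0.01)
        assert params.eps_ref == pytest.approx(0.1665, rel=0.01)

    def test_noisy_recovery(self):
        rng = np.random.default_rng(11)
        eps = rng.uniform(0.06, 0.28, 50)
        cv = 0.30 + 0.22 * np.tanh(20.6 * (eps - 0.1665))
        cv += rng.normal(0.0, 0.05 * (cv.max() - cv.min()), cv.size)
        params, diag = fit_strain_cv(eps, cv, objective="points")
        assert params.alpha == pytest.approx(20.6, rel=0.10)
        assert params.eps_ref == pytest.approx(0.1665, rel=0.10)

    def test_line_objective_interpolates_collinear_midrange(self):
        # near eps_ref the sigmoid is nearly linear; a fit through the
        # regression line passes close to collinear samples there
        eps = np.array([0.15, 0.1665, 0.18])
        slope = 0.22 * 20.6
        cv = 0.30 + slope * (eps - 0.1665)
        params, diag = fit_strain_cv(eps, cv, objective="line")
        pred = 0.30 + 0.22 * np.tanh(params.alpha * (eps - params.eps_ref))
        assert np.max(np.abs(pred - cv)) < 0.01
        assert diag.r_squared == pytest.approx(1.0)

    def test_degenerate_samples(self):
        with pytest.raises(FitError):
            fit_strain_cv(np.full(5, 0.1), np.linspace(0.1, 0.2, 5))
        with pytest.raises(FitError):
            fit_strain_cv(np.array([0.1]), np.array([0.2]))


class TestInterpolate:
    def test_linear_reproduction_1d(self):
        coarse = build_fixture("cable", 20.0, 2.0)
        fine = build_fixture("cable", 20.0, 0.5)
        vals = 3.0 * coarse.nodes[:, 0] + 1.0
        out = interpolate_field(coarse, vals, fine)
        np.testing.assert_allclose(out, 3.0 * fine.nodes[:, 0] + 1.0)

    def test_constant_2d(self):
        coarse = build_fixture("sheet", (10.0, 10.0), 2.0)
        fine = build_fixture("sheet", (10.0, 10.0), 0.5)
        out = interpolate_field(coarse, np.full(coarse.n_nodes, 7.0), fine)
        np.testing.assert_allclose(out, 7.0)

    def test_convexity_bounds(self):
        rng = np.random.default_rng(5)
        coarse = build_fixture("sheet", (10.0, 10.0), 1.0)
        fine = build_fixture("sheet", (10.0, 10.0), 0.3)
        vals = rng.uniform(0.0, 1.0, coarse.n_nodes)
        out = interpolate_field(coarse, vals, fine)
        assert out.min() >= vals.min() - 1e-12
        assert out.max() <= vals.max() + 1e-12

    def test_projection_error_far_outside(self):
        coarse = build_fixture("cable", 10.0, 1.0)
        fine = build_fixture("cable", 30.0, 1.0)
        with pytest.raises(ProjectionError):
            interpolate_field(coarse, coarse.nodes[:, 0], fine)
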