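"""Boltzmann and exponential fitting: oracles, recovery, invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from statekin.curves import (
    BoltzmannFit,
    BoltzmannParams,
    ExponentialFit,
    FitError,
    SLOPE_CONST,
    compare_forms,
    eval_boltzmann,
    fit_boltzmann,
    fit_exponential,
    normalize_to_fit_max,
)

GRID = np.arange(-140.0, 20.0 + 5.0, 10.0)


class TestEvalBoltzmann:
    def test_midpoint_symmetry(self):
        p = BoltzmannParams(i_res=0.1, z=3.0, v_half=-60.0)
        assert eval_boltzmann(p, -60.0) == pytest.approx(0.1 + 0.9 / 2)

    def test_saturation_limits(self):
        p = BoltzmannParams(i_res=0.07, z=2.0, v_half=-60.0)
        assert eval_boltzmann(p, -1e4) == pytest.approx(1.0, abs=1e-12)
        assert eval_boltzmann(p, 1e4) == pytest.approx(0.07, abs=1e-12)

    def test_against_arbitrary_precision(self):
        # independent high-precision evaluation of the same expression
        import sympy
        z, vh, V = sympy.Rational(42, 10), sympy.Rational(-583, 10), -70
        expected = float(1 / (1 + sympy.exp(z * (V - vh) / 24)).evalf(50))
        p = BoltzmannParams(i_res=0.0, z=4.2, v_half=-58.3)
        assert eval_boltzmann(p, -70.0) == pytest.approx(expected, abs=1e-14)

    def test_strictly_decreasing_for_positive_z(self):
        p = BoltzmannParams(i_res=0.05, z=1.5, v_half=-55.0)
        V = np.linspace(-140, 20, 2000)
        y = eval_boltzmann(p, V)
        assert np.all(np.diff(y) < 0)

    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            BoltzmannParams(i_res=1.2, z=2.0, v_half=-60.0)
        with pytest.raises(ValueError):
            BoltzmannParams(i_res=0.0, z=-1.0, v_half=-60.0)


class TestFitBoltzmann:
    def test_noiseless_recovery_control_parameters(self):
        truth = BoltzmannParams(i_res=0.0, z=4.2, v_half=-58.3)
        p = fit_boltzmann(GRID, eval_boltzmann(truth, GRID))
        assert p.v_half == pytest.approx(-58.3, abs=1e-6)
        assert p.z == pytest.approx(4.2, abs=1e-6)
        assert p.i_res == pytest.approx(0.0, abs=1e-6)

    def test_residual_fraction_recovered(self):
        truth = BoltzmannParams(i_res=0.04, z=2.5, v_half=-70.0)
        p = fit_boltzmann(GRID, eval_boltzmann(truth, GRID))
        assert p.i_res == pytest.approx(0.04, abs=1e-6)

    def test_seeded_noise_recovery_within_tolerance(self):
        truth = BoltzmannParams(i_res=0.0, z=4.2, v_half=-58.3)
        clean = eval_boltzmann(truth, GRID)
        v_halves, zs = [], []
        for seed in range(1, 9):
            rng = np.random.default_rng(seed)
            p = fit_boltzmann(GRID, clean + rng.normal(0, 0.02, GRID.shape))
            v_halves.append(p.v_half)
            zs.append(p.z)
        assert np.mean(v_halves) == pytest.approx(-58.3, abs=2.0)
        assert np.mean(zs) == pytest.approx(4.2, abs=0.3)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(FitError):
            fit_boltzmann(GRID, np.ones_like(GRID))
        with pytest.raises(FitError):
            fit_boltzmann(GRID[:4], np.linspace(1, 0, 4))

    def test_estimator_api(self):
        est = BoltzmannFit(fit_i_max=True)
        assert est.get_params()["fit_i_max"] is True
        est.set_params(fit_i_max=False)
        assert est.get_params()["fit_i_max"] is False
        with pytest.raises(ValueError):
            est.set_params(nonsense=1)
        with pytest.raises(FitError):
            BoltzmannFit().predict(GRID)


class TestNormalizeToFitMax:
    def test_already_normalized_unchanged(self):
        truth = BoltzmannParams(i_res=0.0, z=3.0, v_half=-60.0)
        y = eval_boltzmann(truth, GRID)
        p = fit_boltzmann(GRID, y)
        np.testing.assert_allclose(normalize_to_fit_max(y, p), y, atol=1e-9)

    def test_scale_invariance(self):
        truth = BoltzmannParams(i_res=0.0, z=3.0, v_half=-60.0)
        y = eval_boltzmann(truth, GRID)
        p_full = fit_boltzmann(GRID, y, fit_i_max=True)
        p_half = fit_boltzmann(GRID, 0.5 * y, fit_i_max=True)
        np.testing.assert_allclose(
            normalize_to_fit_max(0.5 * y, p_half),
            normalize_to_fit_max(y, p_full), atol=1e-8)

    def test_inhibited_family_ratio_of_asymptotes(self):
        # a partially inhibited family normalized against the control maximum
        # reports exactly the inhibited fraction at its own asymptote
        control = BoltzmannParams(i_res=0.0, z=4.2, v_half=-58.3, i_max=1.0)
        inhibited_scale = 0.42
        y_ctrl = eval_boltzmann(control, GRID)
        y_drug = inhibited_scale * eval_boltzmann(
            BoltzmannParams(i_res=0.0, z=1.9, v_half=-91.9), GRID)
        p_ctrl = fit_boltzmann(GRID, y_ctrl, fit_i_max=True)
        rel = normalize_to_fit_max(y_drug, p_ctrl)
        p_drug = fit_boltzmann(GRID, y_drug, fit_i_max=True)
        assert p_drug.predicted_max / p_ctrl.predicted_max == pytest.approx(
            inhibited_scale, abs=1e-6)
        # refitting the rescaled family recovers the inhibited fraction as
        # its own hyperpolarized asymptote
        p_rel = fit_boltzmann(GRID, rel, fit_i_max=True)
        assert p_rel.predicted_max == pytest.approx(inhibited_scale, abs=1e-6)

    def test_nonpositive_maximum_rejected(self):
        p = BoltzmannParams(i_res=0.0, z=2.0, v_half=-60.0, i_max=0.0)
        with pytest.raises(ValueError):
            normalize_to_fit_max(np.ones(3), p)


class TestFitExponential:
    def test_squared_tau_recovered(self):
        t = np.arange(0.0, 300.0, 2.0)
        y = np.exp(-((t / 100.0) ** 2))
        p = fit_exponential(t, y, "squared")
        assert p.tau == pytest.approx(100.0, rel=1e-6)
        assert p.A == pytest.approx(1.0, rel=1e-6)
        assert p.B == pytest.approx(0.0, abs=1e-8)

    def test_double_development_taus_recovered(self):
        t = np.geomspace(0.1, 120.0, 60)
        t = np.insert(t, 0, 0.0)
        y = 0.55 * np.exp(-t / 3.46) + 0.38 * np.exp(-t / 30.9) + 0.07
        p = fit_exponential(t, y, "double")
        assert p.form == "double"
        assert p.tau == pytest.approx(3.46, rel=1e-4)
        assert p.tau2 == pytest.approx(30.9, rel=1e-4)

    def test_constant_series(self):
        t = np.linspace(0, 10, 20)
        p = fit_exponential(t, np.full(20, 0.7), "single")
        assert p.A == pytest.approx(0.0, abs=1e-9)
        assert p.B == pytest.approx(0.7, abs=1e-9)

    def test_equal_tau_double_collapses_to_single(self):
        t = np.linspace(0, 10, 40)
        y = 0.8 * np.exp(-t / 2.0) + 0.2
        p = fit_exponential(t, y, "double")
        assert p.collapsed_from_double
        assert p.form == "single"
        assert p.tau == pytest.approx(2.0, rel=1e-6)

    def test_input_validation(self):
        with pytest.raises(FitError):
            fit_exponential([0, 1, 2], [1, 0.5, 0.2], "single")  # too few
        with pytest.raises(FitError):
            fit_exponential([0, 1, 1, 2], [1, 0.5, 0.4, 0.2], "single")
        with pytest.raises(ValueError):
            ExponentialFit("cubic")

    def test_fix_offset(self):
        t = np.linspace(0, 20, 30)
        y = 0.9 * np.exp(-t / 4.0)
        p = fit_exponential(t, y, "single", fix_offset=0.0)
        assert p.B == 0.0
        assert p.tau == pytest.approx(4.0, rel=1e-8)


class TestCompareForms:
    def test_squared_generator_preferred(self):
        t = np.arange(0.0, 300.0, 2.0)
        y = np.exp(-((t / 90.0) ** 2))
        assert compare_forms(t, y).preferred == "squared"

    def test_single_generator_preferred(self):
        t = np.arange(0.0, 300.0, 2.0)
        y = np.exp(-t / 90.0)
        assert compare_forms(t, y).preferred == "single"

    def test_pure_noise_inconclusive(self):
        rng = np.random.default_rng(5)
        t = np.arange(0.0, 100.0, 2.0)
        y = 0.5 + rng.normal(0, 0.02, t.shape)
        assert compare_forms(t, y).preferred == "inconclusive"


class TestRecoveryInvariants:
    @pytest.mark.parametrize("form,make", [
        ("single", lambda t: 0.8 * np.exp(-t / 7.0) + 0.2),
        ("squared", lambda t: 0.9 * np.exp(-((t / 12.0) ** 2)) + 0.1),
        ("double", lambda t: 0.5 * np.exp(-t / 1.5)
            + 0.4 * np.exp(-t / 15.0) + 0.1),
    ])
    def test_refit_idempotence(self, form, make):
        t = np.geomspace(0.05, 60.0, 50)
        p1 = fit_exponential(t, make(t), form)
        p2 = fit_exponential(t, p1(t), p1.form)
        assert p2.tau == pytest.approx(p1.tau, abs=1e-8 * max(1, p1.tau))
        assert p2.A == pytest.approx(p1.A, abs=1e-8)
        assert p2.B == pytest.approx(p1.B, abs=1e-8)

    def test_boltzmann_refit_idempotence(self):
        truth = BoltzmannParams(i_res=0.03, z=3.1, v_half=-64.0)
        p1 = fit_boltzmann(GRID, eval_boltzmann(truth, GRID))
        p2 = fit_boltzmann(GRID, eval_boltzmann(p1, GRID))
        assert p2.v_half == pytest.approx(p1.v_half, abs=1e-8)
        assert p2.z == pytest.approx(p1.z, abs=1e-8)

    def test_parameter_recovery_bias_below_two_percent(self):
        """Monte-Carlo bias of all fit families at sigma=0.02, 8 seeds."""
        t = np.geomspace(0.05, 60.0, 60)
        cases = {
            "single": (lambda tt: 0.8 * np.exp(-tt / 7.0) + 0.2,
                       "single", 7.0),
            "squared": (lambda tt: 0.9 * np.exp(-((tt / 12.0) ** 2)) + 0.1,
                        "squared", 12.0),
            "double": (lambda tt: 0.5 * np.exp(-tt / 1.5)
                       + 0.4 * np.exp(-tt / 15.0) + 0.1, "double", 1.5),
        }
        for name, (make, form, tau_true) in cases.items():
            taus = []
            for seed in range(1, 9):
                rng = np.random.default_rng(seed)
                y = make(t) + rng.normal(0, 0.02, t.shape)
                taus.append(fit_exponential(t, y, form).tau)
            bias = abs(np.mean(taus) / tau_true - 1)
            assert bias < 0.02, (name, bias)
        vhs = []
        clean = eval_boltzmann(BoltzmannParams(i_res=0.0, z=4.2,
                                               v_half=-58.3), GRID)
        for seed in range(1, 9):
            rng = np.random.default_rng(seed)
            vhs.append(fit_boltzmann(GRID,
                                     clean + rng.normal(0, 0.02,
                                                        GRID.shape)).v_half)
        assert abs(np.mean(vhs) / -58.3 - 1) < 0.02

    @given(z=st.floats(0.5, 8.0), vh=st.floats(-110.0, -30.0),
           ir=st.floats(0.0, 0.4))
    @settings(max_examples=25, deadline=None)
    def test_fit_recovers_generator_over_parameter_space(self, z, vh, ir):
        truth = BoltzmannParams(i_res=ir, z=z, v_half=vh)
        p = fit_boltzmann(GRID, eval_boltzmann(truth, GRID))
        assert p.v_half == pytest.approx(vh, abs=0.01)
        assert p.z == pytest.approx(z, rel=0.01)
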