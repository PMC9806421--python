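"""Repriming decomposition and the relative state-affinity solve."""

import numpy as np
import pytest

from statekin.affinity import (
    AffinitySystem,
    RecoveryCurve,
    StateAffinitySolver,
    StateFractions,
    build_affinity_system,
    decompose_states,
    recover_ratios_end_to_end,
    solve_affinity,
)
from statekin.channel import InhibitorSchedule
from statekin.io import load_state_fraction_table

TAU_FAST, TAU_SLOW = 0.002, 0.7


def curve_from_fractions(V_h, F_R, F_FI, F_SI):
    """Reconstruct an ideal repriming curve with the given state fractions."""
    T = 1.0 / F_R
    A_fast = F_FI * T
    A_slow = F_SI * T
    t = np.geomspace(1e-4, 8.0, 40)
    y = (1.0 + A_fast * (1 - np.exp(-t / TAU_FAST))
         + A_slow * (1 - np.exp(-t / TAU_SLOW)))
    return RecoveryCurve(V_h=V_h, times=t, i2_over_i1con=y)


def cramer_solve(F, r):
    """Independent 3x3 solve by Cramer's rule."""
    F = np.asarray(F, dtype=float)
    r = np.asarray(r, dtype=float)
    det = np.linalg.det
    D = det(F)
    q = []
    for j in range(3):
        M = F.copy()
        M[:, j] = r
        q.append(det(M) / D)
    return np.array(q)


class TestDecompose:
    def test_published_fraction_rows_reproduced(self):
        # reconstructed curves return each table row within 0.001
        table = load_state_fraction_table()
        for row in table.itertuples():
            sf = decompose_states(
                curve_from_fractions(row.Vh_mV, row.F_R, row.F_FI, row.F_SI))
            assert sf.F_R == pytest.approx(row.F_R, abs=1e-3)
            assert sf.F_FI == pytest.approx(row.F_FI, abs=1e-3)
            assert sf.F_SI == pytest.approx(row.F_SI, abs=1e-3)

    def test_intermediate_example_values(self):
        # T=1.203 with fast asymptote 1.120
        sf = decompose_states(curve_from_fractions(-80.0, 0.832, 0.100, 0.069))
        assert sf.T == pytest.approx(1.203, abs=2e-3)
        assert sf.F_R == pytest.approx(0.832, abs=1e-3)

    def test_full_fast_recovery_is_pure_resting(self):
        t = np.geomspace(1e-4, 8.0, 30)
        y = np.ones_like(t)  # T = 1 exactly: everything recovers instantly
        sf = decompose_states(RecoveryCurve(-100.0, t, y))
        assert sf.F_R == pytest.approx(1.0, abs=1e-9)
        assert sf.F_FI == 0.0 and sf.F_SI == 0.0

    def test_asymptote_below_unity_rejected(self):
        t = np.geomspace(1e-3, 8.0, 30)
        y = 0.9 * (1 - np.exp(-t / 0.1))
        with pytest.raises(ValueError, match="normalization"):
            decompose_states(RecoveryCurve(-80.0, t, y))

    def test_fractions_sum_to_one_and_FR_is_inverse_T(self):
        for F in [(0.118, 0.342, 0.540), (0.832, 0.100, 0.069),
                  (0.5, 0.3, 0.2), (0.985, 0.0, 0.015)]:
            sf = decompose_states(curve_from_fractions(-80.0, *F))
            assert sf.F_R + sf.F_FI + sf.F_SI == pytest.approx(1.0, abs=1e-3)
            assert sf.F_R == pytest.approx(1.0 / sf.T, abs=1e-6)

    def test_invalid_curves_rejected(self):
        with pytest.raises(ValueError):
            RecoveryCurve(-80.0, np.array([0.1, 0.1, 0.2]), np.ones(3))
        with pytest.raises(ValueError):
            RecoveryCurve(-80.0, np.array([0.1, 0.2]), np.array([1.0, -0.5]))


class TestBuildSystem:
    def test_published_table_assembles_printed_rates(self):
        table = load_state_fraction_table()
        entries = [(StateFractions.from_fractions(r.Vh_mV, r.F_R, r.F_FI,
                                                  r.F_SI), r.rate_per_s)
                   for r in table.itertuples()]
        system = build_affinity_system(entries)
        np.testing.assert_allclose(system.rates, [0.0096, 0.0040, 0.0020])
        assert system.coefficients.shape == (3, 3)
        assert system.V_h == (-60.0, -80.0, -100.0)

    def test_identity_rows_give_diagonal_system(self):
        # pure-R, pure-FI and pure-SI rows reduce the solve to the rates
        F = np.eye(3)
        rates = [1.0, 10.0, 2.0]
        sol = StateAffinitySolver().fit(F, rates).solution_
        assert sol.ratio_FI == pytest.approx(10.0)
        assert sol.ratio_SI == pytest.approx(2.0)

    def test_too_few_or_dependent_rows_rejected(self):
        table = load_state_fraction_table()
        entries = [(StateFractions.from_fractions(r.Vh_mV, r.F_R, r.F_FI,
                                                  r.F_SI), r.rate_per_s)
                   for r in table.itertuples()]
        with pytest.raises(ValueError, match=">= 3"):
            build_affinity_system(entries[:2])
        dup = entries[:2] + [entries[1]]
        with pytest.raises(ValueError, match="rank"):
            build_affinity_system(dup)


class TestSolve:
    def test_published_table_ratios_match_cramer_oracle(self):
        table = load_state_fraction_table()
        entries = [(StateFractions.from_fractions(r.Vh_mV, r.F_R, r.F_FI,
                                                  r.F_SI), r.rate_per_s)
                   for r in table.itertuples()]
        system = build_affinity_system(entries)
        sol = solve_affinity(system)
        q = cramer_solve(system.coefficients, system.rates)
        assert sol.ratio_FI == pytest.approx(q[1] / q[0], rel=1e-12)
        assert sol.ratio_SI == pytest.approx(q[2] / q[0], rel=1e-12)
        # frozen oracle values for the printed table
        assert sol.ratio_FI == pytest.approx(10.5431, abs=1e-3)
        assert sol.ratio_SI == pytest.approx(2.1458, abs=1e-3)

    def test_random_systems_match_cramer(self, rng):
        for _ in range(50):
            F = rng.uniform(0.05, 1.0, (3, 3))
            if abs(np.linalg.det(F)) < 1e-3:
                continue
            r = rng.uniform(0.1, 5.0, 3)
            sol = StateAffinitySolver().fit(F, r).solution_
            q = cramer_solve(F, r)
            np.testing.assert_allclose(sol.q, q, rtol=1e-10)

    def test_scale_invariance_exact(self):
        F = np.array([[0.118, 0.342, 0.540],
                      [0.832, 0.100, 0.069],
                      [0.985, 0.0, 0.015]])
        r = np.array([0.0096, 0.0040, 0.0020])
        a = StateAffinitySolver().fit(F, r).solution_
        b = StateAffinitySolver().fit(F, 7.0 * r).solution_
        assert b.ratio_FI == pytest.approx(a.ratio_FI, rel=1e-14)
        assert b.ratio_SI == pytest.approx(a.ratio_SI, rel=1e-14)

    def test_row_permutation_invariance_exact(self):
        F = np.array([[0.118, 0.342, 0.540],
                      [0.832, 0.100, 0.069],
                      [0.985, 0.0, 0.015]])
        r = np.array([0.0096, 0.0040, 0.0020])
        a = StateAffinitySolver().fit(F, r).solution_
        perm = [2, 0, 1]
        b = StateAffinitySolver().fit(F[perm], r[perm]).solution_
        assert b.ratio_FI == pytest.approx(a.ratio_FI, rel=1e-14)
        assert b.ratio_SI == pytest.approx(a.ratio_SI, rel=1e-14)

    def test_negative_rates_reported_not_clipped(self):
        F = np.eye(3)
        sol = StateAffinitySolver().fit(F, [1.0, -0.5, 2.0]).solution_
        assert sol.q_FI == -0.5
        assert any("negative" in w for w in sol.warnings)
        nn = StateAffinitySolver(nonnegative=True).fit(F, [1.0, -0.5, 2.0])
        assert nn.solution_.q_FI == 0.0

    def test_overdetermined_least_squares(self):
        rng = np.random.default_rng(3)
        F = rng.uniform(0.05, 1.0, (6, 3))
        q_true = np.array([0.5, 5.0, 1.0])
        sol = StateAffinitySolver().fit(F, F @ q_true).solution_
        np.testing.assert_allclose(sol.q, q_true, rtol=1e-10)

    def test_singular_and_zero_qR_rejected(self):
        with pytest.raises(np.linalg.LinAlgError):
            StateAffinitySolver().fit(np.ones((3, 3)), [1.0, 1.0, 1.0])
        with pytest.raises(ZeroDivisionError):
            StateAffinitySolver().fit(np.eye(3), [0.0, 1.0, 1.0])


class TestEndToEnd:
    def test_quick_noiseless_recovery(self, model):
        # reduced-scale loop: faster ramp, shorter diary, coarse grid
        r = recover_ratios_end_to_end(
            model.with_binding(1.0, 10.0, 2.0), seed=0,
            schedule=InhibitorSchedule(shape="ramp", ramp_rate=1e-4,
                                       plateau=1.0),
            diary_duration=400.0, diary_dt=0.2,
            recovery_times=np.geomspace(2e-4, 8.0, 30),
        )
        assert r.true_ratio_FI == 10.0 and r.true_ratio_SI == 2.0
        assert r.solution.ratio_FI == pytest.approx(10.0, rel=0.25)
        assert r.solution.ratio_SI == pytest.approx(2.0, rel=0.4)

    def test_state_independent_binding_is_voltage_independent(self, model):
        r = recover_ratios_end_to_end(
            model.with_binding(1.0, 1.0, 1.0), seed=0,
            schedule=InhibitorSchedule(shape="ramp", ramp_rate=1e-4,
                                       plateau=1.0),
            diary_duration=400.0, diary_dt=0.2,
            recovery_times=np.geomspace(2e-4, 8.0, 30),
        )
        rates = np.array(r.rates)
        assert (rates.max() - rates.min()) / rates.mean() < 0.10
        assert r.solution.ratio_FI == pytest.approx(1.0, rel=0.25)
        assert r.solution.ratio_SI == pytest.approx(1.0, rel=0.25)
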