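"""Relaxation-limit corner points, period/amplitude estimates, dimensional forms."""

import math
from dataclasses import replace

import numpy as np
import pytest

import autoreg as ar
from autoreg import relaxation as rx


class TestCorners:
    def test_printed_values(self):
        c = ar.corner_points(0.01)
        assert c["A"] == pytest.approx((1.98, 0.02), rel=1e-12)
        assert c["B"] == pytest.approx((5.05, 0.102), rel=1e-12)
        assert c["C"] == pytest.approx((5.05, 5.05), rel=1e-12)
        assert c["D"] == pytest.approx((1.98, 0.98), rel=1e-12)

    def test_fast_jumps_conserve_mrna(self):
        for eta4 in np.geomspace(1e-5, 0.1, 20):
            c = ar.corner_points(eta4)
            assert c["B"][0] == c["C"][0]  # jump B -> C at constant m
            assert c["A"][0] == c["D"][0]  # jump D -> A at constant m

    def test_corners_sit_at_the_turning_points_to_leading_order(self):
        c, tp = ar.corner_points(0.01), ar.turning_points(0.01)
        # the cycle leaves the left branch at the local maximum: A is well
        # below it and B coincides with it to O(eta4^(3/2))
        assert c["A"][1] < tp.p1
        assert c["B"][1] == pytest.approx(tp.p1, rel=1e-3)
        # D sits at the local minimum to leading order and C far above it
        assert c["D"][1] == pytest.approx(tp.p2, rel=0.01)
        assert c["C"][1] > 5 * tp.p2


class TestPeriodEstimate:
    def test_stiff_regime_reference_values(self):
        t_ab, t_cd, period = ar.period_estimate(0.009, 0.0003, 0.01)
        assert t_ab == pytest.approx(555.556, abs=1e-3)
        assert t_cd == pytest.approx(3054.302, abs=1e-3)
        assert period == pytest.approx(3609.858, abs=1e-3)

    def test_degenerate_boundary_log_term_vanishes(self):
        t_ab, t_cd, period = ar.period_estimate(0.5, 0.1, 1.0 / 16.0)
        assert t_cd == 0.0
        assert period == pytest.approx(2.0 / 0.5, rel=1e-12)  # 1/(2*eta1*1/4)

    def test_refuses_outside_relaxation_regime(self):
        with pytest.raises(ValueError, match="1/16"):
            ar.period_estimate(0.5, 0.1, 0.07)  # log argument < 1
        with pytest.raises(ValueError):
            ar.period_estimate(0.5, 0.1, 0.2)  # no turning points at all

    def test_period_inverse_in_eta1(self):
        periods = [ar.period_estimate(e1, 0.0003, 0.01)[2] for e1 in np.geomspace(0.001, 1, 20)]
        assert np.all(np.diff(periods) < 0)


class TestAmplitudes:
    def test_exact_corner_amplitudes(self):
        amp_p, amp_m = ar.amplitude_estimate(0.01)
        assert amp_p == pytest.approx(4.98, rel=1e-12)
        # exact m_B - m_A is well below the leading-order figure at eta4 = 0.01
        assert amp_m == pytest.approx(3.07, rel=1e-12)
        assert rx.amplitude_leading_order(0.01) == pytest.approx(5.0, rel=1e-12)

    def test_amplitude_ratio_approaches_one(self):
        ratios = []
        for eta4 in (1e-4, 1e-6, 1e-8):
            amp_p, amp_m = ar.amplitude_estimate(eta4)
            ratios.append(amp_p / amp_m)
        deviations = np.abs(np.array(ratios) - 1.0)
        assert np.all(np.diff(deviations) < 0)
        assert deviations[-1] < 1e-3


class TestDimensionalForms:
    def test_printed_period_close_to_exact_rescaling(self, table1_dim):
        printed = rx.dimensional_period(table1_dim)
        exact = rx.dimensional_period_exact(table1_dim)
        assert printed == pytest.approx(exact, rel=0.01)

    def test_leading_order_error_shrinks_with_the_ratios(self):
        dim = ar.DimensionalParams(
            k1=1.0, k2=0.02, k3=1.0, k4=1e4, k5=1.0, P0=1.0, X0=1.0, alpha=1e4
        )
        printed = rx.dimensional_period(dim)
        exact = rx.dimensional_period_exact(dim)
        assert printed == pytest.approx(exact, rel=5e-4)

    def test_period_linear_in_mrna_half_life(self, table1_dim):
        # only the slow-branch log term carries k2: T(k2) = T_AB + const/k2
        t1 = rx.dimensional_period(table1_dim)
        t2 = rx.dimensional_period(replace(table1_dim, k2=table1_dim.k2 / 2))
        t4 = rx.dimensional_period(replace(table1_dim, k2=table1_dim.k2 / 4))
        assert (t4 - t2) == pytest.approx(2 * (t2 - t1), rel=1e-9)
        assert t2 > t1

    def test_amplitudes_independent_of_mrna_rates(self, table1_dim):
        A_P, A_M, ratio = rx.dimensional_amplitudes(table1_dim)
        assert ratio == 495.0  # k4/k5 exactly
        altered = replace(table1_dim, k1=10 * table1_dim.k1, k2=7 * table1_dim.k2)
        A_P2, A_M2, _ = rx.dimensional_amplitudes(altered)
        assert A_P2 == A_P and A_M2 == A_M

    def test_amplitude_ratio_identity_random_sets(self):
        rng = np.random.default_rng(31)
        checked = 0
        while checked < 100:
            k3, k4, k5, P0, X0, alpha = np.exp(rng.uniform(np.log(1e-2), np.log(1e3), 6))
            dim = ar.DimensionalParams(1.0, 1.0, k3, k4, k5, P0, X0, alpha)
            etas, _ = ar.nondimensionalise(dim)
            if etas.eta4 > 1.0 / 16.0:
                continue
            A_P, A_M, ratio = rx.dimensional_amplitudes(dim)
            assert A_P / A_M == pytest.approx(k4 / k5, rel=1e-12)
            assert ratio == pytest.approx(k4 / k5, rel=1e-12)
            checked += 1


class TestAgainstSimulation:
    def test_estimate_is_a_lower_bound_in_the_stiff_regime(self, fig5_params, fig5_cycle):
        _, rep = fig5_cycle
        est = ar.period_estimate(fig5_params.eta1, fig5_params.eta3, fig5_params.eta4)[2]
        assert rep.period >= est * (1 - 0.02)

    def test_cycle_passes_near_corners_B_and_C(self, fig5_params, fig5_cycle):
        traj, rep = fig5_cycle
        corners = ar.corner_points(fig5_params.eta4)
        t1 = traj.peak_times[-1]
        tt = np.linspace(t1 - rep.period, t1, 4000)
        m, p = traj.dense(tt)
        for label in ("B", "C"):
            mc, pc = corners[label]
            err = np.maximum(np.abs(m - mc) / mc, np.abs(p - pc) / pc)
            assert err.min() <= 0.05
        # slow-variable range matches [m_A, m_B] within 5%
        assert m.min() == pytest.approx(corners["A"][0], rel=0.05)
        assert m.max() == pytest.approx(corners["B"][0], rel=0.05)
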