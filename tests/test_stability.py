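"""Jacobian structure, trace/determinant analysis and printed conditions."""

from dataclasses import replace

import numpy as np
import pytest

import autoreg as ar
from autoreg.dynamics import rhs
from autoreg.steady_state import NonUniqueSteadyStateError, SteadyState


def _fd_jacobian(params, m, p, h=1e-6):
    J = np.zeros((2, 2))
    for j, (dm, dp) in enumerate([(h, 0.0), (0.0, h)]):
        f_plus = np.array(rhs(0.0, (m + dm, p + dp), params))
        f_minus = np.array(rhs(0.0, (m - dm, p - dp), params))
        J[:, j] = (f_plus - f_minus) / (2 * h)
    return J


class TestJacobian:
    def test_canonical_entries_and_finite_difference_check(self, table1):
        ss = ar.steady_state(table1)
        J = ar.jacobian_at(table1, ss)
        assert J[0, 0] == -0.02
        assert J[0, 1] == pytest.approx(-0.4274, abs=5e-4)
        assert J[1, 0] == pytest.approx(0.08534, abs=5e-5)
        assert J[1, 1] == pytest.approx(0.6313, abs=2e-4)
        assert np.allclose(J, _fd_jacobian(table1, ss.m_star, ss.p_star), atol=1e-6)

    def test_sign_structure_everywhere(self):
        for params in ar.sampling.sample_dimensionless(1000, seed=21):
            ss = ar.steady_state(params)
            if not ss.unique:
                continue
            J = ar.jacobian_at(params, ss)
            assert J[0, 0] < 0 and J[0, 1] < 0 and J[1, 0] > 0

    def test_outer_branches_have_negative_feedback_entry(self):
        for params in ar.sampling.sample_dimensionless(500, seed=22):
            ss = ar.steady_state(params)
            if ss.unique and ss.branch in ("left", "right"):
                assert ar.jacobian_at(params, ss)[1, 1] < 0

    def test_refuses_non_unique_steady_state(self, table1):
        fake = SteadyState(0.3, 3.0, "middle", False, 0.0, (0.1, 0.3, 0.5))
        with pytest.raises(NonUniqueSteadyStateError):
            ar.jacobian_at(table1, fake)


class TestTraceDet:
    def test_canonical_values(self, table1):
        ss = ar.steady_state(table1)
        tr, det, eigs = ar.trace_det(table1, ss)
        assert tr == pytest.approx(0.611, abs=1e-3)
        assert det == pytest.approx(0.0238, abs=1e-4)
        assert all(e.real > 0 for e in eigs)  # linearly unstable

    def test_left_branch_is_stable(self, table1):
        params = replace(table1, eta1=0.1)
        ss = ar.steady_state(params)
        tr, det, eigs = ar.trace_det(params, ss)
        assert tr < 0 and det > 0
        assert all(e.real < 0 for e in eigs)

    def test_eigenvalues_match_general_solver(self):
        for params in ar.sampling.sample_dimensionless(200, seed=23):
            ss = ar.steady_state(params)
            if not ss.unique:
                continue
            J = ar.jacobian_at(params, ss)
            _, _, eigs = ar.trace_det(params, ss)
            ref = sorted(np.linalg.eigvals(J), key=lambda z: (z.real, z.imag))
            got = sorted(eigs, key=lambda z: (z.real, z.imag))
            assert np.allclose(got, ref, atol=1e-10)


class TestInstabilityInterval:
    def test_canonical_interval(self):
        lo, hi = ar.instability_interval(0.02, 0.01)
        assert lo == pytest.approx(0.1042, abs=1e-4)
        assert hi == pytest.approx(0.9593, abs=1e-4)

    def test_empty_when_mrna_too_unstable(self):
        assert ar.instability_interval(0.7, 0.01) is None

    def test_degenerate_tangency_counts_as_empty(self):
        # eta4 = ((eta3-1)/(3+eta3))^2 makes the discriminant vanish
        assert ar.instability_interval(0.2, 0.0625) is None

    def test_necessary_condition_eta3(self):
        assert ar.necessary_condition_eta3(0.01) == pytest.approx(0.7 / 1.1, rel=1e-12)
        assert ar.necessary_condition_eta3(1.0 / 9.0) == 0.0
        assert ar.necessary_condition_eta3(1e-12) == pytest.approx(1.0, abs=1e-5)
        assert ar.necessary_condition_eta3(1e-4) < 1.0  # mRNA always more stable

    def test_trace_sign_matches_interval_membership(self):
        for params in ar.sampling.sample_dimensionless(2000, seed=24):
            ss = ar.steady_state(params)
            if not ss.unique:
                continue
            tr, _, _ = ar.trace_det(params, ss)
            interval = ar.instability_interval(params.eta3, params.eta4)
            inside = interval is not None and interval[0] < ss.p_star < interval[1]
            assert (tr > 0) == inside


class TestEta1Band:
    def test_canonical_band(self, table1):
        lo, hi = ar.eta1_band(table1)
        assert lo == pytest.approx(11.25, rel=1e-12)
        assert hi == pytest.approx(252.0, rel=1e-12)
        assert lo < table1.eta1 / table1.eta3 < hi

    def test_small_eta2_band_still_ordered(self):
        lo, hi = ar.eta1_band(ar.DimensionlessParams(1.0, 1e-4, 1.0, 0.01))
        assert lo == pytest.approx(505.0, rel=1e-12)
        assert hi == pytest.approx(20002.0, rel=1e-12)
        assert lo < hi

    def test_requires_two_branch_nullcline(self):
        with pytest.raises(ValueError):
            ar.eta1_band(ar.DimensionlessParams(1.0, 0.008, 1.0, 0.2))


class TestDimensionalRegion:
    def test_canonical_ratios_satisfied(self):
        ok, margin = ar.dimensional_region(0.02, 495.0, 124.0)
        assert ok
        assert margin == pytest.approx(0.598 - 0.02, abs=1e-3)

    def test_weak_translation_upregulation_never_oscillates(self):
        # k4/k3 = 8 keeps the bound negative for any intermediary level
        for a in np.geomspace(1.0, 1e6, 30):
            ok, margin = ar.dimensional_region(1e-6, 8.0, a)
            assert not ok and margin < 0

    def test_boundary_of_satisfiability_at_sixteen(self):
        _, margin = ar.dimensional_region(1e-9, 1e12, 16.0)
        assert margin == pytest.approx(0.0, abs=1e-5)


class TestClassify:
    def test_canonical_set_unstable_inside_interval(self, table1):
        rep = ar.classify(table1)
        assert rep.classification.startswith("unstable")
        lo, hi = rep.pc_interval
        assert lo < rep.steady.p_star < hi
        assert all(rep.conditions.values())

    def test_low_and_high_transcription_are_stable(self, table1):
        low = ar.classify(replace(table1, eta1=0.1))
        assert low.classification.startswith("stable")
        assert low.steady.branch == "left"
        high = ar.classify(replace(table1, eta1=6.0))
        assert high.classification.startswith("stable")
        assert high.steady.p_star > high.pc_interval[1]

    def test_outer_branches_always_stable(self):
        for params in ar.sampling.sample_dimensionless(1000, seed=26):
            rep = ar.classify(params)
            if rep.steady.branch in ("left", "right"):
                assert rep.classification.startswith("stable")

    def test_unstable_sets_satisfy_band_necessity(self):
        for params in ar.sampling.sample_dimensionless(1000, seed=27):
            rep = ar.classify(params)
            if rep.classification.startswith("unstable"):
                assert rep.conditions["eta1_in_middle_branch_band"]
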