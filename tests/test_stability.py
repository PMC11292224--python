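"""Quasi-polynomial, root refinement, classification and positivity tests."""

import math

import numpy as np
import pytest

from lactodyn.model_core import RateParamsMM
from lactodyn.stability import (
    Classification,
    QuasiPolynomial,
    build_chi1,
    classify,
    delayed_exp,
    find_roots,
    pade_reduce,
    positivity_check,
    scfe,
)

NE_BAR = 1.139071


class TestSCFE:
    def test_total_enzyme_becomes_free_enzyme(self):
        eq = scfe(NE_BAR)
        assert eq.nE_bar == NE_BAR
        assert eq.nS_bar == 0.0 and eq.nC_bar == 0.0

    def test_conserved_split_between_enzyme_and_complex(self):
        eq = scfe(0.8 + 0.2)
        assert eq.nE_bar == pytest.approx(1.0)

    def test_nonpositive_enzyme_rejected(self):
        with pytest.raises(ValueError):
            scfe(0.0)


class TestBuildChi1:
    def test_printed_constant_term(self, table2_rates, equilibrium):
        q = build_chi1(table2_rates, equilibrium)
        assert complex(q(0.0)).real == pytest.approx(0.0121224945, abs=1e-9)

    def test_printed_zero_delay_quadratic(self, table2_rates, equilibrium):
        from dataclasses import replace

        p0 = replace(table2_rates, tau1=0.0, tau2=0.0)
        q = build_chi1(p0, scfe(NE_BAR))
        c = q.zero_delay_poly()
        assert c[2] == pytest.approx(1.0, abs=0)
        assert c[1] == pytest.approx(0.3262124372, abs=1e-9)
        assert c[0] == pytest.approx(0.0121224945, abs=1e-9)

    def test_printed_delayed_term_coefficient(self, table2_rates, equilibrium):
        q = build_chi1(table2_rates, equilibrium)
        assert q.coefficient(1, (1, 0)) == pytest.approx(0.0992985372, abs=1e-9)

    def test_degenerate_rates_leave_lambda_squared(self):
        p = RateParamsMM(k1=1e-300, k_m1=1e-300, k2=1e-300)
        q = build_chi1(p, scfe(1.0))
        lam = 0.3 + 0.7j
        assert complex(q(lam)) == pytest.approx(lam ** 2, rel=1e-10)

    def test_full_quartic_factors_as_lambda_squared_chi1(self, table2_rates,
                                                         equilibrium):
        p, eq = table2_rates, equilibrium
        chi1 = build_chi1(p, eq)
        chi_full = QuasiPolynomial(
            terms=[
                ([0, 0, 0, 0, 1.0], (0, 0)),
                ([0, 0, 0, p.k_m1], (0, 0)),
                ([0, 0, 0, p.k1 * (eq.nS_bar + eq.nE_bar)], (1, 0)),
                ([0, 0, 0, p.k2], (0, 1)),
                ([0, 0, p.k1 * p.k2 * eq.nE_bar], (1, 1)),
            ],
            tau1=p.tau1, tau2=p.tau2,
        )
        rng = np.random.default_rng(3)
        for _ in range(20):
            lam = complex(*rng.normal(0, 0.3, 2))
            lhs = complex(chi_full(lam))
            rhs = lam ** 2 * complex(chi1(lam))
            assert abs(lhs - rhs) <= 1e-12 * max(1.0, abs(rhs))

    def test_coefficient_identities(self, table2_rates):
        # zero-delay quadratic: linear coeff k_m1 + k1 nE + k2, constant k1 k2 nE
        from dataclasses import replace

        rng = np.random.default_rng(11)
        for _ in range(10):
            k1, km1, k2, ne = rng.uniform(0.01, 2.0, 4)
            p = RateParamsMM(k1=k1, k_m1=km1, k2=k2)
            c = build_chi1(p, scfe(ne)).zero_delay_poly()
            assert c[1] == pytest.approx(km1 + k1 * ne + k2, rel=1e-14)
            assert c[0] == pytest.approx(k1 * k2 * ne, rel=1e-14)


class TestPadeReduce:
    def test_zero_delay_is_exact(self, table2_rates):
        from dataclasses import replace

        p0 = replace(table2_rates, tau1=0.0, tau2=0.0)
        q = build_chi1(p0, scfe(NE_BAR))
        num, den = pade_reduce(q)
        assert np.allclose(num, q.zero_delay_poly())
        assert np.allclose(den, [1.0])

    def test_single_exponential_accuracy(self):
        # e^{-x} vs (1-x/2)/(1+x/2) at x = lam*tau = 0.1: O(x^3) error
        q = QuasiPolynomial(terms=[([1.0], (1, 0))], tau1=1.0)
        num, den = pade_reduce(q)
        lam = 0.1
        approx = np.polynomial.polynomial.polyval(lam, num) / \
            np.polynomial.polynomial.polyval(lam, den)
        assert abs(math.exp(-0.1) - approx) < 1e-4

    def test_value_at_zero_preserved(self, table2_rates, equilibrium):
        q = build_chi1(table2_rates, equilibrium)
        num, den = pade_reduce(q)
        assert np.polynomial.polynomial.polyval(0.0, num) / \
            np.polynomial.polynomial.polyval(0.0, den) == \
            pytest.approx(complex(q(0.0)).real, rel=1e-12)

    def test_numerator_degree_at_most_four(self, table2_rates, equilibrium):
        num, den = pade_reduce(build_chi1(table2_rates, equilibrium))
        assert len(num) - 1 <= 4
        assert len(den) - 1 == 2


class TestFindRoots:
    def test_printed_zero_delay_roots(self, table2_rates):
        from dataclasses import replace

        p0 = replace(table2_rates, tau1=0.0, tau2=0.0)
        q = build_chi1(p0, scfe(NE_BAR))
        roots = sorted(r.real for r in find_roots(q))
        assert roots[0] == pytest.approx(-0.28344384, abs=1e-7)
        assert roots[1] == pytest.approx(-0.04276859, abs=1e-7)
        # independent closed-form quadratic oracle
        c = q.zero_delay_poly()
        disc = math.sqrt(c[1] ** 2 - 4 * c[2] * c[0])
        exact = sorted([(-c[1] - disc) / 2, (-c[1] + disc) / 2])
        assert roots[0] == pytest.approx(exact[0], abs=1e-12)
        assert roots[1] == pytest.approx(exact[1], abs=1e-12)

    def test_artificial_pure_imaginary_pair(self):
        q = QuasiPolynomial(terms=[([1.0, 0.0, 1.0], (0, 0))])
        roots = find_roots(q)
        assert sorted(r.imag for r in roots) == pytest.approx([-1.0, 1.0],
                                                              abs=1e-10)
        assert all(abs(r.real) < 1e-10 for r in roots)

    def test_delayed_case_roots_have_tiny_residuals(self, table2_rates,
                                                    equilibrium):
        q = build_chi1(table2_rates, equilibrium)
        roots, residuals, failed = find_roots(q, full=True)
        assert roots, "expected at least one refined root"
        assert all(res < 1e-10 for res in residuals)
        assert all(abs(complex(q(r))) < 1e-10 for r in roots)

    def test_refinement_never_worsens_residual(self, table2_rates, equilibrium):
        q = build_chi1(table2_rates, equilibrium)
        num, _ = pade_reduce(q)
        seeds = np.polynomial.polynomial.polyroots(num)
        roots = find_roots(q)
        for r in roots:
            seed = min(seeds, key=lambda s: abs(s - r))
            assert abs(complex(q(r))) <= abs(complex(q(complex(seed)))) + 1e-300


class TestClassify:
    def test_case1_roots_marginal(self):
        v = classify([-0.28344384, -0.04276859])
        assert v.classification is Classification.MARGINALLY_STABLE
        assert "lambda**2" in v.rationale

    def test_positive_root_unstable(self):
        assert classify([0.1, -0.3]).classification is Classification.UNSTABLE

    def test_imaginary_pair_periodic_boundary(self):
        v = classify([0.5j, -0.5j])
        assert v.classification is Classification.PERIODIC_BOUNDARY

    def test_never_asymptotically_stable(self):
        # even a deep left-half-plane spectrum stays marginal for chi = l^2 chi1
        v = classify([-5.0, -3.0 + 1j, -3.0 - 1j])
        assert v.classification is Classification.MARGINALLY_STABLE

    def test_empty_root_list_rejected(self):
        with pytest.raises(ValueError):
            classify([])


class TestDelayedExp:
    def test_unit_segment(self):
        for lam in (-3.0, -1.0, 0.5, 2.0):
            assert delayed_exp(lam, 1.0, 0.5) == 1.0
            assert delayed_exp(lam, 1.0, 0.0) == 1.0

    def test_two_term_hand_sum(self):
        assert delayed_exp(-1.0, 1.0, 1.5) == pytest.approx(0.5, abs=1e-14)

    def test_three_term_hand_sum_goes_negative(self):
        assert delayed_exp(-1.0, 1.0, 2.5) == pytest.approx(-0.375, abs=1e-14)

    def test_nonpositive_tau_rejected(self):
        with pytest.raises(ValueError):
            delayed_exp(1.0, 0.0, 1.0)

    def test_shift_property_by_finite_differences(self):
        # d/dx e_tau^{lam x} = lam e_tau^{lam (x - tau)}
        rng = np.random.default_rng(5)
        lam, tau = -0.8, 1.3
        checked = 0
        while checked < 100:
            x = float(rng.uniform(0.1, 12.0))
            if abs(x / tau - round(x / tau)) * tau < 1e-3:
                continue  # avoid the interpolation kinks at multiples of tau
            delta = 1e-5
            fd = (delayed_exp(lam, tau, x + delta)
                  - delayed_exp(lam, tau, x - delta)) / (2 * delta)
            assert fd == pytest.approx(
                lam * delayed_exp(lam, tau, x - tau), abs=1e-6)
            checked += 1


class TestPositivityCheck:
    def test_vanishing_delays_always_hold(self):
        p = RateParamsMM(k1=0.5, k_m1=0.2, k2=0.4, tau1=1e-6, tau2=1e-6)
        report = positivity_check(p, nE0=1.0, nS_max=2.5, horizon=300.0)
        assert report.holds
        assert report.first_violation is None

    def test_constructed_violation_at_tau_plus_inverse_rate(self):
        # condition e_tau1^{-k1 nE0 t} with k1*nE0 = 1, tau1 = 1 first
        # touches zero where the linear segment does: t = tau + 1/|lam| = 2
        p = RateParamsMM(k1=1.0, k_m1=0.1, k2=0.05, tau1=1.0, tau2=0.5)
        report = positivity_check(p, nE0=1.0, nS_max=0.01, horizon=10.0)
        assert not report.holds
        assert report.first_violation == pytest.approx(2.0, abs=0.02)

    def test_identified_delays_violate_sufficient_conditions(
            self, table2_rates):
        report = positivity_check(table2_rates, nE0=NE_BAR, nS_max=2.5,
                                  horizon=300.0)
        # brute-force independent scan of the three delayed exponentials
        conditions = [(-table2_rates.k1 * NE_BAR, table2_rates.tau1),
                      (-table2_rates.k1 * 2.5, table2_rates.tau1),
                      (-table2_rates.k2 * NE_BAR, table2_rates.tau2)]
        brute_holds = True
        for lam, tau in conditions:
            for x in np.arange(0.0, 300.0, 0.01):
                if delayed_exp(lam, tau, float(x)) <= 0:
                    brute_holds = False
                    break
            if not brute_holds:
                break
        assert report.holds == brute_holds
        assert not report.holds  # positivity genuinely fails here
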