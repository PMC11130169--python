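"""Lesion-kinetics engine: closed forms, convergence, and invariants."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from imkdose import (
    LesionCurve,
    MicrodosimetrySpec,
    foci_expected,
    gamma_from_microdosimetry,
    ll_expected,
    ll_plateau,
    make_acute,
    make_continuous,
    neg_log_survival,
    pll_discrete,
    pll_expected,
)


class TestGammaFromMicrodosimetry:
    def test_reference_beam_round_trip(self):
        # y_D chosen to invert to the reference single-event factor 0.954 Gy
        m = MicrodosimetrySpec(y_D=4.677, rho=1.0, r_d=0.5)
        assert gamma_from_microdosimetry(m) == pytest.approx(0.954, abs=0.001)

    def test_inverse_square_in_domain_radius(self):
        g1 = gamma_from_microdosimetry(MicrodosimetrySpec(4.677, 1.0, 0.5))
        g2 = gamma_from_microdosimetry(MicrodosimetrySpec(4.677, 1.0, 1.0))
        assert g1 == pytest.approx(4 * g2, rel=1e-12)

    def test_nonpositive_inputs_rejected(self):
        with pytest.raises(ValueError):
            MicrodosimetrySpec(0.0, 1.0, 0.5)


class TestPllExpected:
    def test_initial_yield_after_acute_pulse(self, hlec, acute_1gy):
        # X at the end of a 33 s pulse: (k_N·Ḋ/(a+c))(1-e^{-(a+c)T}) ≈ 40.5,
        # within a part in a thousand of the delta-pulse value k_N·D
        T = acute_1gy.t_end
        lam = hlec.a_plus_c
        exact = hlec.k_N * 109.2 / lam * -np.expm1(-lam * T)
        x = pll_expected(T, acute_1gy, hlec)
        assert x == pytest.approx(exact, rel=1e-12)
        assert x == pytest.approx(40.5, abs=0.1)

    def test_repair_decay_at_24h(self, hlec, acute_1gy):
        # pure exponential decay after delivery; the delta-pulse form
        # 40.6·e^{-0.309·24} is accurate to ~(a+c)T/2 ≈ 0.15%
        assert pll_expected(24.0, acute_1gy, hlec) == pytest.approx(
            40.6 * np.exp(-0.309 * 24.0), rel=2e-3
        )

    def test_constant_rate_ramp_matches_textbook_form(self, hlec):
        # during a constant-rate exposure X(t) = (k_N·Ḋ/(a+c))(1-e^{-(a+c)t})
        s = make_continuous(1.0, 0.00461)
        rate_h = 0.00461 * 60
        lam = hlec.a_plus_c
        for t in (0.5, 1.0, 2.0, 3.0):
            expected = hlec.k_N * rate_h / lam * -np.expm1(-lam * t)
            assert pll_expected(t, s, hlec) == pytest.approx(expected, rel=1e-12)

    def test_negative_time_rejected(self, hlec, acute_1gy):
        with pytest.raises(ValueError):
            pll_expected(-0.1, acute_1gy, hlec)


class TestPllDiscrete:
    def test_single_pulse_closed_form(self, hlec):
        for t in (0.0, 1.0, 10.0):
            assert pll_discrete(t, [(0.0, 2.0)], hlec) == pytest.approx(
                hlec.k_N * 2.0 * np.exp(-hlec.a_plus_c * t), rel=1e-14
            )

    def test_future_fractions_do_not_contribute(self, hlec):
        assert pll_discrete(1.0, [(0.0, 1.0), (5.0, 1.0)], hlec) == pytest.approx(
            pll_discrete(1.0, [(0.0, 1.0)], hlec), rel=1e-14
        )

    def test_converges_to_constant_rate_limit(self, hlec):
        # the finite-sum form approaches the continuous convolution as the
        # number of fractions grows
        D, T, n = 2.0, 2.0, 1000
        s = make_continuous(D, D / T / 60.0)
        # each subsection's dose is represented at its midpoint
        fracs = [((i + 0.5) * T / n, D / n) for i in range(n)]
        probes = np.linspace(T / 10, 2 * T, 10)
        disc = pll_discrete(probes, fracs, hlec)
        cont = pll_expected(probes, s, hlec)
        assert np.all(np.abs(disc - cont) / cont < 1e-3)


class TestLlExpected:
    def test_plateau_matches_closed_form_survival(self, hlec_consistent):
        # the integrated LL plateau must equal the closed-form -ln S for a
        # constant-rate exposure (validates F and the intra-track kernel)
        for rate in (1.82, 0.00461):
            s = make_continuous(1.0, rate)
            w = ll_plateau(s, hlec_consistent)
            assert w == pytest.approx(
                neg_log_survival(1.0, s, hlec_consistent), rel=1e-9
            )

    def test_quadrature_route_agrees_with_analytic(self, hlec_consistent):
        s = make_continuous(1.0, 0.033)
        for t in (0.2, 0.5, 2.0, np.inf):
            assert ll_expected(t, s, hlec_consistent, method="quadrature") == pytest.approx(
                ll_expected(t, s, hlec_consistent, method="analytic"), rel=1e-8
            )

    def test_acute_plateau_hand_value(self, hlec_consistent):
        # (α0 + γβ0)·1 + β0·1 with F≈1 for a 33 s delivery
        w = ll_plateau(make_acute(1.0, 1.82), hlec_consistent)
        assert w == pytest.approx(0.593, abs=0.003)

    def test_first_order_only_limit(self, hlec):
        # with b = 0 the plateau is exactly α0·D = a·k_N·D/(a+c)
        from dataclasses import replace

        p = replace(hlec, b=1e-300, alpha0=None, beta0=None)
        s = make_continuous(2.0, 0.1)
        assert ll_plateau(s, p) == pytest.approx(
            p.a * p.k_N * 2.0 / p.a_plus_c, rel=1e-9
        )

    def test_non_decreasing_in_time(self, hlec, acute_1gy):
        t = np.linspace(0, 48, 50)
        w = ll_expected(t, acute_1gy, hlec)
        assert np.all(np.diff(w) >= -1e-12)
        assert np.all(w >= 0)


class TestFociExpected:
    def test_zero_at_time_zero(self, hlec, acute_1gy):
        assert foci_expected(0.0, acute_1gy, hlec) == pytest.approx(0.0, abs=1e-12)

    def test_half_hour_after_acute(self, hlec, acute_1gy):
        # dominated by the PLL pool: 40.6·e^{-0.309·0.509} ≈ 34.7 plus a
        # small LL contribution
        val = foci_expected(0.5092, acute_1gy, hlec)
        pll = 40.6 * np.exp(-0.309 * 0.5092)
        assert val > pll
        assert val == pytest.approx(pll, abs=0.2)

    def test_late_time_reaches_ll_plateau(self, wi38):
        s = make_acute(1.0, 1.82)
        w_inf = ll_plateau(s, wi38.with_consistent_lq())
        val = foci_expected(24.0, s, wi38.with_consistent_lq())
        assert val == pytest.approx(w_inf, rel=0.01)
        assert val == pytest.approx(0.62, abs=0.03)


class TestLesionCurve:
    def test_evaluate_and_frame(self, hlec, acute_1gy):
        curve = LesionCurve.evaluate(np.linspace(0.1, 10, 20), acute_1gy, hlec)
        assert np.allclose(curve.foci, curve.pll + curve.ll)
        df = curve.to_frame()
        assert list(df.columns) == ["time_h", "pll", "ll", "foci"]

    def test_decreasing_ll_rejected(self):
        with pytest.raises(ValueError):
            LesionCurve(np.array([0.0, 1.0]), np.array([1.0, 1.0]), np.array([2.0, 1.0]))


@settings(deadline=None, max_examples=30)
@given(
    dose=st.floats(0.1, 5.0),
    rate=st.floats(0.01, 2.0),
    t=st.floats(0.0, 60.0),
)
def test_lesion_counts_non_negative(hlec, dose, rate, t):
    s = make_continuous(dose, rate)
    assert pll_expected(t, s, hlec) >= 0.0
    assert ll_expected(t, s, hlec) >= -1e-12
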