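"""Channel-kinetics unit and property tests.

Expected numbers are analytic limits or hand-evaluated closed forms of the
rate expressions (L'Hopital limits at the removable singularities, sigmoid
midpoints, Nernst ratios).
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from canfire.kinetics import (
    KineticConstants,
    ca_gate_rates,
    can_gate_steady_tau,
    k_gate_rates,
    m_current_steady_tau,
    na_gate_rates,
    nernst_calcium,
    tau_adjustment,
)

C = KineticConstants()
VT = C.VT


class TestSingularPoints:
    """Removable 0/0 singularities are filled with their analytic limits."""

    def test_na_limits(self):
        rates_m, rates_h = na_gate_rates(VT + 13.0)
        assert rates_m.alpha == pytest.approx(1.28, abs=1e-12)
        rates_m, _ = na_gate_rates(VT + 40.0)
        assert rates_m.beta == pytest.approx(1.4, abs=1e-12)
        _, rates_h = na_gate_rates(VT + 17.0)
        assert rates_h.alpha == pytest.approx(0.128, abs=1e-12)

    def test_k_limits(self):
        n = k_gate_rates(VT + 15.0)
        assert n.alpha == pytest.approx(0.16, abs=1e-12)
        n = k_gate_rates(VT + 10.0)
        assert n.beta == pytest.approx(0.5, abs=1e-12)
        n = k_gate_rates(-300.0)
        assert n.alpha == pytest.approx(0.0, abs=1e-12)

    def test_ca_limits(self):
        q, _ = ca_gate_rates(-27.0)
        assert q.alpha == pytest.approx(0.055 * 3.8, abs=1e-12)
        q, _ = ca_gate_rates(-75.0)
        assert q.beta == pytest.approx(0.94, abs=1e-12)
        _, r = ca_gate_rates(-15.0)
        assert r.beta == pytest.approx(0.0065 / 2.0, abs=1e-12)

    @pytest.mark.parametrize("center", [VT + 13.0, VT + 40.0, VT + 15.0, -27.0])
    def test_continuity_across_singularities(self, center):
        # dense 0.001 mV grid spanning each singular point
        V = center + np.arange(-0.05, 0.0501, 0.001)
        for rates in (*na_gate_rates(V), k_gate_rates(V), *ca_gate_rates(V)):
            for r in (rates.alpha, rates.beta):
                assert np.all(np.isfinite(r))
                assert np.all(r >= 0)
                # no jump: neighboring values differ smoothly
                assert np.max(np.abs(np.diff(r))) < 1e-2


class TestRateProperties:
    @given(st.floats(min_value=-120, max_value=80))
    @settings(max_examples=200, deadline=None)
    def test_all_rates_nonnegative_finite(self, V):
        vals = []
        (m, h) = na_gate_rates(V)
        vals += [m.alpha, m.beta, h.alpha, h.beta]
        n = k_gate_rates(V)
        vals += [n.alpha, n.beta]
        (q, r) = ca_gate_rates(V)
        vals += [q.alpha, q.beta, r.alpha, r.beta]
        assert all(np.isfinite(v) and v >= 0 for v in vals)

    def test_m_current_midpoint_and_tau(self):
        s = m_current_steady_tau(-35.0)
        assert s.inf == pytest.approx(0.5, abs=1e-12)
        assert s.tau == pytest.approx(4000.0 / 4.3, rel=1e-12)

    def test_m_current_limits(self):
        s = m_current_steady_tau(200.0)
        assert s.inf > 0.999999
        assert 0 < s.tau < 1.0
        V = np.linspace(-120, 80, 401)
        s = m_current_steady_tau(V)
        assert np.all((s.inf > 0) & (s.inf < 1))
        assert np.all((s.tau > 0) & (s.tau <= C.tau_max))


class TestCANGate:
    def test_half_activation_at_ca_c(self):
        s = can_gate_steady_tau(C.Ca_c)
        assert s.inf == pytest.approx(0.5, abs=1e-14)

    def test_zero_calcium_closes_gate(self):
        assert can_gate_steady_tau(0.0).inf == 0.0

    def test_double_ca_c(self):
        s = can_gate_steady_tau(2 * C.Ca_c)
        assert s.inf == pytest.approx(0.8, abs=1e-14)   # alpha = 4 beta

    def test_monotone_in_calcium(self):
        ca = np.linspace(1e-3, 10.0, 500)
        s = can_gate_steady_tau(ca)
        assert np.all(np.diff(s.inf) > 0)
        assert np.all(np.diff(s.tau) < 0)
        assert np.all(s.tau > 0)

    def test_negative_calcium_rejected(self):
        with pytest.raises(ValueError):
            can_gate_steady_tau(-0.1)

    def test_inf_tau_consistent_with_rates(self):
        # independent re-evaluation: inf = a/(a+b), tau*(a+b)*tau_adj = 1
        for ca in (0.05, 0.2, 0.75, 1.5, 5.0):
            s = can_gate_steady_tau(ca)
            b = C.beta_CAN
            a = b * (ca / C.Ca_c) ** 2
            assert s.inf == pytest.approx(a / (a + b), rel=1e-14)
            assert s.tau * (a + b) * tau_adjustment(C.T) == pytest.approx(
                1.0, rel=1e-14)


class TestNernst:
    def test_equal_concentrations_zero(self):
        # Ca_i (uM) equal to Ca_o expressed in uM -> ratio 1 -> 0 mV
        assert nernst_calcium(2000.0, 2.0, 309.15) == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_physiological_value(self):
        # (RT/2F) ln(1e4) at 36 C, hand-evaluated
        E = nernst_calcium(0.2, 2.0, 309.15)
        assert E == pytest.approx(122.7, abs=0.1)

    def test_doubling_ca_i_shifts_by_ln2(self):
        T = 309.15
        E1 = nernst_calcium(0.3, 2.0, T)
        E2 = nernst_calcium(0.6, 2.0, T)
        shift = 1000.0 * 8.314462618 * T / (2 * 96489.0) * np.log(2.0)
        assert E1 - E2 == pytest.approx(shift, rel=1e-12)
        assert shift == pytest.approx(9.23, abs=0.01)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            nernst_calcium(0.0, 2.0, 309.15)
        with pytest.raises(ValueError):
            nernst_calcium(0.2, -1.0, 309.15)
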