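"""Integrator correctness: resting stability, event delivery, determinism,
convergence, and agreement with an independent ODE solver."""

import numpy as np
import pytest
from scipy.integrate import solve_ivp

from canfire.cells import (
    PyramidalParams,
    PyramidalState,
    pyramidal_derivatives,
    resting_state,
)
from canfire.engine import SimulationError, simulate, voltage_clamp
from canfire.network import (
    NetworkConfig,
    SynapseSpec,
    build_single_cell,
    build_three_pyramidal_network,
    synaptic_conductance_kernel,
)
from canfire.stimulus import ClampCommand, step


def _single(can_scale=1.0):
    return build_single_cell(can_scale)


class TestRestingStability:
    def test_zero_input_network_is_silent(self):
        net = build_three_pyramidal_network(0.02, can_scale=1.0)
        res = simulate(net, [], t_end=10000.0)
        assert all(s.size == 0 for s in res.spikes)
        # V never drifts more than a fraction of a mV from rest
        assert np.max(np.abs(res.V - res.V[:, :1])) < 0.1


class TestStateInvariants:
    def test_gates_bounded_calcium_positive_voltage_bounded(self):
        net = _single(1.0)
        res = simulate(net, [step(0, 0.15, 500.0, 2000.0)], t_end=6000.0)
        assert np.all(res.Ca > 0)
        assert np.all(res.g_CAN >= 0)
        assert np.all((res.V >= -120.0) & (res.V <= 80.0))
        assert np.all(np.diff(res.spikes[0]) > 0)
        assert res.t.shape[0] == res.V.shape[1] == res.Ca.shape[1]

    def test_no_intrinsic_persistence_without_can(self):
        res = simulate(_single(0.0), [step(0, 0.15, 500.0, 2000.0)],
                       t_end=4000.0)
        st = res.spikes[0]
        assert st.size > 0                      # fires during the step
        assert not np.any(st > 2500.0 + 500.0)  # silent 500 ms after offset

    def test_full_can_long_lasting_persistence(self):
        """150 pA / 2 s at full CAN conductance: firing continues past the
        30 s persistence horizon."""
        res = simulate(_single(1.0), [step(0, 0.15, 500.0, 2000.0)],
                       t_end=33000.0)
        st = res.spikes[0]
        assert st.max() > 32000.0
        post = st[(st > 12500.0) & (st < 22500.0)]
        assert 3.0 <= post.size / 10.0 <= 50.0  # physiological range


class TestDeterminism:
    def test_bit_identical_reruns(self):
        net = build_three_pyramidal_network(0.01, can_scale=1.0)
        proto = [step(c, 0.15, 200.0, 500.0) for c in range(3)]
        r1 = simulate(net, proto, t_end=2000.0)
        r2 = simulate(net, proto, t_end=2000.0)
        np.testing.assert_array_equal(r1.V, r2.V)
        for a, b in zip(r1.spikes, r2.spikes):
            np.testing.assert_array_equal(a, b)


class TestSymmetry:
    def test_three_cell_symmetric_run(self):
        net = build_three_pyramidal_network(0.012, can_scale=1.0)
        proto = [step(c, 0.15, 200.0, 1000.0) for c in range(3)]
        res = simulate(net, proto, t_end=3000.0)
        assert np.max(np.abs(res.V[0] - res.V[1])) < 1e-9
        assert np.max(np.abs(res.V[0] - res.V[2])) < 1e-9


class TestEventDelivery:
    def _two_cell_net(self, weight=0.05, delay=2.0):
        p = PyramidalParams().with_can_scale(0.0)
        syn = SynapseSpec(pre=0, post=1, weight=weight, tau_rise=0.5,
                          tau_decay=2.4, E_rev=0.0, delay=delay)
        return NetworkConfig(pyramidal=[p, p], synapses=[syn])

    def test_delay_respected(self):
        net = self._two_cell_net()
        res = simulate(net, [step(0, 0.5, 100.0, 50.0)], t_end=300.0,
                       record_dt=0.01)
        t_pre = res.spikes[0][0]
        v1 = res.V[1]
        rest = v1[0]
        moved = np.nonzero(np.abs(v1 - rest) > 1e-6)[0]
        assert moved.size > 0
        t_first = res.t[moved[0]]
        assert t_first >= t_pre + 2.0 - 1e-9

    def test_event_scheme_matches_kernel_summation(self):
        """The two-state exponential synapse must agree with direct
        summation of the normalized kernel over a toy spike set."""
        p_active = PyramidalParams().with_can_scale(0.0)
        p = PyramidalParams(gbar_Na=0.0, gbar_K=0.0, gbar_M=0.0,
                            gbar_Ca=0.0, gbar_CAN=0.0)   # passive target
        syn = SynapseSpec(pre=0, post=1, weight=0.02, tau_rise=0.5,
                          tau_decay=2.4, E_rev=0.0, delay=2.0)
        net = NetworkConfig(pyramidal=[p_active, p], synapses=[syn])
        # drive cell 0 over threshold three times with brief strong pulses
        proto = [step(0, 2.0, t0, 5.0) for t0 in (50.0, 90.0, 130.0)]
        res = simulate(net, proto, t_end=250.0, record_dt=0.05)
        pre_spikes = res.spikes[0]
        assert pre_spikes.size == 3

        rest = resting_state(p)

        def rhs(t, y):
            g = sum(syn.weight * synaptic_conductance_kernel(
                t - ts - syn.delay, syn.tau_rise, syn.tau_decay)
                for ts in pre_spikes if t > ts + syn.delay)
            s = PyramidalState.from_array(y)
            i_syn = g * (s.V - syn.E_rev)      # uS*mV = nA
            return pyramidal_derivatives(s, p, 0.0, i_syn)

        sol = solve_ivp(rhs, (0.0, 250.0), rest.as_array(), method="LSODA",
                        rtol=1e-10, atol=1e-10, t_eval=res.t, max_step=0.5)
        # event delivery is quantized to the integration grid, so allow a
        # tenth-of-a-millivolt envelope
        assert np.max(np.abs(sol.y[0] - res.V[1])) < 0.1   # mV


class TestConvergence:
    def test_dt_halving(self):
        """Halving the step leaves the post-stimulus rate and spike times
        essentially unchanged."""
        proto = [step(0, 0.15, 500.0, 2000.0)]
        r1 = simulate(_single(1.0), proto, t_end=9000.0, dt=0.01)
        r2 = simulate(_single(1.0), proto, t_end=9000.0, dt=0.005)
        w = (4500.0, 9000.0)
        n1 = np.count_nonzero((r1.spikes[0] >= w[0]) & (r1.spikes[0] < w[1]))
        n2 = np.count_nonzero((r2.spikes[0] >= w[0]) & (r2.spikes[0] < w[1]))
        assert n1 == pytest.approx(n2, abs=max(1, 0.02 * n2))
        m = min(r1.spikes[0].size, r2.spikes[0].size)
        assert np.max(np.abs(r1.spikes[0][:m] - r2.spikes[0][:m])) < 0.5

    def test_independent_solver_oracle(self):
        """Spike times agree with an adaptive scipy integration of the
        same equations through the pure-Python right-hand side."""
        p = PyramidalParams()
        res = simulate(build_single_cell(1.0, params=p),
                       [step(0, 0.15, 200.0, 800.0)], t_end=1500.0)

        rest = resting_state(p)

        def rhs(t, y):
            i_inj = 0.15 if 200.0 <= t < 1000.0 else 0.0
            return pyramidal_derivatives(PyramidalState.from_array(y), p,
                                         i_inj)

        sol = solve_ivp(rhs, (0.0, 1500.0), rest.as_array(), method="LSODA",
                        rtol=1e-10, atol=1e-11, max_step=1.0, dense_output=True)
        t_fine = np.arange(0.0, 1500.0, 0.005)
        v_fine = sol.sol(t_fine)[0]
        up = np.nonzero((v_fine[:-1] < 0.0) & (v_fine[1:] >= 0.0))[0]
        oracle_spikes = []
        last = -np.inf
        for i in up:
            tc = t_fine[i] + 0.005 * (0.0 - v_fine[i]) / (v_fine[i + 1]
                                                          - v_fine[i])
            if tc - last >= 2.0:
                oracle_spikes.append(tc)
                last = tc
        oracle_spikes = np.array(oracle_spikes)
        assert oracle_spikes.size == res.spikes[0].size
        assert np.max(np.abs(oracle_spikes - res.spikes[0])) < 0.2


class TestVoltageClamp:
    def test_constant_hold_settles(self):
        cmd = ClampCommand(((-50.0, 3000.0),))
        t, I = voltage_clamp(PyramidalParams(), cmd)
        tail = I[t > 2000.0]
        # settles to within 0.2% of the holding current
        assert np.max(tail) - np.min(tail) < 2e-3 * np.abs(tail).max()

    def test_step_evokes_inward_can_tail(self):
        # the tail decays on the calcium-pool timescale (tau_r = 1 s, with
        # a large step-evoked Ca elevation), so the window spans many tau_r;
        # it returns to the pre-step holding difference, which is nonzero
        # because -50 mV carries a standing Ca2+/CAN current
        cmd = ClampCommand(((-50.0, 1000.0), (0.0, 10.0), (-50.0, 15000.0)))
        t, I_on = voltage_clamp(PyramidalParams(), cmd)
        _, I_off = voltage_clamp(PyramidalParams().with_can_scale(0.0), cmd)
        diff = I_on - I_off
        base = diff[(t > 900.0) & (t < 1000.0)].mean()
        tail = diff[(t > 1060.0)] - base
        assert tail.min() < -1e-3          # inward (negative) tail
        assert abs(tail[-1]) < 0.05 * abs(tail.min())   # decays back

    def test_can_free_difference_is_zero(self):
        cmd = ClampCommand(((-50.0, 500.0), (0.0, 10.0), (-50.0, 500.0)))
        p0 = PyramidalParams().with_can_scale(0.0)
        t, a = voltage_clamp(p0, cmd)
        _, b = voltage_clamp(p0, cmd)
        np.testing.assert_array_equal(a, b)


class TestErrors:
    def test_invalid_t_end(self):
        with pytest.raises(ValueError):
            simulate(_single(), [], t_end=0.0)

    def test_stimulus_target_validated(self):
        with pytest.raises(ValueError):
            simulate(_single(), [step(5, 0.1, 0.0, 100.0)], t_end=500.0)
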