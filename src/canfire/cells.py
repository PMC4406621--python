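"""Single-compartment cell models.

Two conductance-based cells:

* a CA3-like pyramidal cell with leak, fast Na+, delayed-rectifier K+,
  M-type K+, high-threshold Ca2+, and CAN currents plus a submembrane
  calcium pool, and
* a fast-spiking interneuron with leak, Na+ and K+ only (no adaptation,
  no intrinsic persistence mechanism).

The membrane equation is written in density form (uA/cm^2, mV, ms); point
currents (electrode injection, synaptic input, in nA) are divided by the
membrane area.  The calcium pool integrates the Ca2+ current influx into a
thin submembrane shell and relaxes back to its resting level:

    d[Ca]_i/dt = gamma(I_Ca) + ([Ca]_inf - [Ca]_i)/tau_r
    gamma      = max(0, -k * I_Ca / (2 F d))

so only inward (negative) Ca2+ current raises [Ca]_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .kinetics import (
    KineticConstants,
    ca_gate_rates,
    can_gate_steady_tau,
    k_gate_rates,
    m_current_steady_tau,
    na_gate_rates,
    nernst_calcium,
)

__all__ = [
    "PyramidalParams",
    "PyramidalState",
    "InterneuronParams",
    "InterneuronState",
    "pyramidal_derivatives",
    "interneuron_derivatives",
    "pyramidal_currents",
    "calcium_drive",
    "resting_state",
    "GBAR_CAN_FULL",
    "DEFAULT_AREA",
    "PYR_STATE_NAMES",
    "INT_STATE_NAMES",
]

#: full ("100%") CAN conductance, mS/cm^2 (= 8.67 uS/cm^2)
GBAR_CAN_FULL = 8.67e-3

#: default membrane area, cm^2.  The compartment geometry is a free
#: parameter here (density conductances are mixed with point currents in
#: pA and point synaptic weights); this value is frozen by the one-time
#: calibration in experiments.calibrate_defaults, anchored to the
#: single-cell persistence behaviors and the pure-network onset.
DEFAULT_AREA = 3.10e-4

PYR_STATE_NAMES = ("V", "m", "h", "n", "p", "q", "r", "m_CAN", "Ca_i")
INT_STATE_NAMES = ("V", "m", "h", "n")


@dataclass(frozen=True)
class PyramidalParams:
    """Pyramidal-cell parameters.

    Conductances in mS/cm^2, potentials in mV, capacitance in uF/cm^2,
    calcium in uM, times in ms, area in cm^2.
    """

    Cm: float = 1.0
    g_L: float = 0.01
    E_L: float = -80.0
    gbar_Na: float = 50.0
    E_Na: float = 50.0
    gbar_K: float = 5.0
    E_K: float = -100.0
    gbar_M: float = 0.03           # 30 uS/cm^2
    gbar_Ca: float = 0.1
    gbar_CAN: float = GBAR_CAN_FULL
    E_CAN: float = -20.0
    Ca_inf: float = 0.2            # resting calcium, uM
    tau_r: float = 1000.0          # calcium removal time constant, ms
    # units conversion constant of the calcium drive.  With I_Ca in
    # uA/cm^2, d in um and [Ca] in uM, 1e4 is the canonical value of the
    # source submembrane-pool mechanism for a 1 um shell; it puts the
    # persistent-firing calcium level at ~1-3 uM, the regime where the CAN
    # half-activation scale Ca_c visibly shapes frequency and maintenance.
    k_conv: float = 1e4
    depth_d: float = 1.0           # submembrane shell depth, um
    F: float = 96489.0             # Faraday constant, C/mol
    area: float = DEFAULT_AREA
    const: KineticConstants = field(default_factory=KineticConstants)

    def with_can_scale(self, scale: float) -> "PyramidalParams":
        """Copy with gbar_CAN = scale x full CAN conductance."""
        if scale < 0:
            raise ValueError("can scale must be >= 0")
        return replace(self, gbar_CAN=scale * GBAR_CAN_FULL)


@dataclass
class PyramidalState:
    """Pyramidal-cell state: V (mV), seven gates in [0,1], [Ca]_i (uM)."""

    V: float
    m: float
    h: float
    n: float
    p: float
    q: float
    r: float
    m_CAN: float
    Ca_i: float

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.V, self.m, self.h, self.n, self.p, self.q, self.r,
             self.m_CAN, self.Ca_i], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "PyramidalState":
        return cls(*map(float, y))


@dataclass(frozen=True)
class InterneuronParams:
    """Fast-spiking interneuron parameters (leak, Na+, K+ only)."""

    Cm: float = 1.0
    g_L: float = 0.15
    E_L: float = -70.0
    gbar_Na: float = 50.0
    E_Na: float = 50.0
    gbar_K: float = 10.0
    E_K: float = -100.0
    area: float = DEFAULT_AREA
    const: KineticConstants = field(default_factory=KineticConstants)


@dataclass
class InterneuronState:
    V: float
    m: float
    h: float
    n: float

    def as_array(self) -> np.ndarray:
        return np.array([self.V, self.m, self.h, self.n], dtype=float)

    @classmethod
    def from_array(cls, y: np.ndarray) -> "InterneuronState":
        return cls(*map(float, y))


def calcium_drive(I_Ca_density: float, p: PyramidalParams) -> float:
    """Calcium influx rate gamma (uM/ms) from the Ca2+ current density.

    Inward current is negative by convention and yields a positive drive;
    outward current is clamped to zero drive (no active extrusion through
    this term — removal is handled by the pool's relaxation).
    """
    gamma = -p.k_conv * I_Ca_density / (2.0 * p.F * p.depth_d)
    return max(0.0, gamma)


def pyramidal_currents(s: PyramidalState, p: PyramidalParams) -> dict:
    """Instantaneous ionic current densities (uA/cm^2), positive = outward."""
    c = p.const
    E_Ca = nernst_calcium(s.Ca_i, c.Ca_o, c.T)
    return {
        "I_L": p.g_L * (s.V - p.E_L),
        "I_Na": p.gbar_Na * s.m ** 3 * s.h * (s.V - p.E_Na),
        "I_K": p.gbar_K * s.n ** 4 * (s.V - p.E_K),
        "I_M": p.gbar_M * s.p * (s.V - p.E_K),
        "I_Ca": p.gbar_Ca * s.q ** 2 * s.r * (s.V - E_Ca),
        "I_CAN": p.gbar_CAN * s.m_CAN ** 2 * (s.V - p.E_CAN),
    }


def pyramidal_derivatives(
    s: PyramidalState,
    p: PyramidalParams,
    I_inj: float = 0.0,
    syn_current: float = 0.0,
) -> np.ndarray:
    """Time derivatives of the pyramidal state.

    Parameters
    ----------
    I_inj : float
        Electrode current in nA, positive = depolarizing injection.
    syn_current : float
        Synaptic current in nA, positive = outward (conductance * driving
        force convention); it is subtracted from the membrane balance.

    Returns
    -------
    ndarray of shape (9,) ordered as PYR_STATE_NAMES; dV/dt in mV/ms.
    """
    y = s.as_array()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite pyramidal state")
    c = p.const
    cur = pyramidal_currents(s, p)
    # point currents nA -> density uA/cm^2
    inj_density = I_inj * 1e-3 / p.area
    syn_density = syn_current * 1e-3 / p.area
    dV = (
        -cur["I_L"] - cur["I_Na"] - cur["I_K"] - cur["I_M"]
        - cur["I_Ca"] - cur["I_CAN"] - syn_density + inj_density
    ) / p.Cm

    (am, bm), (ah, bh) = na_gate_rates(s.V, c)
    an, bn = k_gate_rates(s.V, c)
    p_inf, tau_p = m_current_steady_tau(s.V, c)
    (aq, bq), (ar, br) = ca_gate_rates(s.V)
    mc_inf, mc_tau = can_gate_steady_tau(s.Ca_i, c)

    dCa = calcium_drive(cur["I_Ca"], p) + (p.Ca_inf - s.Ca_i) / p.tau_r
    return np.array([
        dV,
        am * (1 - s.m) - bm * s.m,
        ah * (1 - s.h) - bh * s.h,
        an * (1 - s.n) - bn * s.n,
        (p_inf - s.p) / tau_p,
        aq * (1 - s.q) - bq * s.q,
        ar * (1 - s.r) - br * s.r,
        (mc_inf - s.m_CAN) / mc_tau,
        dCa,
    ])


def interneuron_derivatives(
    s: InterneuronState,
    p: InterneuronParams,
    I_inj: float = 0.0,
    syn_current: float = 0.0,
) -> np.ndarray:
    """Time derivatives of the interneuron state (V, m, h, n)."""
    y = s.as_array()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError("non-finite interneuron state")
    c = p.const
    I_L = p.g_L * (s.V - p.E_L)
    I_Na = p.gbar_Na * s.m ** 3 * s.h * (s.V - p.E_Na)
    I_K = p.gbar_K * s.n ** 4 * (s.V - p.E_K)
    inj_density = I_inj * 1e-3 / p.area
    syn_density = syn_current * 1e-3 / p.area
    dV = (-I_L - I_Na - I_K - syn_density + inj_density) / p.Cm
    (am, bm), (ah, bh) = na_gate_rates(s.V, c)
    an, bn = k_gate_rates(s.V, c)
    return np.array([
        dV,
        am * (1 - s.m) - bm * s.m,
        ah * (1 - s.h) - bh * s.h,
        an * (1 - s.n) - bn * s.n,
    ])


def _pyr_equilibrium_ca(V: float, p: PyramidalParams) -> float:
    """Calcium fixed point at clamped V: Ca = Ca_inf + tau_r * gamma(I_Ca).

    gamma depends on Ca only weakly (through E_Ca), so plain fixed-point
    iteration converges geometrically.
    """
    Ca = p.Ca_inf
    for _ in range(60):
        s = _pyr_state_at(V, Ca, p)
        I_Ca = pyramidal_currents(s, p)["I_Ca"]
        Ca_new = p.Ca_inf + p.tau_r * calcium_drive(I_Ca, p)
        if abs(Ca_new - Ca) < 1e-14:
            return Ca_new
        Ca = Ca_new
    return Ca


def _pyr_dvdt_at_equilibrium(V: float, p: PyramidalParams) -> float:
    Ca = _pyr_equilibrium_ca(V, p)
    return pyramidal_derivatives(_pyr_state_at(V, Ca, p), p)[0]


def _pyr_state_at(V: float, Ca: float, p: PyramidalParams) -> PyramidalState:
    """State with every gate at its steady state for (V, Ca)."""
    c = p.const
    (am, bm), (ah, bh) = na_gate_rates(V, c)
    an, bn = k_gate_rates(V, c)
    p_inf, _ = m_current_steady_tau(V, c)
    (aq, bq), (ar, br) = ca_gate_rates(V)
    mc_inf, _ = can_gate_steady_tau(Ca, c)
    return PyramidalState(
        V=V, m=am / (am + bm), h=ah / (ah + bh), n=an / (an + bn),
        p=p_inf, q=aq / (aq + bq), r=ar / (ar + br),
        m_CAN=mc_inf, Ca_i=Ca)


def resting_state(p):
    """Equilibrium state of a cell with zero input.

    Eliminates all gates (and, for the pyramidal cell, the calcium pool) at
    their steady states and bracket-solves the remaining scalar voltage
    equation, scanning upward from a deeply hyperpolarized potential so
    that the *lowest* equilibrium — the true down-state — is returned even
    if the CAN current renders the cell bistable.  Used as the initial
    condition of every simulation (the model is deterministic: no random
    initialization anywhere).

    Raises
    ------
    RuntimeError
        If no equilibrium exists below -40 mV or the fixed-point residual
        exceeds 1e-8 in any state unit.
    """
    if isinstance(p, InterneuronParams):
        f = lambda V: interneuron_derivatives(_int_state_at(V, p), p)[0]
        build = lambda V, q=p: _int_state_at(V, q)
        deriv = interneuron_derivatives
    else:
        f = lambda V: _pyr_dvdt_at_equilibrium(V, p)
        build = lambda V, q=p: _pyr_state_at(V, _pyr_equilibrium_ca(V, q), q)
        deriv = pyramidal_derivatives

    v_lo = -100.0
    f_lo = f(v_lo)
    v_root = None
    for v_hi in np.arange(v_lo + 1.0, -40.0 + 0.5, 1.0):
        f_hi = f(v_hi)
        if f_lo > 0 >= f_hi or f_lo >= 0 > f_hi:
            v_root = optimize.brentq(f, v_lo, v_hi, xtol=1e-13)
            break
        v_lo, f_lo = v_hi, f_hi
    if v_root is None:
        raise RuntimeError(
            "no resting equilibrium found below -40 mV "
            f"(params: {p})")
    s = build(v_root)
    resid = np.abs(deriv(s, p))
    if resid.max() >= 1e-8:
        raise RuntimeError(
            f"resting state residual too large: max |dy/dt| = {resid.max():.3g}"
            f" (state: {s})")
    return s


def _int_state_at(V: float, p: InterneuronParams) -> InterneuronState:
    c = p.const
    (am, bm), (ah, bh) = na_gate_rates(V, c)
    an, bn = k_gate_rates(V, c)
    return InterneuronState(
        V=V, m=am / (am + bm), h=ah / (ah + bh), n=an / (an + bn))
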