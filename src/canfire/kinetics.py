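"""Voltage- and calcium-dependent channel kinetics.

Rate functions for the five ionic currents of the pyramidal-cell model
(fast Na+, delayed-rectifier K+, M-type K+, high-threshold Ca2+, and the
calcium-activated non-specific cation current, CAN) in the single-compartment
Hodgkin–Huxley formalism.  The spike-generating Na+/K+ and the slow M and
Ca2+ currents follow the standard cortical single-compartment forms with an
explicit spike-threshold offset ``VT``; the CAN gate is driven by the
submembrane calcium concentration rather than by voltage.

All functions accept scalars or NumPy arrays (broadcasting) and are total on
finite voltages: the removable 0/0 singularities of the linoid rates are
replaced by their analytic limits, not by epsilon-nudging.

Units: mV, ms, uM (intracellular Ca2+), mM (extracellular Ca2+), K.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple

import numpy as np

__all__ = [
    "GateRates",
    "GateSteadyTau",
    "KineticConstants",
    "na_gate_rates",
    "k_gate_rates",
    "m_current_steady_tau",
    "ca_gate_rates",
    "can_gate_steady_tau",
    "nernst_calcium",
    "tau_adjustment",
]

#: molar gas constant, J/(mol K)
R_GAS = 8.314462618
#: Faraday constant, C/mol (value used throughout the model)
FARADAY = 96489.0


class GateRates(NamedTuple):
    """Forward/backward rates (ms^-1) of a two-state HH gate."""

    alpha: np.ndarray | float
    beta: np.ndarray | float


class GateSteadyTau(NamedTuple):
    """Steady-state activation (dimensionless) and time constant (ms)."""

    inf: np.ndarray | float
    tau: np.ndarray | float


@dataclass(frozen=True)
class KineticConstants:
    """Shared kinetic constants of the pyramidal-cell channel set.

    Parameters
    ----------
    VT : float
        Spike-threshold offset of the Na+/K+ rate functions (mV).  Shifting
        ``VT`` shifts the action-potential threshold.  The default is
        frozen by the one-time calibration in
        ``experiments.calibrate_defaults`` (the published parameter set
        does not determine it); it places spike threshold in the high
        -50s mV, consistent with a hippocampal pyramidal cell.
    tau_max : float
        Maximal time constant of the M-current gate (ms).
    beta_CAN : float
        Backward (closing) rate of the CAN gate (ms^-1).
    Ca_c : float
        Calcium scale of CAN half-activation (uM): the gate's steady state
        is 0.5 when [Ca]_i == Ca_c.
    T : float
        Temperature (K); 309.15 K = 36 C.
    Ca_o : float
        Extracellular calcium concentration (mM), used for the Nernst
        potential of the Ca2+ current.
    """

    VT: float = -63.6
    tau_max: float = 4000.0
    beta_CAN: float = 0.002
    Ca_c: float = 0.75
    T: float = 309.15
    Ca_o: float = 2.0


def _linoid(u):
    """u / (1 - exp(-u)) with the analytic limit 1 at u = 0."""
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    nz = u != 0.0
    out[nz] = u[nz] / (-np.expm1(-u[nz]))
    if out.ndim == 0:
        return float(out)
    return out


def _linoid_neg(u):
    """u / (exp(u) - 1) with the analytic limit 1 at u = 0."""
    u = np.asarray(u, dtype=float)
    out = np.ones_like(u)
    nz = u != 0.0
    out[nz] = u[nz] / np.expm1(u[nz])
    if out.ndim == 0:
        return float(out)
    return out


def na_gate_rates(V, const: KineticConstants = KineticConstants()):
    """Rates of the fast Na+ activation (m) and inactivation (h) gates.

    Returns
    -------
    (GateRates, GateRates)
        Rates for m and h.  alpha_m and beta_m are linoid functions with
        removable singularities at ``VT+13`` and ``VT+40`` mV.
    """
    V = np.asarray(V, dtype=float)
    x = V - const.VT
    alpha_m = 1.28 * _linoid((x - 13.0) / 4.0)
    beta_m = 1.4 * _linoid_neg((x - 40.0) / 5.0)
    alpha_h = 0.128 * np.exp(-(x - 17.0) / 18.0)
    beta_h = 4.0 / (1.0 + np.exp(-(x - 40.0) / 5.0))
    return GateRates(alpha_m, beta_m), GateRates(alpha_h, beta_h)


def k_gate_rates(V, const: KineticConstants = KineticConstants()):
    """Rates of the delayed-rectifier K+ activation gate n."""
    V = np.asarray(V, dtype=float)
    x = V - const.VT
    alpha_n = 0.16 * _linoid((x - 15.0) / 5.0)
    beta_n = 0.5 * np.exp(-(x - 10.0) / 40.0)
    return GateRates(alpha_n, beta_n)


def m_current_steady_tau(V, const: KineticConstants = KineticConstants()):
    """Steady state and time constant of the M-current gate p.

    p_inf is a sigmoid with midpoint -35 mV; tau_p peaks at tau_max/4.3
    near the midpoint and shrinks at depolarized potentials.
    """
    V = np.asarray(V, dtype=float)
    u = V + 35.0
    p_inf = 1.0 / (1.0 + np.exp(-u / 10.0))
    tau_p = const.tau_max / (3.3 * np.exp(u / 20.0) + np.exp(-u / 20.0))
    return GateSteadyTau(p_inf, tau_p)


def ca_gate_rates(V):
    """Rates of the high-threshold Ca2+ current gates q (activation, squared)
    and r (inactivation).  The q-rate has a removable singularity at -27 mV.
    """
    V = np.asarray(V, dtype=float)
    alpha_q = 0.209 * _linoid_neg((-27.0 - V) / 3.8)
    beta_q = 0.94 * np.exp((-75.0 - V) / 17.0)
    alpha_r = 0.000457 * np.exp((-13.0 - V) / 50.0)
    beta_r = 0.0065 / (np.exp((-15.0 - V) / 28.0) + 1.0)
    return GateRates(alpha_q, beta_q), GateRates(alpha_r, beta_r)


def tau_adjustment(T: float) -> float:
    """Temperature factor 3^((T_Celsius - 22)/10) accelerating CAN kinetics."""
    return 3.0 ** ((T - 273.15 - 22.0) / 10.0)


def can_gate_steady_tau(Ca_i, const: KineticConstants = KineticConstants()):
    """Steady state and time constant of the calcium-gated CAN gate m_CAN.

    The opening rate is alpha = beta * ([Ca]_i / Ca_c)^2, so
    m_inf = ([Ca]_i/Ca_c)^2 / (1 + ([Ca]_i/Ca_c)^2): half-open exactly at
    [Ca]_i = Ca_c, near zero at resting calcium, saturating toward 1 at
    high calcium.  tau = 1/(tau_adj*(alpha+beta)); warming shortens it.

    Raises
    ------
    ValueError
        If any Ca_i is negative.
    """
    Ca_i = np.asarray(Ca_i, dtype=float)
    if np.any(Ca_i < 0):
        raise ValueError("Ca_i must be nonnegative (uM)")
    beta = const.beta_CAN
    alpha = beta * (Ca_i / const.Ca_c) ** 2
    inf = alpha / (alpha + beta)
    tau = 1.0 / (tau_adjustment(const.T) * (alpha + beta))
    if inf.ndim == 0:
        return GateSteadyTau(float(inf), float(tau))
    return GateSteadyTau(inf, tau)


def nernst_calcium(Ca_i, Ca_o, T: float):
    """Nernst potential (mV) of Ca2+: (RT/2F) * ln([Ca]_o/[Ca]_i).

    Parameters
    ----------
    Ca_i : scalar or array
        Intracellular calcium, uM.
    Ca_o : scalar
        Extracellular calcium, mM.
    T : float
        Temperature, K.

    Raises
    ------
    ValueError
        On nonpositive concentrations.
    """
    Ca_i = np.asarray(Ca_i, dtype=float)
    if np.any(Ca_i <= 0) or Ca_o <= 0:
        raise ValueError("concentrations must be positive")
    # both concentrations to uM so the ratio is dimensionless
    ratio = (Ca_o * 1000.0) / Ca_i
    E = 1000.0 * R_GAS * T / (2.0 * FARADAY) * np.log(ratio)
    if E.ndim == 0:
        return float(E)
    return E
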