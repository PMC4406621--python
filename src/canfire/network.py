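"""Synapse model and network constructors.

Synapses are conductance-based with a two-exponential (rise/decay) kernel,

    g(t) = w * N * (exp(-t/tau_decay) - exp(-t/tau_rise)),   t >= 0,

normalized (N) so the peak equals 1: the weight ``w`` is therefore the peak
conductance, comparable across time-constant pairs.  Synaptic current is
``g(t) * (V_post - E_rev)``.  Every synapse delivers with a fixed axonal +
synaptic delay (2 ms by default).

Weights are in uS throughout (the working unit of the recurrent-weight
sweeps).  AMPA synapses use rise 0.5 ms / decay 2.4 ms and E_rev = 0 mV;
GABA_A synapses rise 1 ms, decay 7 ms (or slower, for the feedback-inhibition
sweeps) and E_rev = -80 mV.

Two ready-made topologies:

* three identical pyramidal cells, all-to-all recurrent excitation
  (:func:`build_three_pyramidal_network`), and
* the same triad plus one fast-spiking interneuron receiving from and
  inhibiting all three (:func:`build_feedback_inhibition_network`).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .cells import InterneuronParams, PyramidalParams

__all__ = [
    "SynapseSpec",
    "NetworkConfig",
    "synaptic_conductance_kernel",
    "kernel_peak_time",
    "kernel_norm",
    "build_single_cell",
    "build_three_pyramidal_network",
    "build_feedback_inhibition_network",
    "E_AMPA",
    "E_GABA",
    "TAU_AMPA",
    "TAU_GABA",
    "DEFAULT_DELAY",
    "DEFAULT_WPI",
]

E_AMPA = 0.0      # mV
E_GABA = -80.0    # mV
TAU_AMPA = (0.5, 2.4)   # rise, decay (ms)
TAU_GABA = (1.0, 7.0)
DEFAULT_DELAY = 2.0     # ms

#: pyramidal->interneuron weight (uS); calibrated once so that the
#: interneuron reliably discharges on each pyramidal population volley and
#: feedback inhibition regulates the hybrid network into the physiological
#: frequency range.
DEFAULT_WPI = 0.033


@dataclass(frozen=True)
class SynapseSpec:
    """One synapse: pre/post are global cell indices; weight is the peak
    conductance in uS."""

    pre: int
    post: int
    weight: float
    tau_rise: float
    tau_decay: float
    E_rev: float
    delay: float = DEFAULT_DELAY

    def __post_init__(self):
        if not (self.tau_decay > self.tau_rise > 0):
            raise ValueError("need tau_decay > tau_rise > 0")
        if self.weight < 0 or self.delay < 0:
            raise ValueError("weight and delay must be nonnegative")
        if self.pre == self.post:
            raise ValueError("autapses are not allowed")


@dataclass
class NetworkConfig:
    """Cell lists plus synapse list.  Global cell indices run over the
    pyramidal cells first, then the interneurons."""

    pyramidal: list = field(default_factory=list)
    interneurons: list = field(default_factory=list)
    synapses: list = field(default_factory=list)

    @property
    def n_cells(self) -> int:
        return len(self.pyramidal) + len(self.interneurons)

    def validate(self) -> None:
        for syn in self.synapses:
            if not (0 <= syn.pre < self.n_cells and 0 <= syn.post < self.n_cells):
                raise ValueError(f"synapse endpoint out of range: {syn}")

    def describe(self) -> str:
        """CSV dump of cells and synapses for inspection."""
        lines = ["kind,index,detail"]
        for i, p in enumerate(self.pyramidal):
            lines.append(f"pyramidal,{i},gbar_CAN={p.gbar_CAN:g}")
        for j, _ in enumerate(self.interneurons):
            lines.append(f"interneuron,{len(self.pyramidal) + j},")
        lines.append("pre,post,weight_uS,tau_rise_ms,tau_decay_ms,E_rev_mV,delay_ms")
        for s in self.synapses:
            lines.append(
                f"{s.pre},{s.post},{s.weight:g},{s.tau_rise:g},"
                f"{s.tau_decay:g},{s.E_rev:g},{s.delay:g}")
        return "\n".join(lines)


def kernel_peak_time(tau_rise: float, tau_decay: float) -> float:
    """Time of the kernel maximum: (t1*t2/(t2-t1)) * ln(t2/t1)."""
    return (tau_rise * tau_decay / (tau_decay - tau_rise)
            * math.log(tau_decay / tau_rise))


def kernel_norm(tau_rise: float, tau_decay: float) -> float:
    """Normalization factor N making the kernel peak equal 1."""
    tp = kernel_peak_time(tau_rise, tau_decay)
    return 1.0 / (math.exp(-tp / tau_decay) - math.exp(-tp / tau_rise))


def synaptic_conductance_kernel(t_since_spike, tau_rise: float, tau_decay: float):
    """Normalized two-exponential conductance kernel, peak 1 at the analytic
    peak time; zero at t = 0 and for t < 0."""
    if not tau_decay > tau_rise > 0:
        raise ValueError("need tau_decay > tau_rise > 0")
    import numpy as np
    t = np.asarray(t_since_spike, dtype=float)
    N = kernel_norm(tau_rise, tau_decay)
    out = N * (np.exp(-t / tau_decay) - np.exp(-t / tau_rise))
    out = np.where(t < 0, 0.0, out)
    if out.ndim == 0:
        return float(out)
    return out


def build_single_cell(can_scale: float = 1.0,
                      params: PyramidalParams | None = None) -> NetworkConfig:
    """A lone pyramidal cell (no synapses)."""
    base = params or PyramidalParams()
    return NetworkConfig(pyramidal=[base.with_can_scale(can_scale)])


def build_three_pyramidal_network(
    Wpp: float,
    can_scale: float = 1.0,
    params: PyramidalParams | None = None,
) -> NetworkConfig:
    """Three identical pyramidal cells, all-to-all recurrent AMPA synapses
    (6 ordered pairs, no autapses), each of peak conductance ``Wpp`` uS."""
    if Wpp < 0 or not (0 <= can_scale <= 1):
        raise ValueError("Wpp must be >= 0 and can_scale in [0, 1]")
    base = params or PyramidalParams()
    cell = base.with_can_scale(can_scale)
    tr, td = TAU_AMPA
    syns = [
        SynapseSpec(pre=i, post=j, weight=Wpp, tau_rise=tr, tau_decay=td,
                    E_rev=E_AMPA)
        for i in range(3) for j in range(3) if i != j
    ]
    net = NetworkConfig(pyramidal=[replace(cell) for _ in range(3)],
                        synapses=syns)
    net.validate()
    return net


def build_feedback_inhibition_network(
    Wpp: float,
    Wip: float,
    Wpi: float = DEFAULT_WPI,
    tau_inh_decay: float = 5.0,
    can_scale: float = 1.0,
    params: PyramidalParams | None = None,
) -> NetworkConfig:
    """The three-cell recurrent network plus one fast-spiking interneuron.

    The interneuron (global index 3) receives AMPA input from each pyramidal
    cell (weight ``Wpi``) and sends GABAergic synapses back to all three
    (weight ``Wip``, rise 1 ms, decay ``tau_inh_decay``).
    """
    if min(Wpp, Wip, Wpi) < 0:
        raise ValueError("weights must be >= 0")
    if tau_inh_decay <= 1.0:
        raise ValueError("tau_inh_decay must exceed the 1 ms rise time")
    net = build_three_pyramidal_network(Wpp, can_scale, params)
    net.interneurons = [InterneuronParams()]
    tr, td = TAU_AMPA
    for i in range(3):
        net.synapses.append(SynapseSpec(
            pre=i, post=3, weight=Wpi, tau_rise=tr, tau_decay=td,
            E_rev=E_AMPA))
    for i in range(3):
        net.synapses.append(SynapseSpec(
            pre=3, post=i, weight=Wip, tau_rise=TAU_GABA[0],
            tau_decay=tau_inh_decay, E_rev=E_GABA))
    net.validate()
    return net
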