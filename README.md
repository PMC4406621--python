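# canfire

Persistent firing — spiking that continues after its triggering stimulus
ends — is a leading candidate mechanism for short-term memory maintenance.
Two mechanisms can support it: recurrent synaptic excitation within a cell
assembly, and an intrinsic cellular current, the **calcium-activated
non-specific cation (CAN) current** that cholinergic receptor activation
unmasks in hippocampal CA3 pyramidal cells.  `canfire` is a simulation
library for comparing these mechanisms — alone and combined (the *hybrid*
model) — in Hodgkin–Huxley-style cells and small recurrent circuits, for
computational neuroscientists who want a tested, deterministic, scriptable
reimplementation rather than a point-and-click simulator.

## The model in brief

Each pyramidal cell is a single compartment,

&nbsp;&nbsp;&nbsp;&nbsp;*C*<sub>m</sub> d*V*/d*t* = −*I*<sub>L</sub> − *I*<sub>Na</sub> − *I*<sub>K</sub> − *I*<sub>M</sub> − *I*<sub>Ca</sub> − *I*<sub>CAN</sub> − *I*<sub>syn</sub> + *I*<sub>inj</sub>,

with spike currents (*I*<sub>Na</sub>, *I*<sub>K</sub>), spike-frequency
adaptation (*I*<sub>M</sub>), a high-threshold Ca²⁺ current feeding a
submembrane calcium pool (d[Ca]<sub>i</sub>/d*t* = −*k·I*<sub>Ca</sub>/(2*Fd*) +
([Ca]<sub>∞</sub> − [Ca]<sub>i</sub>)/τ<sub>r</sub>), and the CAN current
*ḡ*<sub>CAN</sub>·*m*²·(*V* + 20 mV) whose gate opens with calcium:
*m*<sub>∞</sub> = *r*²/(1 + *r*²), *r* = [Ca]<sub>i</sub>/[Ca]<sub>c</sub>.
Each spike admits calcium, calcium opens the CAN gate, and the CAN current
depolarizes the cell to its next spike — a low-frequency attractor that
needs no synapses.  Networks add two-exponential conductance synapses
(AMPA 0.5/2.4 ms; GABA<sub>A</sub> for the feedback interneuron) with a
2 ms delay, in an all-to-all three-cell topology.  See
[`docs/methods.md`](docs/methods.md) for the full equations, numerics, and
calibration.

## A worked example

```bash
python examples/single_cell_persistent_firing.py
```

prints

```
full CAN conductance:
  spikes during step : 55
  persistence class  : long_lasting
  post-offset rate   : 5.5 Hz (10-20 s window)
  peak [Ca]_i        : 9.85 uM
CAN removed:
  spikes during step : 27
  persistence class  : none
  post-offset rate   : 0.0 Hz (10-20 s window)
  peak [Ca]_i        : 5.43 uM
```

With the CAN current the cell keeps firing at ~5.5 Hz long after the 2 s,
150 pA step ends (it never stops on its own — a "long-lasting" response);
without it the same stimulus leaves only silence, as in control recordings
without cholinergic agonist.  The other scripts in `examples/` walk
through the network results: the weight sweep (pure network all-or-nothing
at >100 Hz versus the hybrid's tunable 5–50 Hz), distractor robustness,
theta coexistence, and pattern completion.

Library use is three lines:

```python
import canfire as cf
net = cf.build_three_pyramidal_network(Wpp=0.01, can_scale=1.0)
res = cf.simulate(net, cf.make_protocol_fixture("network_init"), t_end=23000.0)
```

A thin CLI mirrors this (`canfire simulate`, `canfire run <experiment>`,
`canfire fixtures`).

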