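# Methods

`canfire` simulates persistent firing — spiking that outlives its triggering
stimulus — in single hippocampal CA3-like pyramidal cells and in small
recurrent circuits built from them.  Two mechanisms can sustain the firing:
an *intrinsic* one, the calcium-activated non-specific cation (CAN) current
that cholinergic receptor activation makes available, and a *synaptic* one,
recurrent AMPA excitation among the cells.  The package exists to compare
the two and their combination (the "hybrid" configuration) on frequency
range, robustness to distractors, compatibility with theta-band drive,
frequency control by feedback inhibition, and pattern completion.

## Cell models

The pyramidal cell is a single Hodgkin–Huxley compartment:

    Cm dV/dt = −I_L − I_Na − I_K − I_M − I_Ca − I_CAN − I_syn + I_inj

with densities in µA/cm² (Cm = 1 µF/cm²).  The currents:

* **I_L** — leak, g_L = 0.01 mS/cm², E_L = −80 mV.
* **I_Na, I_K** — spike-generating Na⁺ (ḡ = 50 mS/cm², m³h) and
  delayed-rectifier K⁺ (ḡ = 5 mS/cm², n⁴), with the standard
  cortical-neuron rate functions shifted by a threshold offset VT.
* **I_M** — slow non-inactivating K⁺ current (ḡ = 30 µS/cm², gate p with
  σ-midpoint −35 mV, τ_max = 4 s): spike-frequency adaptation.
* **I_Ca** — high-threshold Ca²⁺ current (ḡ = 0.1 mS/cm², q²r), the
  calcium source.  E_Ca is computed each step from the instantaneous
  Nernst ratio ([Ca]_o = 2 mM).
* **I_CAN** — ḡ·m²·(V − E_CAN), E_CAN = −20 mV, ḡ between 0 and
  8.67 µS/cm² ("0–100 % CAN").  The gate m is driven by calcium, not
  voltage: α = β·([Ca]_i/Ca_c)², β = 0.002 ms⁻¹, so
  m_∞ = r²/(1+r²) with r = [Ca]_i/Ca_c, half-open at [Ca]_i = Ca_c
  (0.75 µM default).  τ_m = 1/(τ_adj·(α+β)) with τ_adj = 3^((T−22 °C)/10);
  kinetics accelerate with warming, and T is fixed at 36 °C.

The submembrane calcium pool integrates Ca²⁺-current influx into a 1 µm
shell and relaxes to its 0.2 µM resting level with τ_r = 1 s:

    d[Ca]_i/dt = max(0, −k·I_Ca/(2Fd)) + (0.2 µM − [Ca]_i)/τ_r

Only inward I_Ca contributes (the pool has no outward-current term; removal
is the relaxation).  With I_Ca in µA/cm², d in µm and [Ca] in µM, the
conversion constant is k = 10⁴ — the canonical value of the
submembrane-shell mechanism this pool follows at 1 µm depth.  This choice
matters: it puts the persistent-firing calcium level at ~1–3 µM, the regime
in which Ca_c visibly controls both ignition (a brief 500 pA/86 ms pulse
ignites persistent firing at Ca_c = 0.65 µM but not 0.85 µM) and
maintenance (raising Ca_c slows and finally extinguishes maintained
firing).  A tenfold larger k drives the pool to tens of µM, saturates the
CAN gate, and erases both behaviors along with the self-terminating regime.

The feedback interneuron is the fast-spiking variant of the same formalism:
leak (0.15 mS/cm², −70 mV), Na⁺ (50 mS/cm²) and K⁺ (10 mS/cm²) only — no
adaptation and no intrinsic persistence mechanism.

Persistent firing here is a genuine attractor: each spike admits Ca²⁺,
calcium opens the CAN gate, and the CAN current depolarizes the cell to
the next spike.  At full CAN conductance the loop settles near 5.5 Hz and
[Ca]_i ≈ 2.5 µM; at 80–90 % conductance the loop is marginal and firing
decays away over seconds (self-terminating); below ~70 % only an
afterdepolarization remains.

## Synapses and networks

Synapses are conductance-based with a rise/decay two-exponential kernel
normalized to unit peak, so a weight *is* a peak conductance (µS) and
weights are comparable across kinetics: AMPA 0.5/2.4 ms, E = 0 mV;
GABA_A 1 ms rise, 5–250 ms decay, E = −80 mV.  Delivery lags the
presynaptic spike (upward 0 mV crossing, 2 ms debounce) by a 2 ms delay.
Two constructors cover the study designs: three identical pyramidal cells
all-to-all (6 synapses of weight Wpp), optionally plus one interneuron fed
by all three (weight Wpi) and inhibiting all three (weight Wip).

## Numerics

The integrator is a fixed-step classical RK4 (default dt = 0.01 ms,
sampled at 0.1 ms).  Design points:

* Each synapse is carried as two exponential auxiliary states incremented
  at delivery; their decay is propagated *analytically*, including to the
  RK half-steps, so the synaptic conductance entering every stage is exact.
  Equivalence with direct kernel summation is asserted in the test-suite.
* The CAN gate is updated by an exact exponential (Rush–Larsen) step with
  calcium frozen across dt, because its time constant collapses below dt
  at high calcium, where the gate simply tracks m_∞; all other gates are
  mildly stiff at worst (fastest τ ≈ 0.04 ms at spike peak, λ·dt ≈ 0.25)
  and stay inside the RK4 vector.
* Spike times come from linear interpolation of the threshold crossing,
  not from the sampling grid; deliveries are scheduled on the step grid
  (quantization ≤ dt).
* Gates are clamped to [0,1] and calcium to >0 after each step; the exact
  flow preserves these domains, so the clamp only removes roundoff-scale
  excursions.
* Everything is deterministic: initial conditions are always the
  root-found resting state (the scan-and-bracket solver returns the lowest
  equilibrium even where the CAN current makes the cell bistable), and
  identical inputs give bit-identical outputs.

Halving dt changes the measured persistent-firing frequency by well under
2 % and spike times by ≪ 0.5 ms; an independent adaptive integration
(SciPy LSODA on the pure-Python right-hand side) agrees with production
spike times to < 0.2 ms over a 1.5 s protocol.  Both checks are tests.

## Measurement conventions

* **Frequency**: spike count in the half-open window [offset+10 s,
  offset+20 s) divided by 10 s.  Quantization is therefore 0.1 Hz.
* **Persistence class** over a 30 s horizon after stimulus offset:
  `long_lasting` if at least one spike falls in the final 2 s before the
  horizon (operationalizing "does not stop by itself"), `none` if there
  are no post-offset spikes at all, `self_terminating` otherwise.  A
  100 ms grace after offset attributes spikes already in flight to the
  stimulus.
* **Thresholds** along a sweep are reported as the (last-failing,
  first-passing) grid pair; non-monotone sweeps are flagged, not hidden.

## Calibration (what the published parameter set leaves open)

Density conductances are combined with point currents (pA) and point
synaptic weights, which requires a membrane area; the spike-threshold
offset VT and the pyramidal→interneuron weight Wpi are likewise free.
`experiments.calibrate_defaults` pins them once, deterministically, against
three anchors, and the resulting values are frozen as package defaults:

| parameter | frozen value | anchored to |
|---|---|---|
| VT | −63.6 mV | single cell: no persistence without CAN; long-lasting ~5 Hz at full CAN; self-terminating band at 80–90 % |
| area | 3.10×10⁻⁴ cm² | pure-network persistence onset between Wpp = 0.016 and 0.017 µS, ~120 Hz just above onset |
| Wpi | 0.033 µS | interneuron discharges on every pyramidal volley; feedback inhibition regulates the hybrid circuit into the 3–50 Hz band |
| weight unit | µS | the printed weight grid (0.005–0.03) only reproduces the onset anchor in µS; in nS the synapses are ~10³ too weak |

All experiment drivers consume only this frozen configuration; nothing is
re-tuned per experiment.

## What the drivers reproduce — and known limitations

With the frozen defaults the package reproduces, qualitatively and mostly
quantitatively: the single-cell persistence classes versus CAN conductance;
the pure network's all-or-nothing onset (silent at 0.016, ~118 Hz at
0.017 µS) versus the hybrid's gradual 5→50 Hz growth over Wpp 0–0.012; the
hybrid's survival of −400 pA distractors up to seconds versus the pure
network's death at 20 ms; theta coexistence (pure network terminated just
above 120 pA at 7 Hz, hybrid surviving beyond); and feedback-inhibition
frequency control (hybrid smoothly lowered to ~12 Hz at Wip = 0.03 µS,
pure network cliff-dropping from >100 Hz to 0 near Wip ≈ 0.01).

Known deviations, stable across every calibration the anchors allow:

* the 70 % CAN cell shows only an afterdepolarization (class `none`)
  rather than brief self-terminating firing;
* the hybrid model completes patterns *more* eagerly than its published
  counterpart: non-cued cells are recruited from Wpp ≈ 0.009 µS (one cue)
  and ≈ 0.004 µS (two cues), versus 0.0135 and 0.007.  The cued cells'
  EPSPs summate on this cell's long membrane time constant (~100 ms) and
  ignite the CAN loop earlier than in the original.  The pure network's
  completion threshold (≈ 0.019 µS) is reproduced.

The trade-off is structural: the anchors above leave no free parameter
that moves the hybrid completion thresholds without breaking the
single-cell frequency or the network onset.

## Synthetic data

`canfire.synth` generates what the analysis stage needs without the
simulator: protocol fixtures (every stimulus design used by the drivers,
serializable), and surrogate spike trains/voltage traces with known ground
truth — regular trains at a chosen rate with seeded, ordering-preserving
uniform jitter, rendered as triangular spike templates on a flat baseline.
These surrogates exercise the detector's counting, interpolation and
refractory logic exactly; they make no attempt to mimic real membrane
noise, spike-shape variability, bursting, or adaptation, so passing
detector tests says nothing about robustness to those features of real
recordings.  The simulator itself is deterministic, and no experiment here
consumes stochastic input.
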