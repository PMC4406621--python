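"""Can persistent firing coexist with theta-band oscillatory drive?

Imposes a 7 Hz sinusoidal current on all cells 5 s after persistent
firing is established.  In the pure network the first trough that silences
the cells kills the activity outright above a modest amplitude; the hybrid
model keeps firing (theta-modulated) through amplitudes that destroy the
pure network, because the CAN current spans the troughs.
"""

from canfire.experiments import run_theta_entrainment

for scale, wpp, label in [(0.0, 0.018, "pure network"),
                          (1.0, 0.008, "hybrid model")]:
    rep = run_theta_entrainment(scale, wpp, amplitudes=(0.10, 0.12, 0.13))
    print(f"{label} (Wpp = {wpp}):")
    for v, s in zip(rep.tables["amplitude"].values,
                    rep.tables["amplitude"].summaries):
        state = "survives" if s.frequency > 0 else "terminated"
        print(f"  7 Hz, {v * 1000:.0f} pA -> {state} "
              f"({s.frequency:.1f} Hz during)")
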