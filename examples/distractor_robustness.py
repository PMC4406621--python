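"""Robustness of persistent firing against hyperpolarizing distractors.

Establishes persistent firing (150 pA / 2 s to all three cells), then
injects -400 pA to every cell 5 s later, for increasing durations.  The
pure network dies at the briefest interruption (a 20 ms gap breaks the
spike ping-pong); the hybrid model rides out seconds of hyperpolarization
because the calcium pool and CAN gate outlive the silence, and only a
very long distractor drains them.
"""

from canfire.experiments import run_distractor_grid

for scale, label in [(0.0, "pure network"), (1.0, "hybrid model")]:
    rep = run_distractor_grid(scale, Wpp=0.02, durations=(0.02, 1.0, 7.6))
    print(f"{label} (Wpp = 0.02):")
    for row in rep.tables["grid"]:
        state = "survives" if row["survived"] else "terminated"
        print(f"  -400 pA x {row['duration_s']:>4} s -> {state} "
              f"({row['frequency_Hz']:.1f} Hz after)")
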