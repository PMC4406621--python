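"""Pattern completion: recruiting unstimulated cells through recurrence.

Cues only cell 1 (100 pA / 2 s) and asks whether cells 2 and 3 join the
persistent firing.  Below a completion threshold in Wpp only the cued cell
fires; above it the whole assembly ignites.  The printed value is the mean
rate of the *non-cued* cells 10-20 s after the cue ends.
"""

from canfire.experiments import run_pattern_completion

rep = run_pattern_completion(1.0, n_cued=1,
                             wpp_grid=[0.005, 0.010, 0.015])
print("hybrid model, one-cell cue:")
print(rep.tables["Wpp"].to_frame().to_string(index=False))
print("completion threshold (last silent, first recruited):",
      rep.thresholds["completion"])
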