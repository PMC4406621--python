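"""Experiment drivers: the study designs, end to end.

Every driver builds its network from the frozen calibrated defaults, runs
the stimulus protocol, and reduces the result with the standard measurement
conventions (10–20 s post-offset frequency window, 30 s persistence
horizon).  The calibration itself — the membrane area, the spike-threshold
offset VT of the Na+/K+ rates, and the pyramidal→interneuron weight Wpi,
none of which is fixed by the published parameter set — is done once by
:func:`calibrate_defaults` and frozen into the package defaults; no driver
re-tunes anything.

Conventions shared by all drivers:

* stimulation starts after 1 s of rest; the standard initiation is a
  150 pA / 2 s step (100 pA / 2 s for retrieval cues);
* "5 s after the initiation of persistent firing" = 5 s after stimulus
  offset;
* frequency after a distractor or during theta is measured 10–20 s after
  the distractor offset / sinusoid onset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .analysis import (
    PersistenceClass,
    SweepTable,
    firing_frequency,
    locate_threshold,
    summarize_firing,
)
from .cells import GBAR_CAN_FULL, PyramidalParams
from .engine import simulate, voltage_clamp
from .kinetics import KineticConstants
from .network import (
    DEFAULT_WPI,
    build_feedback_inhibition_network,
    build_single_cell,
    build_three_pyramidal_network,
)
from .stimulus import ClampCommand, sinusoid, step

__all__ = [
    "ExperimentReport",
    "STIM_ONSET",
    "STIM_DURATION",
    "STIM_OFFSET",
    "run_single_cell_can_scaling",
    "run_wpp_sweep",
    "run_distractor_grid",
    "run_theta_entrainment",
    "run_feedback_inhibition_sweep",
    "run_pattern_completion",
    "run_cac_sensitivity",
    "run_voltage_clamp_check",
    "calibrate_defaults",
]

STIM_ONSET = 1000.0       # ms of rest before any stimulation
STIM_DURATION = 2000.0    # ms, standard initiation step
STIM_OFFSET = STIM_ONSET + STIM_DURATION
INIT_AMP = 0.15           # nA, standard initiation amplitude
CUE_AMP = 0.10            # nA, retrieval-cue amplitude

#: post-offset time simulated when only the 10-20 s frequency window is
#: needed (23 s total); persistence classification to the 30 s horizon
#: uses HORIZON_T_END.
FREQ_T_END = STIM_OFFSET + 20000.0
HORIZON_T_END = STIM_OFFSET + 31000.0


@dataclass
class ExperimentReport:
    """Driver output: a config snapshot sufficient to re-run the experiment
    bit-identically, the sweep table(s), and any derived thresholds."""

    experiment_id: str
    config: dict
    tables: dict = field(default_factory=dict)
    thresholds: dict = field(default_factory=dict)
    notes: dict = field(default_factory=dict)


def _init_protocol(cells, amp=INIT_AMP):
    return [step(c, amp, STIM_ONSET, STIM_DURATION) for c in cells]


def _snapshot(**kw) -> dict:
    p = PyramidalParams()
    base = {
        "VT": p.const.VT, "area_cm2": p.area, "Ca_c_uM": p.const.Ca_c,
        "gbar_CAN_full_mS_cm2": GBAR_CAN_FULL, "Wpi_uS": DEFAULT_WPI,
        "stim_onset_ms": STIM_ONSET, "stim_duration_ms": STIM_DURATION,
    }
    base.update(kw)
    return base


def run_single_cell_can_scaling(
    scales=(1.0, 0.9, 0.8, 0.7, 0.6),
    amp: float = INIT_AMP,
    dt: float = 0.01,
) -> ExperimentReport:
    """Single-cell response to the standard step at graded CAN conductance.

    Full conductance sustains low-frequency persistent firing past the 30 s
    horizon; reduced conductance yields self-terminating firing of shrinking
    duration and, low enough, only an afterdepolarization.
    """
    scales = sorted(scales)
    summaries = []
    for sc in scales:
        net = build_single_cell(sc)
        res = simulate(net, _init_protocol([0], amp), HORIZON_T_END, dt=dt)
        summaries.append(summarize_firing(res.spikes[0], STIM_OFFSET))
    table = SweepTable("can_scale", np.asarray(scales, float), summaries)
    return ExperimentReport(
        "single_cell_can_scaling", _snapshot(amp_nA=amp),
        tables={"can_scale": table})


def run_wpp_sweep(
    can_scale: float,
    wpp_grid,
    dt: float = 0.01,
    classify: bool = False,
) -> ExperimentReport:
    """Frequency of network persistent firing versus recurrent weight Wpp.

    All three cells receive the standard initiation; by symmetry one cell's
    spike train summarizes the network.  ``classify=True`` extends each run
    to the 30 s persistence horizon.
    """
    wpp_grid = np.asarray(sorted(wpp_grid), float)
    t_end = HORIZON_T_END if classify else FREQ_T_END
    summaries = []
    for wpp in wpp_grid:
        net = build_three_pyramidal_network(float(wpp), can_scale)
        res = simulate(net, _init_protocol(range(3)), t_end, dt=dt)
        # persistence judged over the simulated post-offset span
        summaries.append(summarize_firing(res.spikes[0], STIM_OFFSET,
                                          horizon=t_end - STIM_OFFSET))
    table = SweepTable("Wpp", wpp_grid, summaries)
    onset = locate_threshold(table, lambda s: s.frequency > 0)
    return ExperimentReport(
        "wpp_sweep", _snapshot(can_scale=can_scale),
        tables={"Wpp": table}, thresholds={"persistence_onset": onset})


def run_distractor_grid(
    can_scale: float,
    Wpp: float = 0.02,
    amplitudes=(-0.4,),
    durations=(0.02, 1.0, 7.6),
    dt: float = 0.01,
) -> ExperimentReport:
    """Hyperpolarizing distractors against established persistent firing.

    Initiation (150 pA / 2 s to all cells), then at offset + 5 s a negative
    step of each (amplitude, duration) to all cells.  Survival = any
    spikes in the 10–20 s window after the distractor ends.
    """
    d_on = STIM_OFFSET + 5000.0
    rows = []
    for amp in amplitudes:
        for dur_s in durations:
            dur = dur_s * 1000.0
            d_off = d_on + dur
            proto = _init_protocol(range(3)) + [
                step(c, amp, d_on, dur) for c in range(3)]
            net = build_three_pyramidal_network(Wpp, can_scale)
            res = simulate(net, proto, d_off + 20000.0, dt=dt)
            f = firing_frequency(res.spikes[0],
                                 (d_off + 10000.0, d_off + 20000.0))
            rows.append({"amplitude_nA": amp, "duration_s": dur_s,
                         "frequency_Hz": f, "survived": f > 0})
    surviving = {(r["amplitude_nA"], r["duration_s"]) for r in rows
                 if r["survived"]}
    return ExperimentReport(
        "distractor_grid",
        _snapshot(can_scale=can_scale, Wpp=Wpp),
        tables={"grid": rows}, notes={"surviving": sorted(surviving)})


def run_theta_entrainment(
    can_scale: float,
    Wpp: float,
    amplitudes=(0.10, 0.11, 0.12, 0.13, 0.14, 0.15),
    frequency: float = 7.0,
    dt: float = 0.01,
) -> ExperimentReport:
    """Theta-band sinusoidal drive imposed on established persistent firing.

    A 7 Hz sinusoid to all cells starting 5 s after initiation offset;
    survival and frequency measured 10–20 s into the sinusoid.
    """
    s_on = STIM_OFFSET + 5000.0
    amplitudes = np.asarray(sorted(amplitudes), float)
    summaries = []
    for amp in amplitudes:
        proto = _init_protocol(range(3)) + [
            sinusoid(c, float(amp), s_on, 20000.0, frequency)
            for c in range(3)]
        net = build_three_pyramidal_network(Wpp, can_scale)
        res = simulate(net, proto, s_on + 20000.0, dt=dt)
        summaries.append(summarize_firing(res.spikes[0], s_on,
                                          horizon=20000.0))
    table = SweepTable("theta_amplitude", amplitudes, summaries)
    termination = locate_threshold(table, lambda s: s.frequency == 0)
    return ExperimentReport(
        "theta_entrainment",
        _snapshot(can_scale=can_scale, Wpp=Wpp, theta_Hz=frequency),
        tables={"amplitude": table},
        thresholds={"termination_boundary": termination})


def run_feedback_inhibition_sweep(
    can_scale: float,
    Wip_grid,
    tau_inh: float = 5.0,
    Wpp: float = 0.02,
    Wpi: float = DEFAULT_WPI,
    dt: float = 0.01,
) -> ExperimentReport:
    """Frequency versus inhibitory weight Wip in the 3+1 feedback circuit."""
    Wip_grid = np.asarray(sorted(Wip_grid), float)
    summaries = []
    int_rates = []
    for wip in Wip_grid:
        net = build_feedback_inhibition_network(
            Wpp, float(wip), Wpi=Wpi, tau_inh_decay=tau_inh,
            can_scale=can_scale)
        res = simulate(net, _init_protocol(range(3)), FREQ_T_END, dt=dt)
        summaries.append(summarize_firing(res.spikes[0], STIM_OFFSET,
                                          horizon=FREQ_T_END - STIM_OFFSET))
        int_rates.append(firing_frequency(
            res.spikes[3], (STIM_OFFSET + 10000.0, STIM_OFFSET + 20000.0)))
    table = SweepTable("Wip", Wip_grid, summaries)
    cutoff = locate_threshold(table, lambda s: s.frequency == 0)
    return ExperimentReport(
        "feedback_inhibition",
        _snapshot(can_scale=can_scale, Wpp=Wpp, Wpi=Wpi, tau_inh_ms=tau_inh),
        tables={"Wip": table},
        thresholds={"termination_boundary": cutoff},
        notes={"interneuron_Hz": int_rates})


def run_pattern_completion(
    can_scale: float,
    n_cued: int,
    wpp_grid,
    dt: float = 0.01,
) -> ExperimentReport:
    """Recruitment of non-cued cells by partial-cue stimulation.

    100 pA / 2 s to the cued cell(s) only; reported value is the mean
    frequency of the non-cued cells in the standard window, and the
    completion threshold is the smallest Wpp recruiting them.
    """
    if n_cued not in (1, 2):
        raise ValueError("n_cued must be 1 or 2")
    cued = list(range(n_cued))
    noncued = [c for c in range(3) if c not in cued]
    wpp_grid = np.asarray(sorted(wpp_grid), float)
    summaries = []
    for wpp in wpp_grid:
        net = build_three_pyramidal_network(float(wpp), can_scale)
        res = simulate(net, _init_protocol(cued, CUE_AMP), FREQ_T_END, dt=dt)
        merged = np.sort(np.concatenate([res.spikes[c] for c in noncued]))
        s = summarize_firing(merged, STIM_OFFSET,
                             horizon=FREQ_T_END - STIM_OFFSET)
        s.frequency /= len(noncued)      # mean over non-cued cells
        summaries.append(s)
    table = SweepTable("Wpp", wpp_grid, summaries)
    thr = locate_threshold(table, lambda s: s.frequency > 0)
    return ExperimentReport(
        "pattern_completion",
        _snapshot(can_scale=can_scale, n_cued=n_cued),
        tables={"Wpp": table}, thresholds={"completion": thr})


def run_cac_sensitivity(
    ca_c_grid=(0.65, 0.75, 0.85),
    dt: float = 0.01,
) -> ExperimentReport:
    """Sensitivity of initiation and maintenance to the CAN half-activation
    calcium scale [Ca]_c.

    For each value: (a) a brief strong pulse (500 pA / 86 ms) probing how
    many spikes suffice to ignite persistent firing, and (b) the standard
    2 s step probing maintained frequency.
    """
    rows = []
    for cac in ca_c_grid:
        p = PyramidalParams(
            const=replace(KineticConstants(), Ca_c=float(cac)))
        net_b = build_single_cell(1.0, params=p)
        res_b = simulate(net_b, [step(0, 0.5, STIM_ONSET, 86.0)],
                         STIM_ONSET + 86.0 + 31000.0, dt=dt)
        brief = summarize_firing(res_b.spikes[0], STIM_ONSET + 86.0)
        net_l = build_single_cell(1.0, params=p)
        res_l = simulate(net_l, _init_protocol([0]), HORIZON_T_END, dt=dt)
        long = summarize_firing(res_l.spikes[0], STIM_OFFSET)
        rows.append({"Ca_c_uM": cac,
                     "brief_class": brief.persistence.value,
                     "long_class": long.persistence.value,
                     "long_frequency_Hz": long.frequency})
    return ExperimentReport("cac_sensitivity", _snapshot(),
                            tables={"Ca_c": rows})


def run_voltage_clamp_check(dt: float = 0.01) -> ExperimentReport:
    """Voltage-clamp isolation of the CAN tail current.

    Hold at -50 mV, step to 0 mV for 10 ms, return to -50 mV.  The CAN
    component is the difference between the full-model current and the
    CAN-free control; after repolarization it appears as a slow inward
    tail that decays back to baseline (transient, not sustained) on the
    calcium-pool timescale, hence the long post-step window.
    """
    cmd = ClampCommand(((-50.0, 2000.0), (0.0, 10.0), (-50.0, 15000.0)))
    p_on = PyramidalParams()
    p_off = p_on.with_can_scale(0.0)
    t, I_on = voltage_clamp(p_on, cmd, dt=dt)
    _, I_off = voltage_clamp(p_off, cmd, dt=dt)
    diff = I_on - I_off
    # tail relative to the pre-step holding difference (the -50 mV hold
    # carries a standing Ca2+-activated component)
    base = float(diff[(t > 1900.0) & (t < 2000.0)].mean())
    after = t > 2010.0 + 50.0       # past repolarization transients
    tail = diff[after] - base
    peak_inward = float(tail.min())
    final = float(tail[-1])
    return ExperimentReport(
        "voltage_clamp_check", _snapshot(),
        tables={"t_ms": t, "difference_current_nA": diff},
        notes={"holding_difference_nA": base,
               "peak_inward_nA": peak_inward, "final_nA": final,
               "decayed_to_frac_of_peak":
                   abs(final) / abs(peak_inward)
                   if peak_inward != 0 else 0.0})


def calibrate_defaults(verify_only: bool = True, dt: float = 0.01) -> dict:
    """One-time calibration of the parameters the published set leaves open.

    Verifies (and, with ``verify_only=False``, grid-searches VT and the
    membrane area for) the two anchor behaviors that pin the free
    parameters:

    1. single-cell anchors — no persistent firing without the CAN current,
       long-lasting (>= 30 s) persistent firing at full CAN conductance,
       after the standard 150 pA / 2 s step;
    2. network anchor — the pure network's persistence onset lies between
       Wpp = 0.016 and 0.017 uS.

    Returns the frozen configuration dict; raises RuntimeError with the
    failed criterion if it cannot be satisfied.  Deterministic and
    idempotent: re-running always returns the same values.
    """
    candidates = [(KineticConstants().VT, PyramidalParams().area)]
    if not verify_only:
        # documented search box: VT in 0.2 mV steps, area in 2% steps
        candidates += [
            (vt, area)
            for vt in np.arange(-63.0, -60.0, 0.2)
            for area in np.arange(2.6e-4, 3.3e-4, 0.06e-4)
        ]
    failures = []
    for VT, area in candidates:
        const = replace(KineticConstants(), VT=float(VT))
        p = PyramidalParams(area=float(area), const=const)
        ok, why = _check_anchors(p, dt)
        if ok:
            return {
                "VT_mV": float(VT), "area_cm2": float(area),
                "Wpi_uS": DEFAULT_WPI, "weight_unit": "uS",
                "Ca_c_uM": const.Ca_c,
                "gbar_CAN_full_mS_cm2": GBAR_CAN_FULL,
            }
        failures.append(f"VT={VT}, area={area}: {why}")
    raise RuntimeError(
        "calibration failed for every candidate:\n" + "\n".join(failures))


def _check_anchors(p: PyramidalParams, dt: float):
    net0 = build_single_cell(0.0, params=p)
    res0 = simulate(net0, _init_protocol([0]), STIM_OFFSET + 1000.0, dt=dt)
    post0 = res0.spikes[0][res0.spikes[0] > STIM_OFFSET + 500.0]
    if post0.size:
        return False, "CAN-free cell keeps firing after the step"
    net1 = build_single_cell(1.0, params=p)
    res1 = simulate(net1, _init_protocol([0]), HORIZON_T_END, dt=dt)
    s1 = summarize_firing(res1.spikes[0], STIM_OFFSET)
    if s1.persistence is not PersistenceClass.LONG_LASTING:
        return False, f"full-CAN cell is {s1.persistence.value}"
    for wpp, want in ((0.016, False), (0.017, True)):
        net = build_three_pyramidal_network(wpp, 0.0, params=p)
        res = simulate(net, _init_protocol(range(3)), FREQ_T_END, dt=dt)
        f = firing_frequency(res.spikes[0],
                             (STIM_OFFSET + 10000.0, STIM_OFFSET + 20000.0))
        if (f > 0) != want:
            return False, f"pure network at Wpp={wpp}: {f:.1f} Hz"
    return True, ""
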