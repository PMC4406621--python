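"""Deterministic surrogate data and protocol fixtures.

Seeded generators for (a) surrogate spike trains and voltage traces with
known ground truth, so the spike-analysis stage can be tested independently
of the simulator, and (b) the named stimulus-protocol fixtures used by every
experiment driver (current steps, distractors, theta sinusoids, cue
stimulations).  All generators are pure functions of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stimulus import StimulusElement, sinusoid, step

__all__ = [
    "SurrogateSpec",
    "make_spike_train",
    "make_surrogate_voltage_trace",
    "make_protocol_fixture",
    "list_protocol_fixtures",
]


@dataclass(frozen=True)
class SurrogateSpec:
    """Surrogate spike-train description.

    A regular train at ``rate`` Hz over ``duration`` ms, each spike time
    perturbed by a uniform jitter of at most ``jitter`` x the inter-spike
    interval /2 (ordering-preserving).  The waveform template is a
    triangular spike of given width/peak pasted on a flat baseline.
    """

    rate: float                  # Hz
    duration: float              # ms
    jitter: float = 0.0          # fraction in [0, 1)
    seed: int = 0
    waveform_width: float = 2.0  # ms
    waveform_peak: float = 30.0  # mV
    baseline: float = -70.0      # mV

    def __post_init__(self):
        if self.rate < 0 or self.duration <= 0:
            raise ValueError("rate >= 0 and duration > 0 required")
        if not 0 <= self.jitter < 1:
            raise ValueError("jitter must be in [0, 1)")
        if self.waveform_peak <= self.baseline:
            raise ValueError("waveform peak must exceed baseline")


def make_spike_train(spec: SurrogateSpec) -> np.ndarray:
    """Spike times (ms): a regular grid at 1/rate with seeded uniform
    jitter bounded to preserve ordering.  floor(rate * duration) spikes."""
    if spec.rate == 0:
        return np.empty(0)
    isi = 1000.0 / spec.rate
    n = int(np.floor(spec.rate * spec.duration * 1e-3))
    base = (np.arange(n) + 0.5) * isi
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed)
        base = base + rng.uniform(-1, 1, n) * spec.jitter * isi / 2.0
    return base


def make_surrogate_voltage_trace(train: np.ndarray, spec: SurrogateSpec,
                                 dt: float = 0.1):
    """Baseline trace with a triangular spike template pasted at each train
    time.  Returns ``(t, V)``; raises if templates would overlap."""
    train = np.asarray(train, dtype=float)
    if train.size > 1 and np.diff(np.sort(train)).min() < spec.waveform_width:
        raise ValueError("spike templates overlap: waveform wider than ISI")
    t = np.arange(0.0, spec.duration + dt / 2, dt)
    V = np.full_like(t, spec.baseline)
    half = spec.waveform_width / 2.0
    for ts in train:
        mask = np.abs(t - ts) < half
        V[mask] = np.maximum(
            V[mask],
            spec.baseline + (spec.waveform_peak - spec.baseline)
            * (1.0 - np.abs(t[mask] - ts) / half))
    return t, V


# --- named protocol fixtures ------------------------------------------------

_STANDARD_ONSET = 1000.0      # ms of pre-stimulus rest in every protocol
_STANDARD_STEP = 0.15         # nA
_STANDARD_DUR = 2000.0        # ms
_CUE_AMP = 0.1                # nA


def _init_all(n_cells=3, amp=_STANDARD_STEP):
    return [step(c, amp, _STANDARD_ONSET, _STANDARD_DUR)
            for c in range(n_cells)]


def _fixtures() -> dict:
    offset = _STANDARD_ONSET + _STANDARD_DUR
    return {
        # single-cell initiation (Fig-1-style): 150 pA, 2 s
        "single_cell_step": [step(0, _STANDARD_STEP, _STANDARD_ONSET,
                                  _STANDARD_DUR)],
        # network initiation to all three pyramidal cells
        "network_init": _init_all(),
        # 1-cue / 2-cue pattern-completion protocols: 100 pA, 2 s
        "cue_one": [step(0, _CUE_AMP, _STANDARD_ONSET, _STANDARD_DUR)],
        "cue_two": [step(0, _CUE_AMP, _STANDARD_ONSET, _STANDARD_DUR),
                    step(1, _CUE_AMP, _STANDARD_ONSET, _STANDARD_DUR)],
        # brief strong pulse for the calcium-scale sensitivity runs
        "brief_pulse": [step(0, 0.5, _STANDARD_ONSET, 86.0)],
        # distractor: -400 pA, 20 ms to all cells, 5 s after offset
        "distractor_20ms": _init_all() + [
            step(c, -0.4, offset + 5000.0, 20.0) for c in range(3)],
        # theta drive: 7 Hz sinusoid to all cells, 5 s after offset
        "theta_7hz": _init_all() + [
            sinusoid(c, 0.12, offset + 5000.0, 20000.0, 7.0)
            for c in range(3)],
    }


def list_protocol_fixtures() -> list[str]:
    return sorted(_fixtures())


def make_protocol_fixture(name: str) -> list[StimulusElement]:
    """Registered stimulus protocols by name (see list_protocol_fixtures)."""
    fx = _fixtures()
    if name not in fx:
        raise KeyError(
            f"unknown protocol fixture {name!r}; known: {sorted(fx)}")
    return fx[name]
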