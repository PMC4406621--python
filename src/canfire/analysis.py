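"""Spike detection and persistent-firing measurement conventions.

The measurement pipeline mirrors the study design used throughout the
experiments:

* spikes = upward crossings of 0 mV with a 2 ms refractory debounce,
  linear-interpolated crossing times;
* persistent-firing frequency = spike count in the half-open window
  [offset + 10 s, offset + 20 s) divided by 10 s;
* persistence class relative to a 30 s horizon after stimulus offset:
  ``none`` (no post-offset spikes), ``long_lasting`` (still firing in the
  final 2 s before the horizon — operationalizing "does not stop by
  itself"), ``self_terminating`` otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum

import numpy as np
import pandas as pd

__all__ = [
    "PersistenceClass",
    "FiringSummary",
    "SweepTable",
    "detect_spikes",
    "firing_frequency",
    "classify_persistence",
    "summarize_firing",
    "locate_threshold",
]


class PersistenceClass(str, Enum):
    NONE = "none"
    SELF_TERMINATING = "self_terminating"
    LONG_LASTING = "long_lasting"


@dataclass
class FiringSummary:
    """Per-cell summary of one run's post-stimulus activity."""

    spike_times: np.ndarray
    frequency: float                 # Hz over the analysis window
    persistence: PersistenceClass
    last_spike: float | None         # ms, None if no spikes

    def __post_init__(self):
        if self.frequency < 0:
            raise ValueError("frequency must be >= 0")


@dataclass
class SweepTable:
    """Frequency/persistence summaries over a strictly increasing grid."""

    parameter: str
    values: np.ndarray
    summaries: list = field(default_factory=list)   # FiringSummary per value

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if np.any(np.diff(self.values) <= 0):
            raise ValueError("sweep grid must be strictly increasing")

    @property
    def frequencies(self) -> np.ndarray:
        return np.array([s.frequency for s in self.summaries])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            self.parameter: self.values[: len(self.summaries)],
            "frequency_Hz": [s.frequency for s in self.summaries],
            "persistence": [s.persistence.value for s in self.summaries],
        })


def detect_spikes(t: np.ndarray, V: np.ndarray, threshold: float = 0.0,
                  refractory: float = 2.0) -> np.ndarray:
    """Spike times (ms) from a sampled voltage trace.

    Upward crossings of ``threshold`` separated by at least ``refractory``
    ms; each crossing time is linearly interpolated between the bracketing
    samples.  The grid must be uniform.
    """
    t = np.asarray(t, dtype=float)
    V = np.asarray(V, dtype=float)
    if t.shape != V.shape:
        raise ValueError("t and V must have the same shape")
    if t.size < 2:
        return np.empty(0)
    dt = np.diff(t)
    if not np.allclose(dt, dt[0], rtol=1e-6, atol=1e-9):
        raise ValueError("non-uniform time grid")
    below = V[:-1] < threshold
    above = V[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - V[i]) / (V[i + 1] - V[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    return np.array(times)


def firing_frequency(spike_times: np.ndarray, window: tuple) -> float:
    """Mean rate (Hz) in the half-open window [t0, t1) given in ms."""
    t0, t1 = window
    if t1 <= t0:
        raise ValueError("window must satisfy t1 > t0")
    st = np.asarray(spike_times, dtype=float)
    count = int(np.count_nonzero((st >= t0) & (st < t1)))
    return count / ((t1 - t0) * 1e-3)


def classify_persistence(spike_times: np.ndarray, stim_offset: float,
                         horizon: float = 30000.0,
                         grace: float = 0.0) -> PersistenceClass:
    """Persistence class of the post-offset spiking relative to a horizon.

    ``long_lasting`` requires at least one spike in the final 2 s before
    ``stim_offset + horizon`` (firing continues through the horizon);
    ``none`` means no spikes in (offset + grace, offset + horizon] at all.
    ``grace`` (ms) attributes spikes whose upstroke was already in flight
    at stimulus offset to the stimulus itself, not to persistence.
    """
    if horizon <= 0:
        raise ValueError("horizon must be positive")
    st = np.asarray(spike_times, dtype=float)
    post = st[(st > stim_offset + grace) & (st <= stim_offset + horizon)]
    if post.size == 0:
        return PersistenceClass.NONE
    if np.any(post >= stim_offset + horizon - 2000.0):
        return PersistenceClass.LONG_LASTING
    return PersistenceClass.SELF_TERMINATING


def summarize_firing(spike_times: np.ndarray, stim_offset: float,
                     window_start: float = 10000.0,
                     window_len: float = 10000.0,
                     horizon: float = 30000.0,
                     grace: float = 100.0) -> FiringSummary:
    """FiringSummary with the standard post-offset measurement window
    [offset + window_start, offset + window_start + window_len).

    A 100 ms grace excludes spikes still in flight at stimulus offset from
    the persistence classification (they belong to the stimulus response).
    """
    st = np.asarray(spike_times, dtype=float)
    freq = firing_frequency(
        st, (stim_offset + window_start,
             stim_offset + window_start + window_len))
    cls = classify_persistence(st, stim_offset, horizon, grace)
    last = float(st.max()) if st.size else None
    return FiringSummary(spike_times=st, frequency=freq, persistence=cls,
                         last_spike=last)


def locate_threshold(sweep: SweepTable, predicate):
    """Boundary of a single false->true transition of ``predicate`` along
    the sweep grid.

    Returns ``(last_false_value, first_true_value)``, or ``None`` if the
    predicate is false everywhere.  If the predicate is true from the first
    grid point, returns ``(None, first_value)``.  A non-monotone pattern
    (multiple transitions) returns the extreme boundary pair and sets the
    ``multiple_transitions`` flag.
    """
    flags = np.array([bool(predicate(s)) for s in sweep.summaries])
    vals = sweep.values[: len(flags)]
    if not flags.any():
        return None
    first_true = int(np.argmax(flags))
    transitions = int(np.count_nonzero(np.diff(flags.astype(int)) != 0))
    boundary = (
        float(vals[first_true - 1]) if first_true > 0 else None,
        float(vals[first_true]),
    )
    if transitions > 1 or (flags[0] and transitions > 0):
        last_false = int(np.nonzero(~flags)[0].max())
        return {
            "multiple_transitions": True,
            "boundary": boundary,
            "extremes": (float(vals[last_false]), boundary[1]),
        }
    return boundary
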