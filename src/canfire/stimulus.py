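"""Stimulus protocol representation.

A protocol is a list of :class:`StimulusElement` objects — current steps or
sinusoids targeted at individual cells.  Amplitudes are point currents in nA
(positive = depolarizing); a sinusoid of amplitude A injects
``A * sin(2*pi*f*(t - onset) + phase)`` for the duration of the element, so
the first half-cycle is depolarizing at phase 0.

For voltage-clamp runs the command waveform is a piecewise-constant
:class:`ClampCommand`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["StimulusElement", "ClampCommand", "step", "sinusoid"]


@dataclass(frozen=True)
class StimulusElement:
    kind: str                 # "step" | "sinusoid"
    cell: int                 # target cell (global index)
    amplitude: float          # nA
    onset: float              # ms
    duration: float           # ms
    frequency: float = 0.0    # Hz (sinusoid only)
    phase: float = 0.0        # radians (sinusoid only)

    def __post_init__(self):
        if self.kind not in ("step", "sinusoid"):
            raise ValueError(f"unknown stimulus kind {self.kind!r}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.kind == "sinusoid" and self.frequency <= 0:
            raise ValueError("sinusoid needs a positive frequency")

    def to_dict(self) -> dict:
        return {
            "kind": self.kind, "cell": self.cell,
            "amplitude": self.amplitude, "onset": self.onset,
            "duration": self.duration, "frequency": self.frequency,
            "phase": self.phase,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StimulusElement":
        return cls(**d)


def step(cell: int, amplitude_nA: float, onset_ms: float,
         duration_ms: float) -> StimulusElement:
    """Current step of given amplitude (nA)."""
    return StimulusElement("step", cell, amplitude_nA, onset_ms, duration_ms)


def sinusoid(cell: int, amplitude_nA: float, onset_ms: float,
             duration_ms: float, frequency_Hz: float,
             phase: float = 0.0) -> StimulusElement:
    """Sinusoidal current injection (theta-style drive at ~7 Hz)."""
    return StimulusElement("sinusoid", cell, amplitude_nA, onset_ms,
                           duration_ms, frequency_Hz, phase)


@dataclass(frozen=True)
class ClampCommand:
    """Piecewise-constant voltage-clamp command: [(level mV, duration ms)]."""

    segments: tuple = field(default_factory=tuple)

    def __post_init__(self):
        segs = tuple((float(v), float(d)) for v, d in self.segments)
        if any(d <= 0 for _, d in segs):
            raise ValueError("segment durations must be positive")
        object.__setattr__(self, "segments", segs)

    @property
    def total_duration(self) -> float:
        return sum(d for _, d in self.segments)
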