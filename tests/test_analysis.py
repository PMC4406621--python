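"""Spike detection, frequency windows, persistence classes, thresholds."""

import numpy as np
import pytest

from canfire.analysis import (
    PersistenceClass,
    SweepTable,
    FiringSummary,
    classify_persistence,
    detect_spikes,
    firing_frequency,
    locate_threshold,
)
from canfire.synth import (
    SurrogateSpec,
    make_spike_train,
    make_surrogate_voltage_trace,
)


class TestDetectSpikes:
    def test_flat_trace_no_spikes(self):
        t = np.arange(0, 1000, 0.1)
        assert detect_spikes(t, np.full_like(t, -80.0)).size == 0

    def test_subthreshold_trace_no_spikes(self):
        spec = SurrogateSpec(rate=10, duration=2000, waveform_peak=-1.0)
        t, V = make_surrogate_voltage_trace(make_spike_train(spec), spec)
        assert detect_spikes(t, V).size == 0

    def test_seventeen_known_spikes(self):
        spec = SurrogateSpec(rate=17 / 3.0, duration=3000, jitter=0.1, seed=7)
        train = make_spike_train(spec)
        assert train.size == 17
        t, V = make_surrogate_voltage_trace(train, spec)
        det = detect_spikes(t, V)
        assert det.size == 17
        # each detection within the rising flank of its template
        assert np.all(np.abs(det - train) < spec.waveform_width)

    def test_exact_counts_on_many_random_surrogates(self):
        """Detector recovers the generator's ground truth on 200 randomized
        surrogate trains (rates 1-50 Hz, jitter up to 20%)."""
        rng = np.random.default_rng(42)
        for k in range(200):
            rate = float(rng.uniform(1.0, 50.0))
            jitter = float(rng.uniform(0.0, 0.2))
            spec = SurrogateSpec(rate=rate, duration=4000, jitter=jitter,
                                 seed=int(rng.integers(2 ** 31)),
                                 waveform_width=2.0)
            train = make_spike_train(spec)
            if train.size > 1 and np.diff(train).min() < spec.waveform_width:
                continue  # template overlap (generator refuses these)
            t, V = make_surrogate_voltage_trace(train, spec, dt=0.1)
            assert detect_spikes(t, V).size == train.size

    def test_refractory_debounce(self):
        t = np.arange(0, 10, 0.1)
        V = np.full_like(t, -70.0)
        V[(t > 2) & (t < 2.4)] = 20.0   # one crossing
        V[(t > 3) & (t < 3.4)] = 20.0   # second crossing 1 ms later
        det = detect_spikes(t, V, refractory=2.0)
        assert det.size == 1

    def test_nonuniform_grid_rejected(self):
        t = np.array([0.0, 0.1, 0.3, 0.4])
        with pytest.raises(ValueError):
            detect_spikes(t, np.zeros(4))

    def test_resampling_invariance(self):
        spec = SurrogateSpec(rate=20, duration=5000, jitter=0.15, seed=3)
        train = make_spike_train(spec)
        f = {}
        for dt in (0.05, 0.1):
            t, V = make_surrogate_voltage_trace(train, spec, dt=dt)
            det = detect_spikes(t, V)
            f[dt] = firing_frequency(det, (0.0, 5000.0))
        # within one interpolation bin of each other
        assert abs(f[0.05] - f[0.1]) <= 1.0 / 5.0


class TestFrequency:
    def test_arithmetic(self):
        st = np.linspace(0, 10000, 52, endpoint=False)
        assert firing_frequency(st, (0, 10000)) == pytest.approx(5.2)

    def test_empty_window(self):
        assert firing_frequency(np.array([]), (0, 1000)) == 0.0

    def test_half_open_boundary(self):
        st = np.array([500.0, 1000.0])
        assert firing_frequency(st, (0, 1000)) == pytest.approx(1.0)
        assert firing_frequency(st, (0, 1000.0001)) == pytest.approx(
            2 / 1.0000001e0, rel=1e-3)

    def test_bad_window(self):
        with pytest.raises(ValueError):
            firing_frequency(np.array([1.0]), (10, 10))


class TestPersistence:
    def test_long_lasting(self):
        st = np.arange(0, 33000, 200.0)   # 5 Hz spanning offset -> 30 s
        assert classify_persistence(st, 3000.0) is PersistenceClass.LONG_LASTING

    def test_self_terminating(self):
        st = np.arange(0, 15000, 200.0)   # ends 12 s after offset
        assert (classify_persistence(st, 3000.0)
                is PersistenceClass.SELF_TERMINATING)

    def test_none(self):
        st = np.arange(0, 3000, 100.0)    # only stimulus-driven spikes
        assert classify_persistence(st, 3000.0) is PersistenceClass.NONE

    def test_grace_excludes_spikes_in_flight(self):
        st = np.array([2990.0, 3001.0])
        assert classify_persistence(st, 3000.0) \
            is PersistenceClass.SELF_TERMINATING
        assert classify_persistence(st, 3000.0, grace=100.0) \
            is PersistenceClass.NONE

    def test_monotone_appending_spikes_never_demotes(self):
        base = np.arange(3100, 31000, 250.0)
        cls1 = classify_persistence(base, 3000.0)
        cls2 = classify_persistence(np.append(base, [32000.0, 32900.0]),
                                    3000.0)
        order = [PersistenceClass.NONE, PersistenceClass.SELF_TERMINATING,
                 PersistenceClass.LONG_LASTING]
        assert order.index(cls2) >= order.index(cls1)


def _summary(freq):
    return FiringSummary(spike_times=np.array([]), frequency=freq,
                         persistence=PersistenceClass.NONE, last_spike=None)


class TestLocateThreshold:
    def test_all_false(self):
        sw = SweepTable("w", [1, 2, 3], [_summary(0)] * 3)
        assert locate_threshold(sw, lambda s: s.frequency > 0) is None

    def test_simple_boundary(self):
        sw = SweepTable("w", [1, 2, 3, 4],
                        [_summary(f) for f in (0, 0, 5, 7)])
        assert locate_threshold(sw, lambda s: s.frequency > 0) == (2.0, 3.0)

    def test_true_from_start(self):
        sw = SweepTable("w", [1, 2], [_summary(5), _summary(6)])
        assert locate_threshold(sw, lambda s: s.frequency > 0) == (None, 1.0)

    def test_multiple_transitions_flagged(self):
        sw = SweepTable("w", [1, 2, 3, 4],
                        [_summary(f) for f in (0, 5, 0, 7)])
        out = locate_threshold(sw, lambda s: s.frequency > 0)
        assert out["multiple_transitions"]
        assert out["boundary"] == (1.0, 2.0)
        assert out["extremes"] == (3.0, 2.0)

    def test_grid_must_increase(self):
        with pytest.raises(ValueError):
            SweepTable("w", [1, 1, 2], [])
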