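"""Baseline estimation, event segmentation and classification."""

import math

import numpy as np
import pytest

import porekinetics as pk
from porekinetics.detect import BaselineError, DetectionParams


def make_trace(samples, fs=20_000.0):
    return pk.CurrentTrace(samples=np.asarray(samples, float), sampling_rate_hz=fs)


class TestBaseline:
    def test_constant_trace(self):
        trace = make_trace(np.full(4000, 150.0))
        level, sd = pk.estimate_baseline(trace)
        assert level == 150.0
        assert sd == 0.0

    def test_robust_to_blocked_duty_cycle(self):
        cfg = pk.SimulationConfig(
            duration_s=20.0,
            species=pk.condition_species("cc", duplex_rate_hz=4.0, ss_rate_hz=3.0),
            filter_cutoff_hz=None,
            seed=21,
        )
        truth = pk.sample_event_train(cfg)
        duty = sum(ev.dwell_s for ev in truth) / cfg.duration_s
        assert 0.1 < duty < 0.5
        trace = pk.render_trace(truth, cfg)
        level, sd = pk.estimate_baseline(trace)
        assert abs(level - 150.0) < 0.5
        assert abs(sd - 2.0) < 0.5

    def test_mostly_blocked_trace_raises(self):
        # blocked ~95% of the time with open gaps shorter than the window
        fs = 20_000
        x = np.full(fs * 2, 36.8)
        for k in range(0, fs * 2, fs // 5):
            x[k : k + fs // 100] = 150.0
        with pytest.raises(BaselineError, match="mostly blocked"):
            pk.estimate_baseline(make_trace(x))


class TestDetectEvents:
    def test_noiseless_roundtrip_recovers_every_event(self, noiseless_recording):
        truth, trace = noiseless_recording
        events = pk.detect_events(trace)
        assert len(events) == len(truth)
        pairs = pk.match_events(truth, events)
        assert len(pairs) == len(truth)
        period = 1.0 / trace.sampling_rate_hz
        for tr_ev, det in pairs:
            assert abs(det.t_off_s - tr_ev.dwell_s) <= period + 1e-12
            assert abs(det.residual_pa - tr_ev.residual_mean_pa) < 1e-6
            assert det.label == pk.classify_dwell(tr_ev.dwell_s)
            assert det.ending_spike == tr_ev.ending_spike

    def test_flat_trace_yields_no_events(self):
        trace = make_trace(np.full(4000, 150.0))
        assert pk.detect_events(trace) == []

    @pytest.mark.parametrize(
        "dwell_s,expected",
        [(0.0002, pk.SPIKE_SS), (0.005, pk.RECT_SS), (0.059, pk.DUPLEX)],
    )
    def test_dwell_classification_rules(self, dwell_s, expected):
        cfg = pk.SimulationConfig(
            duration_s=1.0, noise_sd_pa=0.0, filter_cutoff_hz=None, seed=0
        )
        ev = pk.EventTruth(0.4, dwell_s, expected, 36.8, 0)
        events = pk.detect_events(pk.render_trace([ev], cfg))
        assert len(events) == 1
        assert events[0].label == expected

    def test_ending_spike_flag_and_residual_exclusion(self):
        cfg = pk.SimulationConfig(
            duration_s=1.0, noise_sd_pa=0.0, filter_cutoff_hz=None, seed=0
        )
        ev = pk.EventTruth(
            0.3, 0.05, pk.DUPLEX, 36.8, 0,
            ending_spike=True, spike_level_pa=18.4, spike_width_s=0.001,
        )
        det = pk.detect_events(pk.render_trace([ev], cfg))[0]
        assert det.ending_spike
        assert det.residual_pa == pytest.approx(36.8, abs=1e-9)

    def test_events_disjoint_ordered_with_consistent_t_on(self, noisy_recording):
        cfg, _, trace = noisy_recording
        events = pk.detect_events(trace)
        assert events
        assert math.isnan(events[0].t_on_s)
        for a, b in zip(events, events[1:]):
            assert b.start_s >= a.end_s
            assert b.t_on_s == pytest.approx(b.start_s - a.end_s)
        assert sum(ev.t_off_s for ev in events) <= cfg.duration_s

    def test_detection_invariant_to_constant_offset(self, noisy_recording):
        # the threshold is recomputed from the shifted baseline, so the same
        # events reappear; filter-smeared edges may move a crossing by a sample
        _, _, trace = noisy_recording
        base = pk.detect_events(trace)
        shifted = pk.CurrentTrace(trace.samples + 10.0, trace.sampling_rate_hz)
        moved = pk.detect_events(shifted)
        assert len(moved) == len(base)
        assert [ev.label for ev in moved] == [ev.label for ev in base]
        period = 1.0 / trace.sampling_rate_hz
        for a, b in zip(base, moved):
            assert abs(a.start_s - b.start_s) <= 2 * period

    def test_class_confusion_below_one_percent_at_study_noise(self, noisy_recording):
        _, truth, trace = noisy_recording
        events = pk.detect_events(trace)
        pairs = pk.match_events(truth, events)
        assert len(pairs) >= 0.99 * len(truth)
        wrong = sum(
            det.label != pk.classify_dwell(tr_ev.dwell_s) for tr_ev, det in pairs
        )
        assert wrong / len(pairs) < 0.01


class TestEventFrequency:
    @staticmethod
    def _ss_events(n):
        return [
            pk.BlockEvent(
                start_s=i * 0.1, end_s=i * 0.1 + 0.001, t_off_s=0.001,
                residual_pa=17.4, label=pk.RECT_SS,
            )
            for i in range(n)
        ]

    def test_frequency_is_count_over_duration(self):
        events = self._ss_events(652)
        assert pk.ssdna_frequency(events, 100.0) == pytest.approx(6.52)

    def test_no_events_zero_frequency(self):
        assert pk.event_frequency([], 10.0) == 0.0

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            pk.event_frequency([], 0.0)

    def test_class_filter_selects_only_requested(self):
        events = self._ss_events(10) + [
            pk.BlockEvent(5.0, 5.1, t_off_s=0.1, residual_pa=36.8, label=pk.DUPLEX)
        ]
        assert pk.event_frequency(events, 10.0, classes=(pk.DUPLEX,)) == 0.1
        assert pk.ssdna_frequency(events, 10.0) == 1.0


def test_events_csv_roundtrip(tmp_path, noisy_recording):
    _, _, trace = noisy_recording
    events = pk.detect_events(trace)
    path = tmp_path / "events.csv"
    pk.write_events_csv(events, path)
    back = pk.read_events_csv(path)
    assert len(back) == len(events)
    assert back[3].label == events[3].label
    assert back[3].t_off_s == pytest.approx(events[3].t_off_s)
    assert math.isnan(back[0].t_on_s)


def test_detection_params_validation():
    with pytest.raises(ValueError):
        DetectionParams(threshold_fraction=1.5).validate()
    with pytest.raises(ValueError):
        DetectionParams(duplex_threshold_s=0.0005).validate()
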