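"""Event-train sampling and trace rendering."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import porekinetics as pk
from porekinetics.simulate import MIN_GAP_S


def duplex_only_cfg(tau_components, rate_hz=1.0, duration_s=1000.0, seed=0, **kw):
    return pk.SimulationConfig(
        duration_s=duration_s,
        species=[
            pk.EventClassSpec(
                pk.DUPLEX, rate_hz, list(tau_components), 36.8, 0.0, **kw
            )
        ],
        noise_sd_pa=0.0,
        filter_cutoff_hz=None,
        seed=seed,
    )


class TestSampleEventTrain:
    def test_zero_rates_give_empty_train(self):
        cfg = pk.SimulationConfig(
            duration_s=10.0,
            species=[pk.EventClassSpec(pk.DUPLEX, 0.0, [(0.059, 1.0)], 36.8)],
            seed=0,
        )
        assert pk.sample_event_train(cfg) == []

    def test_mean_dwell_matches_law_of_large_numbers(self):
        cfg = duplex_only_cfg([(0.059, 1.0)], seed=1)
        truth = pk.sample_event_train(cfg)
        dwells = np.array([ev.dwell_s for ev in truth])
        se = 0.059 / math.sqrt(dwells.size)
        assert abs(dwells.mean() - 0.059) < 3 * se

    def test_mixture_component_fractions(self):
        cfg = duplex_only_cfg([(0.051, 0.3), (0.384, 0.7)], seed=2)
        truth = pk.sample_event_train(cfg)
        frac0 = np.mean([ev.component == 0 for ev in truth])
        se = math.sqrt(0.3 * 0.7 / len(truth))
        assert abs(frac0 - 0.3) < 3 * se

    def test_arrival_rate_recovered(self):
        cfg = pk.SimulationConfig(
            duration_s=500.0,
            species=pk.condition_species("cc_ag", duplex_rate_hz=0.3, ss_rate_hz=4.10),
            seed=3,
        )
        truth = pk.sample_event_train(cfg)
        f_ss = pk.ssdna_frequency(truth, cfg.duration_s)
        se = math.sqrt(4.10 / cfg.duration_s)
        assert abs(f_ss - 4.10) < 3 * se

    def test_excessive_duty_cycle_rejected(self):
        cfg = duplex_only_cfg([(0.384, 1.0)], rate_hz=2.0, duration_s=10.0)
        with pytest.raises(ValueError, match="duty cycle"):
            pk.sample_event_train(cfg)

    def test_seed_determinism_is_bitwise(self):
        import pandas.testing as pdt

        from porekinetics.simulate import truth_to_frame

        cfg = duplex_only_cfg([(0.051, 0.3), (0.384, 0.7)], duration_s=50.0, seed=7)
        a, b = pk.sample_event_train(cfg), pk.sample_event_train(cfg)
        pdt.assert_frame_equal(truth_to_frame(a), truth_to_frame(b))

    @given(seed=st.integers(0, 2**16), rate=st.floats(0.1, 2.0))
    def test_train_sorted_and_non_overlapping(self, seed, rate):
        cfg = pk.SimulationConfig(
            duration_s=20.0,
            species=pk.condition_species("cc", duplex_rate_hz=rate, ss_rate_hz=2.0),
            seed=seed,
        )
        truth = pk.sample_event_train(cfg)
        for a, b in zip(truth, truth[1:]):
            assert b.start_s - a.end_s >= MIN_GAP_S - 1e-12
        assert all(ev.end_s <= cfg.duration_s for ev in truth)
        assert all(ev.dwell_s > 0 for ev in truth)

    def test_ssdna_dwells_respect_class_windows(self):
        cfg = pk.SimulationConfig(
            duration_s=200.0,
            species=pk.condition_species("cc", duplex_rate_hz=0.0, ss_rate_hz=5.0),
            seed=4,
        )
        truth = pk.sample_event_train(cfg)
        assert truth
        for ev in truth:
            assert pk.classify_dwell(ev.dwell_s) == ev.label

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError, match="sum to 1"):
            pk.EventClassSpec(pk.DUPLEX, 1.0, [(0.05, 0.5), (0.4, 0.4)], 36.8).validate()
        with pytest.raises(ValueError, match="duration_s"):
            pk.SimulationConfig(duration_s=0.0).validate()
        with pytest.raises(ValueError, match="cutoff"):
            pk.SimulationConfig(duration_s=1.0, filter_cutoff_hz=15_000.0).validate()


class TestRenderTrace:
    def test_pure_baseline_statistics(self):
        cfg = pk.SimulationConfig(
            duration_s=5.0, noise_sd_pa=2.0, filter_cutoff_hz=None, seed=8
        )
        trace = pk.render_trace([], cfg)
        n = trace.n_samples
        assert n == round(cfg.duration_s * cfg.sampling_rate_hz)
        assert abs(trace.samples.mean() - 150.0) < 3 * 2.0 / math.sqrt(n)
        assert abs(trace.samples.std() - 2.0) < 0.2

    def test_single_noiseless_event_is_exact(self):
        cfg = pk.SimulationConfig(
            duration_s=1.0, noise_sd_pa=0.0, filter_cutoff_hz=None, seed=0
        )
        ev = pk.EventTruth(0.25, 0.1, pk.DUPLEX, 36.8, 0)
        trace = pk.render_trace([ev], cfg)
        assert int((trace.samples == 36.8).sum()) == round(0.1 * 20_000)
        assert trace.samples[0] == 150.0

    def test_lowpass_filter_reduces_noise(self):
        cfg = pk.SimulationConfig(duration_s=2.0, noise_sd_pa=2.0, seed=9)
        unfiltered = pk.render_trace(
            [], pk.SimulationConfig(duration_s=2.0, noise_sd_pa=2.0,
                                    filter_cutoff_hz=None, seed=9)
        )
        filtered = pk.render_trace([], cfg)
        assert filtered.samples[4000:].std() < unfiltered.samples[4000:].std()

    def test_overlapping_truth_rejected(self):
        cfg = pk.SimulationConfig(duration_s=1.0, seed=0)
        evs = [
            pk.EventTruth(0.1, 0.2, pk.DUPLEX, 36.8, 0),
            pk.EventTruth(0.2, 0.1, pk.DUPLEX, 36.8, 0),
        ]
        with pytest.raises(ValueError, match="overlap"):
            pk.render_trace(evs, cfg)


class TestInterchangeFormats:
    def test_text_trace_roundtrip(self, tmp_path):
        cfg = pk.SimulationConfig(duration_s=0.05, noise_sd_pa=1.0, seed=1)
        trace = pk.render_trace([], cfg)
        path = tmp_path / "trace.csv"
        pk.write_trace_text(trace, path)
        back = pk.read_trace_text(path)
        assert back.sampling_rate_hz == pytest.approx(20_000.0)
        np.testing.assert_allclose(back.samples, trace.samples, rtol=1e-6)

    def test_binary_trace_roundtrip(self, tmp_path):
        cfg = pk.SimulationConfig(duration_s=0.05, noise_sd_pa=1.0, seed=2)
        trace = pk.render_trace([], cfg)
        path = tmp_path / "trace.bin"
        pk.write_trace_binary(trace, path)
        back = pk.read_trace(path)  # dialect sniffing
        assert back.sampling_rate_hz == 20_000.0
        np.testing.assert_allclose(back.samples, trace.samples, atol=1e-4)

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.bin"
        path.write_bytes(b"NOTMAGIC" + b"\0" * 32)
        with pytest.raises(ValueError, match="magic"):
            pk.read_trace_binary(path)

    def test_truth_csv_roundtrip(self, tmp_path, noiseless_recording):
        truth, _ = noiseless_recording
        path = tmp_path / "truth.csv"
        pk.write_truth_csv(truth, path)
        back = pk.read_truth_csv(path)
        assert len(back) == len(truth)
        assert back[0].label == truth[0].label
        assert back[0].start_s == pytest.approx(truth[0].start_s)
        assert [ev.ending_spike for ev in back] == [ev.ending_spike for ev in truth]
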