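"""EMG conditioning, event detection, stride segmentation and ERAs."""

import numpy as np
import pytest

from reflexgait import preprocessing as pp
from reflexgait.preprocessing import GaitEvents

RATE = 1000.0


class TestConditionEmg:
    def test_dc_input_is_removed(self):
        env = pp.condition_emg(np.ones(5000), RATE).values
        assert env[1000:-1000].max() < 1e-3

    def test_rectified_sine_mean_two_over_pi(self):
        # 2 kHz sampling: 20 samples/cycle keeps the discrete rectified mean
        # within a fraction of a percent of the continuous value 2/pi
        rate = 2000.0
        t = np.arange(int(5 * rate)) / rate
        env = pp.condition_emg(np.sin(2 * np.pi * 100 * t), rate).values
        settled = env[4000:-4000]
        assert np.mean(settled) == pytest.approx(2 / np.pi, rel=0.02)

    def test_rate_below_band_edge_rejected(self):
        with pytest.raises(ValueError, match="band edge"):
            pp.condition_emg(np.zeros(4000), 800.0)

    def test_output_non_negative(self):
        rng = np.random.default_rng(0)
        env = pp.condition_emg(rng.standard_normal(4000), RATE).values
        assert env.min() >= 0.0

    def test_zero_lag_on_symmetric_burst(self):
        # envelope peak of a symmetric tone burst stays at the burst centre
        t = np.arange(int(2 * RATE)) / RATE
        centre = 1.0
        burst = np.sin(2 * np.pi * 120 * t) * np.exp(-(((t - centre) / 0.05) ** 2))
        env = pp.condition_emg(burst, RATE).values
        assert abs(t[int(np.argmax(env))] - centre) <= 0.002


class TestDetectHeelStrikes:
    def test_all_zero_channel_yields_no_events(self):
        assert pp.detect_heel_strikes(np.zeros(1000), RATE).size == 0

    def test_debounce_merges_close_crossings(self):
        x = np.zeros(1000)
        x[100:110] = 1.0
        x[130:140] = 1.0  # 20 ms later: merged under 50 ms debounce
        ev = pp.detect_heel_strikes(x, RATE, debounce_s=0.05, refine_onset=False)
        assert len(ev) == 1

    def test_invariant_to_positive_rescaling(self):
        rng = np.random.default_rng(1)
        x = np.clip(np.sin(2 * np.pi * np.arange(4000) / 1000.0), 0, None)
        a = pp.detect_heel_strikes(x, RATE)
        b = pp.detect_heel_strikes(37.5 * x, RATE)
        np.testing.assert_array_equal(a, b)

    def test_onset_refinement_on_synthetic_pulse(self, small_setup):
        rec_cfg = small_setup["config"]
        from reflexgait.synthetic import generate_fsr_signals

        rec = generate_fsr_signals(small_setup["events"], rec_cfg)
        det = pp.detect_heel_strikes(rec.channel("FSR_L_heel"), rec.rate_hz)
        true = small_setup["events"].left_times
        true = true[true < rec.duration_s - 1.0]
        assert np.abs(det[: len(true)] - true).max() <= 2.0 / rec.rate_hz


class TestSegmentStrides:
    def test_regular_strikes(self):
        ev = GaitEvents(left_times=np.array([0.0, 1.0, 2.0]))
        seg = pp.segment_strides(ev, "left")
        assert seg.n_strides == 2
        np.testing.assert_allclose(seg.durations, [1.0, 1.0])
        assert seg.mean_duration_s == pytest.approx(1.0)

    def test_jittered_mean_matches_arithmetic_mean(self):
        rng = np.random.default_rng(2)
        times = np.cumsum(1.0 + 0.1 * rng.standard_normal(30))
        seg = pp.segment_strides(GaitEvents(left_times=times), "left")
        assert seg.mean_duration_s == pytest.approx(np.diff(times).mean())

    def test_fewer_than_two_strikes_rejected(self):
        with pytest.raises(ValueError):
            pp.segment_strides(GaitEvents(left_times=np.array([1.0])), "left")

    def test_contralateral_strike_inside_each_stride(self, small_setup):
        ev = small_setup["events"]
        seg = pp.segment_strides(ev, "left")
        for t0, dur, r in zip(seg.start_times, seg.durations, ev.right_times):
            assert t0 < r < t0 + dur


class TestEra:
    def test_periodic_signal_tiles_one_period(self):
        period = 0.5
        n = int(10 * RATE)
        t = np.arange(n) / RATE
        x = 1.0 + np.cos(2 * np.pi * t / period)
        events = np.arange(2.0, 7.0, period)
        era = pp.event_related_average(x, RATE, events, stride_s=period)
        half = era.lags_s.size // 2
        np.testing.assert_allclose(era.mean[half:], era.mean[: half + 1], atol=1e-9)

    def test_single_event_equals_raw_window(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(3000)
        era = pp.event_related_average(x, RATE, np.array([1.5]), stride_s=0.5)
        np.testing.assert_array_equal(era.mean, x[1000:2001])

    def test_out_of_range_events_dropped_and_counted(self):
        x = np.zeros(2000)
        era = pp.event_related_average(x, RATE, np.array([0.1, 1.0, 1.95]), stride_s=0.5)
        assert era.n_events == 1 and era.n_dropped == 2

    def test_no_usable_events_rejected(self):
        with pytest.raises(ValueError):
            pp.event_related_average(np.zeros(100), RATE, np.array([0.01]), stride_s=0.5)

    def test_era_error_decays_with_event_count(self, small_setup):
        # averaging suppresses envelope noise roughly as 1/sqrt(N)
        from reflexgait import synthetic as syn

        cfg, events, rec = small_setup["config"], small_setup["events"], small_setup["rec"]
        k = next(k for k in small_setup["kernels"] if (k.muscle, k.foot) == ("BF", "IH"))
        env = pp.condition_emg(rec.channel("EMG_L_BF"), rec.rate_hz).values
        oracle = syn.true_envelope(events, k, cfg, "L", rec.duration_s)
        seg = pp.segment_strides(events, "left")
        errs = []
        for n_events in (4, 16, 44):
            ev = events.left_times[1 : 1 + n_events]
            era = pp.event_related_average(env, rec.rate_hz, ev, seg.mean_duration_s)
            oracle_era = pp.event_related_average(oracle, rec.rate_hz, ev, seg.mean_duration_s)
            errs.append(np.sqrt(np.mean((era.mean - oracle_era.mean) ** 2)))
        assert errs[2] < errs[1] < errs[0]


class TestMeanHeelTemplate:
    def test_identical_pulses_average_to_the_pulse(self):
        pulse = np.concatenate([np.hanning(400), np.zeros(600)])
        x = np.tile(pulse, 6)
        ev = GaitEvents(left_times=np.arange(6.0))
        seg = pp.segment_strides(ev, "left")
        tmpl = pp.mean_heel_template(x, RATE, seg)
        assert tmpl.size == 1000
        np.testing.assert_allclose(tmpl, pulse, atol=1e-9)

    def test_template_length_is_one_mean_stride(self, small_setup, small_segmentation):
        heel = small_setup["rec"].channel("FSR_L_heel")
        tmpl = pp.mean_heel_template(heel, small_setup["rec"].rate_hz, small_segmentation)
        expected = int(round(small_segmentation.mean_duration_s * small_setup["rec"].rate_hz))
        assert tmpl.size == expected

    def test_matches_stack_and_mean_oracle(self):
        rng = np.random.default_rng(5)
        x = rng.random(5000)
        ev = GaitEvents(left_times=np.array([0.0, 1.0, 2.0, 3.0, 4.0]))
        seg = pp.segment_strides(ev, "left")
        tmpl = pp.mean_heel_template(x, RATE, seg)
        oracle = np.mean([x[i * 1000 : (i + 1) * 1000] for i in range(4)], axis=0)
        np.testing.assert_allclose(tmpl, oracle, atol=1e-9)
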