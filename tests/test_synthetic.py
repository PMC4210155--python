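"""Synthetic gait-recording generator: speed profiles, events, FSR, EMG."""

import numpy as np
import pytest

from reflexgait import synthetic as syn
from reflexgait import preprocessing as pp
from reflexgait.system_id import nrmse
from reflexgait.preprocessing import GaitEvents


class TestSpeedSequence:
    def test_sequence_one_layout(self):
        # 20 settings repeated twice over a 0.5 m/s range
        prof = syn.generate_speed_sequence(20, (0.9, 1.4), repeats=2, seed=3)
        assert len(prof.settings) == 40
        d = np.abs(np.diff(prof.speeds))
        changing = d[d > 1e-12]
        assert np.all((changing >= 0.05 - 1e-9) & (changing <= 0.10 + 1e-9))

    def test_single_setting_is_constant(self):
        prof = syn.generate_speed_sequence(1, (1.0, 1.5), repeats=1, seed=0)
        assert len(prof.settings) == 1
        assert prof.total_range == 0.0

    def test_realized_range_brackets_requested_width(self):
        # brute force over 100 seeds: the walk must nearly span the range
        for seed in range(100):
            prof = syn.generate_speed_sequence(20, (0.9, 1.4), repeats=2, seed=seed)
            assert prof.total_range <= 0.5 + 1e-9
            assert prof.total_range >= 0.5 - 0.1 - 1e-9

    def test_narrow_range_rejected(self):
        with pytest.raises(ValueError, match="narrower"):
            syn.generate_speed_sequence(5, (1.0, 1.02), seed=0)

    def test_range_outside_walking_speeds_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_speed_sequence(5, (0.1, 0.6), seed=0)


class TestGaitEvents:
    def test_constant_speed_gives_constant_cadence(self):
        cfg = syn.SynthConfig(seed=1, stride_jitter=0.0)
        prof = syn.generate_speed_sequence(1, (1.25, 1.25), seed=1,
                                           strides_per_setting=10, config=cfg)
        ev = syn.generate_gait_events(prof, cfg)
        np.testing.assert_allclose(np.diff(ev.left_times),
                                   np.diff(ev.left_times)[0], rtol=1e-9)

    def test_strides_per_setting_matches_request(self):
        cfg = syn.SynthConfig(seed=2)
        prof = syn.generate_speed_sequence(4, (0.9, 1.4), seed=2,
                                           strides_per_setting=25, config=cfg)
        ev = syn.generate_gait_events(prof, cfg)
        assert len(ev.left_times) - 1 == 4 * 25

    def test_contralateral_strike_near_mid_stride(self):
        cfg = syn.SynthConfig(seed=3)
        prof = syn.generate_speed_sequence(3, (0.9, 1.4), seed=3,
                                           strides_per_setting=10, config=cfg)
        ev = syn.generate_gait_events(prof, cfg)
        phases = [
            (r - ev.left_times[i]) / (ev.left_times[i + 1] - ev.left_times[i])
            for i, r in zip(range(len(ev.left_times) - 1), ev.right_times)
        ]
        assert np.allclose(np.mean(phases), 0.5, atol=0.05)
        assert np.all((np.array(phases) > 0.3) & (np.array(phases) < 0.7))


class TestFsrSignals:
    def test_empty_events_give_all_zero_channels(self):
        cfg = syn.SynthConfig(seed=0)
        rec = syn.generate_fsr_signals(GaitEvents(), cfg, duration_s=2.0)
        assert np.all(rec.samples == 0)

    def test_single_stance_pulse_onset_at_event(self):
        cfg = syn.SynthConfig(seed=0)
        ev = GaitEvents(left_times=np.array([1.0]))
        rec = syn.generate_fsr_signals(ev, cfg, duration_s=3.0)
        heel = rec.channel("FSR_L_heel")
        onset = np.flatnonzero(heel > 0)[0]
        assert abs(onset - 1000) <= 1
        assert heel[:999].max() == 0.0

    def test_zero_in_swing_and_unimodal_per_stance(self, small_setup):
        rec = syn.generate_fsr_signals(small_setup["events"], small_setup["config"])
        heel = rec.channel("FSR_L_heel")
        assert heel.min() >= 0.0 and heel.max() <= 1.0 + 1e-9

    def test_detection_roundtrip_within_two_samples(self, small_setup):
        rec = syn.generate_fsr_signals(small_setup["events"], small_setup["config"])
        for side, foot in (("L", "left_times"), ("R", "right_times")):
            det = pp.detect_heel_strikes(rec.channel(f"FSR_{side}_heel"), rec.rate_hz)
            true = getattr(small_setup["events"], foot)
            true = true[true < rec.duration_s - 1.0]
            assert len(det) >= len(true)
            err = np.abs(det[: len(true)] - true)
            assert err.max() <= 2.0 / rec.rate_hz

    def test_overlapping_stances_rejected(self):
        cfg = syn.SynthConfig(seed=0)
        ev = GaitEvents(left_times=np.array([1.0, 1.05]))
        with pytest.raises(ValueError, match="overlap"):
            syn.generate_fsr_signals(ev, cfg, duration_s=3.0)


class TestEmg:
    def test_no_kernel_for_muscle_leaves_noise_floor(self, small_setup):
        cfg, events = small_setup["config"], small_setup["events"]
        kernels = [k for k in small_setup["kernels"] if k.muscle == "RF"]
        rec = syn.generate_emg(events, kernels, cfg, duration_s=20.0)
        env_bf = pp.condition_emg(rec.channel("EMG_L_BF"), rec.rate_hz).values
        env_rf = pp.condition_emg(rec.channel("EMG_L_RF"), rec.rate_hz).values
        assert env_bf.max() < 0.1 * env_rf.max()

    def test_conditioned_envelope_matches_convolution_oracle(self, small_setup):
        cfg, events = small_setup["config"], small_setup["events"]
        rec = small_setup["rec"]
        k = next(k for k in small_setup["kernels"] if (k.muscle, k.foot) == ("RF", "CH"))
        oracle = syn.true_envelope(events, k, cfg, "L", rec.duration_s)
        env = pp.condition_emg(rec.channel("EMG_L_RF"), rec.rate_hz).values
        n = min(env.size, oracle.size)
        assert nrmse(env[:n], oracle[:n]) < 0.10

    def test_envelope_grows_with_belt_speed(self):
        cfg = syn.SynthConfig(seed=9, envelope_snr=100.0, speed_gain=0.8, stride_jitter=0.0)
        slow = GaitEvents(left_times=np.arange(5) * 1.4,
                          left_speeds=np.full(5, 1.0))
        fast = GaitEvents(left_times=np.arange(5) * 1.4,
                          left_speeds=np.array([1.0, 1.2, 1.4, 1.6, 1.6]))
        k = syn.default_kernels(cfg)[1]  # BF/IH
        env_slow = syn.true_envelope(slow, k, cfg, "L", 8.0)
        env_fast = syn.true_envelope(fast, k, cfg, "L", 8.0)
        # per-stride peaks rise monotonically under a positive speed gain
        peaks_fast = [env_fast[int(1.4 * i * 1000):int(1.4 * (i + 1) * 1000)].max() for i in range(1, 4)]
        peaks_slow = [env_slow[int(1.4 * i * 1000):int(1.4 * (i + 1) * 1000)].max() for i in range(1, 4)]
        assert np.all(np.diff(peaks_fast) > 0)
        assert np.allclose(np.diff(peaks_slow), 0.0, atol=1e-6)

    def test_kernel_longer_than_two_strides_rejected(self, small_setup):
        cfg, events = small_setup["config"], small_setup["events"]
        bad = syn.GroundTruthKernel("RF", "CH", np.ones(int(5.0 * cfg.rate_hz)), cfg.rate_hz)
        with pytest.raises(ValueError, match="two strides"):
            syn.generate_emg(events, [bad], cfg, duration_s=10.0)


class TestFixture:
    def test_roundtrip_and_determinism(self, tmp_path):
        from reflexgait.io import read_recording
        from reflexgait.synthetic import fixture_digest

        cfg = syn.SynthConfig(seed=11)
        prof = syn.generate_speed_sequence(2, (1.0, 1.3), seed=11,
                                           strides_per_setting=3, config=cfg)
        digests = []
        for sub in ("a", "b"):
            rec, events, kernels = syn.generate_recording(prof, cfg)
            paths = syn.write_fixture(rec, events, kernels, tmp_path / sub, cfg)
            digests.append(fixture_digest(paths))
            back = read_recording(paths["recording"], cfg.rate_hz)
            np.testing.assert_allclose(back.samples, rec.samples, rtol=1e-8, atol=1e-9)
            assert len(back.channels) == 16
        assert digests[0] == digests[1]

    def test_same_seed_same_output(self):
        cfg = syn.SynthConfig(seed=21)
        prof = syn.generate_speed_sequence(2, (1.0, 1.3), seed=21,
                                           strides_per_setting=3, config=cfg)
        a, ea, _ = syn.generate_recording(prof, cfg)
        b, eb, _ = syn.generate_recording(prof, cfg)
        np.testing.assert_array_equal(a.samples, b.samples)
        np.testing.assert_array_equal(ea.left_times, eb.left_times)
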