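import numpy as np
import pytest
from scipy import signal as sig

from scalphfo.detect import design_bandpass
from scalphfo.io import EEGRecording
from scalphfo.simulate import (
    GroundTruthEvent,
    SimulationConfig,
    embed_artifacts,
    embed_events,
    generate_background,
    generate_task_triggers,
    make_burst_event,
    realized_snr,
    simulate_cohort_rates,
)


class TestBackground:
    def test_white_noise_identity_case(self):
        cfg = SimulationConfig(duration_s=10.0, channel_labels=["C3"],
                               background_exponent=0.0, slow_wave_amp_uv=0.0,
                               background_rms_uv=10.0, rng_seed=0)
        rec = generate_background(cfg)
        assert abs(rec.data.mean()) < 0.5  # zero-mean
        f, p = sig.welch(rec.data[0], fs=cfg.fs, nperseg=2048)
        sel = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert abs(slope) < 0.1  # flat spectrum

    def test_deterministic_under_fixed_seed(self, small_config):
        a = generate_background(small_config)
        b = generate_background(small_config)
        assert np.array_equal(a.data, b.data)

    def test_pink_spectrum_slope(self):
        # Welch-PSD fit oracle on the generated signal
        cfg = SimulationConfig(duration_s=60.0, channel_labels=["C3"],
                               background_exponent=1.0, slow_wave_amp_uv=0.0,
                               rng_seed=3)
        rec = generate_background(cfg)
        f, p = sig.welch(rec.data[0], fs=cfg.fs, nperseg=8192)
        sel = (f >= 1) & (f <= 100)
        slope = np.polyfit(np.log(f[sel]), np.log(p[sel]), 1)[0]
        assert slope == pytest.approx(-1.0, abs=0.1)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            SimulationConfig(duration_s=-1.0)
        with pytest.raises(ValueError):
            SimulationConfig(fs=0.0)


class TestGroundTruthEvent:
    def test_band_invariants(self):
        with pytest.raises(ValueError, match="ripple_like"):
            GroundTruthEvent("C3", 0, 100, 300.0, 10.0, 4, kind="ripple_like")
        with pytest.raises(ValueError, match="fast_ripple_like"):
            GroundTruthEvent("C3", 0, 100, 100.0, 10.0, 4,
                             kind="fast_ripple_like")

    def test_duration_matches_cycles_within_one_sample(self):
        fs = 1024.0
        ev = make_burst_event("C3", 0, 150.0, 10.0, 8, fs)
        assert abs(ev.n_samples - 8 * fs / 150.0) <= 1


class TestEmbedEvents:
    def test_zero_amplitude_identity(self, background, small_config):
        ev = make_burst_event("C3", 3000, 150.0, 0.0, 8, small_config.fs)
        rec, _ = embed_events(background, [ev])
        assert np.array_equal(rec.data, background.data)

    def test_channel_locality(self, background, small_config):
        ev = make_burst_event("C3", 3000, 150.0, 50.0, 8, small_config.fs)
        rec, _ = embed_events(background, [ev])
        assert np.array_equal(rec.channel("C4"), background.channel("C4"))
        assert not np.array_equal(rec.channel("C3"), background.channel("C3"))

    def test_additivity(self, background, small_config):
        fs = small_config.fs
        a = [make_burst_event("C3", 2000, 120.0, 30.0, 6, fs)]
        b = [make_burst_event("C4", 6000, 300.0, 30.0, 6, fs)]
        once, _ = embed_events(background, a + b)
        stepwise, _ = embed_events(embed_events(background, a)[0], b)
        np.testing.assert_array_equal(once.data, stepwise.data)

    def test_burst_rms_matches_taper_oracle(self):
        # closed-form RMS of a tapered sinusoid, computed numerically
        fs, amp = 1024.0, 40.0
        cfg = SimulationConfig(duration_s=4.0, channel_labels=["C3"],
                               background_rms_uv=0.0, slow_wave_amp_uv=0.0)
        zero = EEGRecording(np.zeros((1, cfg.n_samples)), fs, ["C3"])
        ev = make_burst_event("C3", 2048, 150.0, amp, 8, fs)
        rec, _ = embed_events(zero, [ev], taper="hann")
        taps = design_bandpass(fs, 80.0, 500.0)
        seg = sig.filtfilt(taps, [1.0], rec.data[0])[2048 : 2048 + ev.n_samples]
        w = sig.windows.hann(ev.n_samples, sym=True)
        expected = amp * np.sqrt(np.mean(w**2)) / np.sqrt(2)
        assert np.sqrt(np.mean(seg**2)) == pytest.approx(expected, rel=0.05)

    def test_realized_snr_agrees_with_independent_band_rms(
        self, background, small_config
    ):
        fs = small_config.fs
        ev = make_burst_event("C3", 5120, 150.0, 60.0, 8, fs)
        rec, out = embed_events(background, [ev])
        # independent recomputation with explicit slicing
        taps = design_bandpass(fs, 80.0, 500.0)
        x = sig.filtfilt(taps, [1.0], rec.channel("C3"))
        a, b = ev.onset_sample, ev.offset_sample
        half = int(fs // 2)
        ev_rms = np.sqrt(np.mean(x[a:b] ** 2))
        bg = np.concatenate([x[a - half : a], x[b : b + half]])
        expected = ev_rms / np.sqrt(np.mean(bg**2))
        assert out[0].snr == pytest.approx(expected, rel=0.01)

    def test_overlap_warns_but_embeds_both(self, background, small_config):
        fs = small_config.fs
        evs = [make_burst_event("C3", 3000, 150.0, 30.0, 8, fs),
               make_burst_event("C3", 3020, 150.0, 30.0, 8, fs)]
        with pytest.warns(UserWarning, match="overlap"):
            rec, _ = embed_events(background, evs)
        assert not np.array_equal(rec.channel("C3"),
                                  background.channel("C3"))

    def test_event_outside_recording_rejected(self, background, small_config):
        ev = make_burst_event("C3", small_config.n_samples - 10, 150.0, 30.0,
                              8, small_config.fs)
        with pytest.raises(ValueError, match="exceeds"):
            embed_events(background, [ev])


class TestArtifacts:
    def test_empty_list_is_identity(self, background):
        rec = embed_artifacts(background, [])
        assert np.array_equal(rec.data, background.data)

    def test_line_artifact_killed_by_bandpass(self):
        # filter attenuation oracle: 50 Hz residual < 1% after 80-500 Hz
        fs = 1024.0
        zero = EEGRecording(np.zeros((1, 4096)), fs, ["C3"])
        art = GroundTruthEvent("C3", 1024, 3072, 50.0, 100.0, 4,
                               kind="artifact_line")
        rec = embed_artifacts(zero, [art])
        in_rms = np.sqrt(np.mean(rec.data[0, 1024:3072] ** 2))
        taps = design_bandpass(fs, 80.0, 500.0)
        out = sig.filtfilt(taps, [1.0], rec.data[0])
        out_rms = np.sqrt(np.mean(out[1024:3072] ** 2))
        assert out_rms < 0.01 * in_rms

    def test_spike_rings_like_false_ripple(self):
        # filter-response oracle: a biphasic transient passed through the
        # band-pass shows >= 4 apparent oscillation cycles
        fs = 1024.0
        zero = EEGRecording(np.zeros((1, 4096)), fs, ["C3"])
        art = GroundTruthEvent("C3", 2000, 2061, 150.0, 120.0, 3,
                               kind="artifact_spike")
        rec = embed_artifacts(zero, [art])
        taps = design_bandpass(fs, 80.0, 500.0)
        out = sig.filtfilt(taps, [1.0], rec.data[0])
        seg = out[1980 : 2101]
        peaks = sig.argrelextrema(np.abs(seg), np.greater)[0]
        strong = peaks[np.abs(seg[peaks]) > 0.1 * np.abs(seg).max()]
        assert strong.size >= 8  # >= 4 cycles, two rectified peaks each

    def test_non_artifact_kind_rejected(self, background, small_config):
        ev = make_burst_event("C3", 3000, 150.0, 30.0, 8, small_config.fs)
        with pytest.raises(ValueError, match="artifact"):
            embed_artifacts(background, [ev])


class TestTaskTriggers:
    def test_counting_one_trial(self):
        cfg = SimulationConfig(duration_s=60.0, channel_labels=["C3"])
        trig = generate_task_triggers(cfg, 1, 30.0, 10)
        assert trig.count("typing") == 10
        assert trig.count("resting") == 15  # every 2 s in a 30 s block
        assert all(s < 60 * cfg.fs for s, _ in trig.entries)

    def test_sorted_ascending(self):
        cfg = SimulationConfig(duration_s=240.0, channel_labels=["C3"])
        trig = generate_task_triggers(cfg, 2, 30.0, 10)
        samples = [s for s, _ in trig.entries]
        assert samples == sorted(samples)
        assert len(set(samples)) == len(samples)

    def test_study_like_session_needs_17_minutes(self):
        # 17 trials of 30 s plus equal resting = 17 min of signal
        short = SimulationConfig(duration_s=16 * 60.0, channel_labels=["C3"])
        with pytest.raises(ValueError, match="exceeds"):
            generate_task_triggers(short, 17, 30.0, 10)
        ok = SimulationConfig(duration_s=17 * 60.0, channel_labels=["C3"])
        trig = generate_task_triggers(ok, 17, 30.0, 10)
        assert trig.count("typing") == 170

    def test_requires_at_least_one_trial(self):
        cfg = SimulationConfig(duration_s=60.0, channel_labels=["C3"])
        with pytest.raises(ValueError):
            generate_task_triggers(cfg, 0, 30.0, 10)


class TestCohortRates:
    def test_shape_and_groups(self):
        df = simulate_cohort_rates(18, 6, seed=0)
        assert len(df) == 24
        assert (df["group"] == "epilepsy").sum() == 18
        assert (df[["ripple", "fast_ripple"]] >= 0).all().all()

    def test_epilepsy_fast_ripple_excess_on_average(self):
        df = simulate_cohort_rates(200, 200, seed=1)
        diff_e = (df.query("group=='epilepsy'")["fast_ripple"]
                  - df.query("group=='epilepsy'")["ripple"]).mean()
        diff_c = (df.query("group=='control'")["fast_ripple"]
                  - df.query("group=='control'")["ripple"]).mean()
        assert diff_e - diff_c > 0.005
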