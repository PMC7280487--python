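import numpy as np
import pytest

from scalphfo.classify import (
    ClassifierParams,
    classify_events,
    count_regular_cycles,
    cwt_blob_isolation,
    emd_regularity,
    stockwell_transform,
    validate_events,
)
from scalphfo.detect import EventOfInterest, bandpass_fir, detect
from scalphfo.emd import emd, instantaneous_frequency
from scalphfo.io import EEGRecording
from scalphfo.simulate import (
    GroundTruthEvent,
    SimulationConfig,
    embed_artifacts,
    embed_events,
    generate_background,
    make_burst_event,
)

FS = 1024.0


def _burst_recording(freq, amplitude=40.0, n_cycles=10, noise_rms=1.0,
                     seed=0, n_s=8192):
    rng = np.random.default_rng(seed)
    data = rng.normal(0, noise_rms, (1, n_s)) if noise_rms else \
        np.zeros((1, n_s))
    rec = EEGRecording(data, FS, ["C3"])
    ev = make_burst_event("C3", n_s // 2, freq, amplitude, n_cycles, FS)
    rec, truths = embed_events(rec, [ev])
    return rec, truths[0]


class TestStockwell:
    def test_known_frequency_oracle(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 200.0 * t)
        mag, freqs = stockwell_transform(x, FS, 40.0, 500.0)
        peak = freqs[np.argmax(mag.mean(axis=1))]
        assert abs(peak - 200.0) <= 1.0

    def test_zero_segment(self):
        mag, _ = stockwell_transform(np.zeros(1024), FS, 40.0, 500.0)
        assert np.all(mag == 0)

    def test_linearity_in_amplitude(self):
        t = np.arange(1024) / FS
        x = np.sin(2 * np.pi * 150.0 * t)
        m1, _ = stockwell_transform(x, FS, 80.0, 300.0)
        m3, _ = stockwell_transform(3 * x, FS, 80.0, 300.0)
        np.testing.assert_allclose(m3, 3 * m1, rtol=1e-9, atol=1e-12)

    def test_fmax_above_nyquist_rejected(self):
        with pytest.raises(ValueError, match="Nyquist"):
            stockwell_transform(np.zeros(1024), FS, 80.0, 600.0)

    @pytest.mark.parametrize("freq", [90.0, 150.0, 250.0, 350.0, 450.0])
    def test_peak_frequency_across_band(self, freq):
        t = np.arange(2048) / FS
        x = np.sin(2 * np.pi * freq * t)
        mag, freqs = stockwell_transform(x, FS, 40.0, 500.0)
        peak = freqs[np.argmax(mag.mean(axis=1))]
        assert abs(peak - freq) <= 1.0

    def test_agrees_with_mne_stockwell_oracle(self):
        # independent implementation cross-check on a chirp-free burst
        mne_tf = pytest.importorskip("mne.time_frequency")
        rng = np.random.default_rng(5)
        t = np.arange(2048) / FS
        x = np.sin(2 * np.pi * 180.0 * t) * np.exp(
            -((t - 1.0) ** 2) / 0.01
        ) + 0.05 * rng.normal(size=t.size)
        power, _, freqs = mne_tf.tfr_array_stockwell(
            x[None, None, :], FS, fmin=80, fmax=400, width=1.0
        )
        mne_peak = freqs[np.argmax(power[0].mean(axis=1))]
        mag, our_freqs = stockwell_transform(x, FS, 80.0, 400.0)
        our_peak = our_freqs[np.argmax((mag**2).mean(axis=1))]
        assert abs(our_peak - mne_peak) <= 5.0


class TestClassification:
    @pytest.mark.parametrize("freq,expected", [
        (100.0, "ripple"), (150.0, "ripple"), (200.0, "ripple"),
        (300.0, "fast_ripple"), (350.0, "fast_ripple"),
        (400.0, "fast_ripple"),
    ])
    def test_pure_burst_labels(self, freq, expected):
        rec, truth = _burst_recording(freq)
        eois = detect(rec)
        hits = [e for e in eois if e.onset_sample < truth.offset_sample
                and truth.onset_sample < e.offset_sample]
        assert hits, "burst not detected"
        ces = classify_events(hits, rec)
        assert all(ce.label == expected for ce in ces)
        assert all(abs(ce.peak_frequency_hz - freq) <= 5 for ce in ces)

    def test_boundary_250_goes_to_fast_ripple(self):
        rec, truth = _burst_recording(250.0)
        eois = detect(rec)
        ces = classify_events(eois, rec)
        hit = [c for c in ces if c.eoi.onset_sample < truth.offset_sample
               and truth.onset_sample < c.eoi.offset_sample]
        assert hit[0].label == "fast_ripple"

    def test_emg_burst_flagged_as_artifact(self):
        cfg = SimulationConfig(duration_s=8.0, channel_labels=["C3"],
                               rng_seed=2)
        rec = generate_background(cfg)
        art = GroundTruthEvent("C3", 4000, 4205, 150.0, 150.0, 3,
                               kind="artifact_emg")
        rec = embed_artifacts(rec, [art], np.random.default_rng(2))
        eois = detect(rec)
        hits = [e for e in eois if e.onset_sample < 4205
                and 4000 < e.offset_sample]
        assert hits, "EMG burst not even detected"
        ces = classify_events(hits, rec)
        assert not validate_events(ces)


class TestCycleCounting:
    def test_six_cycle_constant_burst(self):
        t = np.arange(int(6 * FS / 150)) / FS
        x = np.sin(2 * np.pi * 150.0 * t)
        assert count_regular_cycles(x) == 6

    def test_three_cycle_burst_fails_review_bound(self):
        t = np.arange(int(3 * FS / 150)) / FS
        x = np.sin(2 * np.pi * 150.0 * t)
        assert count_regular_cycles(x) == 3
        assert count_regular_cycles(x) < 4

    def test_flat_zero_segment(self):
        assert count_regular_cycles(np.zeros(100)) == 0

    def test_irregular_spacing_breaks_run(self):
        t1 = np.arange(int(4 * FS / 150)) / FS
        t2 = np.arange(int(4 * FS / 400)) / FS
        x = np.concatenate([np.sin(2 * np.pi * 150 * t1),
                            np.zeros(40),
                            np.sin(2 * np.pi * 400 * t2)])
        assert count_regular_cycles(x) < 8


class TestBlobIsolation:
    def test_pure_burst_in_white_noise_isolated(self):
        rec, truth = _burst_recording(150.0, amplitude=40.0, noise_rms=1.0)
        eoi = EventOfInterest("C3", truth.onset_sample, truth.offset_sample,
                              (truth.onset_sample + truth.offset_sample) // 2,
                              5.0)
        assert cwt_blob_isolation(eoi, rec) > 0.8

    def test_filtered_spike_not_isolated(self):
        zero = EEGRecording(np.zeros((1, 8192)), FS, ["C3"])
        art = GroundTruthEvent("C3", 4000, 4061, 150.0, 100.0, 3,
                               kind="artifact_spike")
        rec = embed_artifacts(zero, [art])
        eoi = EventOfInterest("C3", 4010, 4050, 4030, 5.0)
        assert cwt_blob_isolation(eoi, rec) < 0.5

    def test_zero_event_scores_zero_with_warning(self):
        rec = EEGRecording(np.zeros((1, 4096)), FS, ["C3"])
        eoi = EventOfInterest("C3", 2000, 2050, 2020, 5.0)
        with pytest.warns(UserWarning, match="all-zero"):
            assert cwt_blob_isolation(eoi, rec) == 0.0


class TestEmd:
    def test_monocomponent_first_imf_is_input(self):
        t = np.arange(256) / FS
        x = np.sin(2 * np.pi * 150.0 * t)
        imfs, residue, converged = emd(x)
        assert converged
        # discrete extrema undershoot the true peaks at ~6.8 samples per
        # cycle, so the envelope wiggles a few percent
        np.testing.assert_allclose(imfs[0][20:-20], x[20:-20], atol=0.08)
        assert all(np.abs(im).max() < 0.1 for im in imfs[1:])

    def test_completeness(self, rng):
        x = rng.normal(size=300).cumsum()  # rough drifting signal
        imfs, residue, _ = emd(x)
        recon = np.sum(imfs, axis=0) + residue
        np.testing.assert_allclose(recon, x, rtol=1e-6, atol=1e-9)

    def test_instantaneous_frequency_of_sinusoid(self):
        t = np.arange(512) / FS
        x = np.sin(2 * np.pi * 200.0 * t)
        assert instantaneous_frequency(x, FS) == pytest.approx(200.0, rel=0.05)

    def test_drift_removed_by_mode_selection(self):
        # the count on the selected IMF matches the drift-free construction
        n = int(8 * FS / 150)
        t = np.arange(n) / FS
        clean = np.sin(2 * np.pi * 150.0 * t)
        drift = clean + 3.0 * np.sin(2 * np.pi * 8.0 * t)
        filt_clean = EEGRecording(clean[None, :], FS, ["C3"])
        filt_drift = EEGRecording(drift[None, :], FS, ["C3"])
        eoi = EventOfInterest("C3", 0, n, n // 2, 5.0)
        c_clean, _ = emd_regularity(eoi, filt_clean)
        c_drift, _ = emd_regularity(eoi, filt_drift)
        assert c_drift == pytest.approx(c_clean, abs=1)

    def test_too_short_segment(self):
        with pytest.raises(ValueError, match="short"):
            emd(np.zeros(3))


class TestValidation:
    def _ce(self, label="ripple", n_osc=5, blob=0.9):
        from scalphfo.classify import ClassifiedEvent

        eoi = EventOfInterest("C3", 100, 160, 120, 4.0)
        return ClassifiedEvent(eoi, 150.0, label, n_osc, blob, 0.1)

    def test_all_criteria_met_kept(self):
        assert validate_events([self._ce()]) != []

    def test_three_oscillations_discarded(self):
        assert validate_events([self._ce(n_osc=3)]) == []

    def test_artifact_discarded_regardless(self):
        assert validate_events([self._ce(label="artifact", n_osc=9,
                                         blob=1.0)]) == []

    def test_low_blob_discarded(self):
        assert validate_events([self._ce(blob=0.3)]) == []

    def test_output_subset_of_input(self):
        events = [self._ce(), self._ce(n_osc=2), self._ce(label="artifact")]
        out = validate_events(events)
        assert all(e in events for e in out)
        params = ClassifierParams()
        for e in out:
            assert e.label != "artifact"
            assert e.n_oscillations >= params.min_oscillations
            assert e.blob_isolation >= params.min_blob_isolation
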