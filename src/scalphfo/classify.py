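"""Stage-2 classification and validation of candidate events.

Stage 1 flags energy excursions; this stage decides what they are.  Three
independent looks at each event of interest (EoI) stand in for the visual
review criteria of semi-automated HFO workflows:

* an S-transform (Stockwell) power spectrum at the RMS peak, which must
  show an *isolated* high-frequency peak — a spectral trough between any
  low-frequency (< 80 Hz) content and the peak — to rule out broadband
  artifacts; surviving events are labeled ripple (peak < 250 Hz) or fast
  ripple (peak >= 250 Hz);
* a count of consecutive, regularly spaced oscillation cycles in the
  band-passed signal (a real HFO shows at least four);
* a continuous-wavelet "blob isolation" score that distinguishes a
  time-frequency island confined above 80 Hz from the vertical ridge a
  filtered spike produces (the classic "false ripple").

An optional EMD check repeats the cycle count on the intrinsic mode
function closest to the event's peak frequency.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy import ndimage as _ndi
from scipy.signal import argrelextrema

from .detect import DetectorParams, EventOfInterest, bandpass_fir
from .emd import emd as _emd_sift
from .emd import instantaneous_frequency
from .io import EEGRecording

__all__ = [
    "ClassifierParams",
    "ClassifiedEvent",
    "stockwell_transform",
    "classify_event",
    "classify_events",
    "count_oscillations",
    "count_regular_cycles",
    "cwt_blob_isolation",
    "emd_regularity",
    "validate_events",
    "classified_to_frame",
]

RIPPLE_FR_BOUNDARY_HZ = 250.0  # peak frequency >= boundary -> fast ripple
BAND_FLOOR_HZ = 80.0           # minimum HFO frequency


@dataclass
class ClassifierParams:
    """Stage-2 constants.

    ``trough_ratio_threshold`` is the maximum allowed ratio of the
    spectral trough (between low-frequency content and the HFO peak) to
    the peak power for an event to count as isolated.
    ``amplitude_fraction`` is the fraction of the event's maximum that a
    cycle peak must reach to be counted; with the default Hann-tapered
    events a half-maximum criterion would discount the outer cycles of a
    genuine burst, so the default is 0.25.
    """

    context_ms: float = 100.0
    spectrum_fmin_hz: float = 40.0
    spectrum_fmax_hz: float = 500.0
    trough_ratio_threshold: float = 0.5
    amplitude_fraction: float = 0.25
    regularity_tolerance: float = 0.5
    cwt_fmin_hz: float = 32.0
    cwt_fmax_hz: float = 512.0
    cwt_voices_per_octave: int = 12
    min_oscillations: int = 4
    min_blob_isolation: float = 0.5
    require_emd: bool = False


@dataclass
class ClassifiedEvent:
    """An EoI after spectral classification and validation scoring."""

    eoi: EventOfInterest
    peak_frequency_hz: float
    label: str  # ripple | fast_ripple | artifact
    n_oscillations: int
    blob_isolation: float
    trough_ratio: float
    emd_passed: bool | None = None

    def __post_init__(self) -> None:
        if self.label not in ("ripple", "fast_ripple", "artifact"):
            raise ValueError(f"unknown label {self.label!r}")


# ---------------------------------------------------------------------------
# Stockwell transform
# ---------------------------------------------------------------------------

def stockwell_transform(
    segment: np.ndarray,
    fs: float,
    fmin_hz: float,
    fmax_hz: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Discrete S-transform magnitude of a single-channel segment.

    The segment is zero-padded to a whole number of seconds so the
    frequency grid lands on integer Hertz; rows are frequencies
    ``fmin..fmax`` (1 Hz steps), columns the original samples.  Returns
    ``(magnitude, freqs)``.
    """
    x = np.asarray(segment, dtype=float)
    if x.ndim != 1:
        raise ValueError("expected a single-channel segment")
    if fmax_hz > fs / 2:
        raise ValueError(f"fmax {fmax_hz} Hz exceeds Nyquist {fs / 2} Hz")
    if x.size < 2 * fs / max(fmin_hz, 1e-9):
        # fewer than two cycles of fmin: spectrum below is meaningless
        warnings.warn("segment shorter than two cycles of fmin", stacklevel=2)
    fs_i = int(round(fs))
    if abs(fs - fs_i) > 1e-9:
        raise ValueError("integer sampling rate required for the 1-Hz grid")
    n_sec = max(int(np.ceil(x.size / fs_i)), 1)
    N = n_sec * fs_i
    pad_left = (N - x.size) // 2
    xp = np.zeros(N)
    xp[pad_left : pad_left + x.size] = x

    X = np.fft.fft(xp)
    # analytic-signal spectrum: without this the negative-frequency
    # mirror leaks into voices near Nyquist and biases their peaks
    X[N // 2 + 1 :] = 0.0
    X[1 : (N + 1) // 2] *= 2.0
    freqs = np.arange(int(np.ceil(fmin_hz)), int(np.floor(fmax_hz)) + 1)
    bins = freqs * n_sec  # integer FFT bin of each voice frequency
    m = np.arange(N)
    m_signed = ((m + N // 2) % N) - N // 2
    # rows: localized Gaussian windows in the frequency domain
    G = np.exp(
        -2.0 * np.pi**2 * m_signed[None, :] ** 2 / bins[:, None].astype(float) ** 2
    )
    shifted = X[(m[None, :] + bins[:, None]) % N]
    S = np.fft.ifft(shifted * G, axis=1)
    mag = np.abs(S)[:, pad_left : pad_left + x.size]
    if not np.any(x):
        mag = np.zeros_like(mag)
    return mag, freqs.astype(float)


# ---------------------------------------------------------------------------
# Spectral classification
# ---------------------------------------------------------------------------

def _event_context(
    eoi: EventOfInterest, recording: EEGRecording, context_ms: float
) -> tuple[np.ndarray, int]:
    ctx = int(round(context_ms * recording.fs / 1000.0))
    lo = eoi.onset_sample - ctx
    hi = eoi.offset_sample + ctx
    if lo < 0 or hi > recording.n_samples:
        warnings.warn("event context truncated at recording bounds",
                      stacklevel=3)
        lo = max(lo, 0)
        hi = min(hi, recording.n_samples)
    return recording.channel(eoi.channel)[lo:hi], lo


def classify_event(
    eoi: EventOfInterest,
    recording: EEGRecording,
    params: ClassifierParams | None = None,
    filtered: EEGRecording | None = None,
) -> ClassifiedEvent:
    """Classify one EoI from the raw recording.

    The instantaneous S-transform power spectrum at the RMS peak supplies
    the peak frequency (argmax at or above 80 Hz) and the trough-isolation
    artifact test; cycle counting and the wavelet blob score fill in the
    validation fields.  ``filtered`` may carry the pre-computed band-passed
    recording to avoid re-filtering per event.
    """
    params = params or ClassifierParams()
    if filtered is None:
        filtered = bandpass_fir(recording)
    seg, lo = _event_context(eoi, recording, params.context_ms)
    fmax = min(params.spectrum_fmax_hz, recording.fs / 2)
    mag, freqs = stockwell_transform(seg, recording.fs,
                                     params.spectrum_fmin_hz, fmax)
    # Time-averaged event power spectrum (a single column at the RMS peak
    # is too erratic to expose the broadband signature of muscle
    # artifacts); the peak frequency is its in-band argmax.
    power = (mag[:, eoi.onset_sample - lo : eoi.offset_sample - lo] ** 2
             ).mean(axis=1)
    in_band = freqs >= BAND_FLOOR_HZ
    band_power = power[in_band]
    band_freqs = freqs[in_band]
    i_peak = int(np.argmax(band_power))
    peak_f = float(band_freqs[i_peak])

    # Isolation test on the amplitude spectral density: dividing power by
    # f undoes the f-proportional bandwidth of the S-transform voices
    # (broadband noise would otherwise masquerade as high-frequency
    # peaked); the square root compares amplitudes, which separates a
    # broadband plateau from a true peak far more sharply than power.
    dens = np.sqrt(power / freqs)
    peak_p = float(dens[in_band].max())

    # Low-frequency content only counts when it is spectrally separated
    # from the peak: the S-transform's Gaussian voice at f has frequency
    # resolution sigma_f = f / (2*pi), so the peak's own skirt reaches
    # ~2*sigma_f below it and must not be mistaken for artifact content.
    sigma_f = peak_f / (2 * np.pi)
    low = freqs < min(BAND_FLOOR_HZ, peak_f - 2 * sigma_f)
    if peak_p <= 0:
        trough_ratio = 1.0
        isolated = False
    elif not low.any() or dens[low].max() <= params.trough_ratio_threshold * peak_p:
        # no appreciable low-frequency content: trivially isolated
        trough_ratio = float(dens[low].max() / peak_p) if low.any() else 0.0
        isolated = True
    else:
        i_low = int(np.argmax(dens[low]))
        f_low = freqs[low][i_low]
        between = (freqs > f_low) & (freqs <= peak_f)
        trough = float(dens[between].min()) if between.any() else peak_p
        trough_ratio = trough / peak_p
        isolated = trough_ratio <= params.trough_ratio_threshold

    if not isolated:
        label = "artifact"
    elif peak_f >= RIPPLE_FR_BOUNDARY_HZ:
        label = "fast_ripple"
    else:
        label = "ripple"

    n_osc = count_oscillations(eoi, filtered, params.amplitude_fraction,
                               params.regularity_tolerance)
    blob = cwt_blob_isolation(eoi, recording, params)
    return ClassifiedEvent(
        eoi=eoi,
        peak_frequency_hz=peak_f,
        label=label,
        n_oscillations=n_osc,
        blob_isolation=blob,
        trough_ratio=float(trough_ratio),
    )


def classify_events(
    eois: list[EventOfInterest],
    recording: EEGRecording,
    params: ClassifierParams | None = None,
    detector_params: DetectorParams | None = None,
) -> list[ClassifiedEvent]:
    """Classify a batch of EoIs, filtering the recording once."""
    params = params or ClassifierParams()
    dp = detector_params or DetectorParams()
    filtered = bandpass_fir(recording, dp.band_low_hz, dp.band_high_hz,
                            dp.n_taps, dp.corner_offset_hz)
    out = [classify_event(e, recording, params, filtered) for e in eois]
    if params.require_emd:
        for ce in out:
            _, ce.emd_passed = emd_regularity(ce.eoi, filtered, ce, params)
    return out


# ---------------------------------------------------------------------------
# Oscillation counting
# ---------------------------------------------------------------------------

def count_regular_cycles(
    x: np.ndarray,
    amplitude_fraction: float = 0.25,
    regularity_tolerance: float = 0.5,
) -> int:
    """Longest run of consecutive, regularly spaced cycle peaks in ``x``.

    Cycle peaks are local maxima of the signal reaching
    ``amplitude_fraction`` of the segment maximum; successive peaks count
    as consecutive when their spacing is within ``regularity_tolerance``
    (fractional) of the median spacing.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 3 or not np.any(x):
        return 0
    peaks = argrelextrema(x, np.greater)[0]
    top = x.max()
    if top <= 0:
        return 0
    peaks = peaks[x[peaks] >= amplitude_fraction * top]
    if peaks.size == 0:
        return 0
    if peaks.size == 1:
        return 1
    intervals = np.diff(peaks)
    med = np.median(intervals)
    ok = np.abs(intervals - med) <= regularity_tolerance * med
    best = run = 1
    for good in ok:
        run = run + 1 if good else 1
        best = max(best, run)
    return int(best)


def count_oscillations(
    eoi: EventOfInterest,
    filtered_recording: EEGRecording,
    amplitude_fraction: float = 0.25,
    regularity_tolerance: float = 0.5,
) -> int:
    """Count regular oscillation cycles of an EoI in the band-passed EEG."""
    seg = filtered_recording.channel(eoi.channel)[
        eoi.onset_sample : eoi.offset_sample
    ]
    return count_regular_cycles(seg, amplitude_fraction, regularity_tolerance)


# ---------------------------------------------------------------------------
# Wavelet blob isolation
# ---------------------------------------------------------------------------

def cwt_blob_isolation(
    eoi: EventOfInterest,
    recording: EEGRecording,
    params: ClassifierParams | None = None,
) -> float:
    """Score in [0, 1]: is the event a time-frequency island above 80 Hz?

    An analytic-Morlet scalogram is computed over 32–512 Hz around the
    event.  The connected supra-half-maximum region containing the event's
    peak (above 80 Hz) is found; the score is the region's above-80-Hz
    energy divided by the region's total energy, i.e. it measures how far
    the region extends vertically below 80 Hz.  A genuine oscillation is
    confined in frequency (score near 1); a spike rides a vertical
    broadband ridge whose supra-half-maximum power continues below 80 Hz
    (score toward 0).
    """
    params = params or ClassifierParams()
    seg, lo = _event_context(eoi, recording, params.context_ms)
    if not np.any(seg):
        warnings.warn("all-zero event segment: blob isolation undefined (0)",
                      stacklevel=2)
        return 0.0
    fmax = min(params.cwt_fmax_hz, 0.98 * recording.fs / 2)
    n_oct = np.log2(fmax / params.cwt_fmin_hz)
    n_f = int(np.ceil(n_oct * params.cwt_voices_per_octave)) + 1
    freqs = params.cwt_fmin_hz * 2 ** np.linspace(0, n_oct, n_f)
    wavelet = "cmor1.5-1.0"
    fc = pywt.central_frequency(wavelet)
    scales = fc * recording.fs / freqs
    coef, _ = pywt.cwt(seg, scales, wavelet, sampling_period=1.0 / recording.fs)
    power = np.abs(coef) ** 2  # rows follow `freqs` order

    cols_event = slice(eoi.onset_sample - lo, eoi.offset_sample - lo)
    rows_high = freqs >= BAND_FLOOR_HZ
    sub = power[np.ix_(rows_high, range(*cols_event.indices(power.shape[1])))]
    if sub.size == 0 or sub.max() <= 0:
        return 0.0
    r_rel, c_rel = np.unravel_index(np.argmax(sub), sub.shape)
    r_peak = np.flatnonzero(rows_high)[r_rel]
    c_peak = cols_event.start + c_rel
    peak_power = power[r_peak, c_peak]

    mask = power >= 0.5 * peak_power
    labels, _ = _ndi.label(mask)
    region = labels == labels[r_peak, c_peak]
    e_high = float(power[region & rows_high[:, None]].sum())
    e_low = float(power[region & ~rows_high[:, None]].sum())
    if e_high + e_low <= 0:
        return 0.0
    return e_high / (e_high + e_low)


# ---------------------------------------------------------------------------
# EMD regularity
# ---------------------------------------------------------------------------

def emd_regularity(
    eoi: EventOfInterest,
    filtered_recording: EEGRecording,
    classified: ClassifiedEvent | None = None,
    params: ClassifierParams | None = None,
) -> tuple[int, bool]:
    """Cycle count on the intrinsic mode function nearest the peak frequency.

    Returns ``(count, passed)`` with ``passed = count >= 4``; a
    non-convergent sifting fails conservatively.
    """
    params = params or ClassifierParams()
    seg = filtered_recording.channel(eoi.channel)[
        eoi.onset_sample : eoi.offset_sample
    ]
    if seg.size < 4:
        return 0, False
    try:
        imfs, _, converged = _emd_sift(seg)
    except Exception:
        return 0, False
    if not imfs:
        return 0, False
    target = classified.peak_frequency_hz if classified is not None else None
    if target is None:
        target = BAND_FLOOR_HZ
    fs = filtered_recording.fs
    best = min(imfs,
               key=lambda im: abs(instantaneous_frequency(im, fs) - target))
    count = count_regular_cycles(best, params.amplitude_fraction,
                                 params.regularity_tolerance)
    return count, bool(converged and count >= params.min_oscillations)


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_events(
    classified: list[ClassifiedEvent],
    params: ClassifierParams | None = None,
) -> list[ClassifiedEvent]:
    """Keep events satisfying every enabled review criterion.

    A kept event has a non-artifact label, at least
    ``params.min_oscillations`` regular cycles, blob isolation at or above
    ``params.min_blob_isolation``, and — when ``require_emd`` is set — a
    passing EMD cycle count.
    """
    params = params or ClassifierParams()
    out = []
    for ce in classified:
        if ce.label == "artifact":
            continue
        if ce.n_oscillations < params.min_oscillations:
            continue
        if ce.blob_isolation < params.min_blob_isolation:
            continue
        if params.require_emd and not ce.emd_passed:
            continue
        out.append(ce)
    return out


def classified_to_frame(events: list[ClassifiedEvent]):
    """Classified events as a pandas DataFrame (TSV-ready)."""
    import pandas as pd

    return pd.DataFrame(
        [
            {
                "channel": ce.eoi.channel,
                "onset_sample": ce.eoi.onset_sample,
                "offset_sample": ce.eoi.offset_sample,
                "peak_sample": ce.eoi.peak_sample,
                "peak_rms_sd": ce.eoi.peak_rms_sd,
                "peak_frequency_hz": ce.peak_frequency_hz,
                "label": ce.label,
                "n_oscillations": ce.n_oscillations,
                "blob_isolation": ce.blob_isolation,
                "trough_ratio": ce.trough_ratio,
            }
            for ce in events
        ],
        columns=[
            "channel", "onset_sample", "offset_sample", "peak_sample",
            "peak_rms_sd", "peak_frequency_hz", "label", "n_oscillations",
            "blob_isolation", "trough_ratio",
        ],
    )
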