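"""Synthetic scalp-EEG generation with ground truth.

Every downstream stage of the pipeline is validated against signals built
here: a 1/f^beta background with slow-wave activity, tapered oscillatory
bursts in the 80–500 Hz band (ripple-like below 250 Hz, fast-ripple-like
above), the classic artifact families that masquerade as HFOs on the scalp
(muscle bursts, filtered spikes, line harmonics), and task trigger trains
alternating typing and resting blocks.

Channels are statistically independent background processes plus locally
embedded events — no volume conduction; that is deliberate, since the
pipeline treats channels independently.

The signal-to-noise ratio of an embedded burst is defined operationally as
the ratio of its RMS to the background RMS, both measured in the 80–500 Hz
band, with the background taken from the surrounding second of signal
(event excluded).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import signal as _sig

from .detect import design_bandpass
from .io import EEGRecording, TriggerRecord
from .montage import STUDY_CHANNELS_29

__all__ = [
    "SimulationConfig",
    "GroundTruthEvent",
    "make_burst_event",
    "generate_background",
    "embed_events",
    "embed_artifacts",
    "generate_task_triggers",
    "realized_snr",
    "place_random_events",
    "simulate_cohort_rates",
    "EVENT_KINDS",
    "ARTIFACT_KINDS",
]

ARTIFACT_KINDS = ("artifact_emg", "artifact_spike", "artifact_line")
EVENT_KINDS = ("ripple_like", "fast_ripple_like") + ARTIFACT_KINDS

#: margin kept between any embedded event and the recording edges, seconds
EDGE_MARGIN_S = 0.5


@dataclass
class SimulationConfig:
    """Parameters of the synthetic scalp-EEG background.

    ``fs`` and the channel layout default to an epilepsy-monitoring-unit
    setting (1024 Hz, 29 extended 10–20 electrodes).  ``background_rms_uv``
    sets the broadband background scale; ``slow_wave_amp_uv`` the RMS of an
    additional 0.5–2 Hz slow-wave component.
    """

    fs: float = 1024.0
    duration_s: float = 60.0
    channel_labels: list[str] = field(
        default_factory=lambda: list(STUDY_CHANNELS_29)
    )
    background_exponent: float = 1.0
    background_rms_uv: float = 15.0
    slow_wave_amp_uv: float = 20.0
    line_freq_hz: float = 50.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if not self.fs > 0 or not self.duration_s > 0:
            raise ValueError("fs and duration_s must be positive")

    @property
    def n_samples(self) -> int:
        return int(round(self.fs * self.duration_s))

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.rng_seed)


@dataclass
class GroundTruthEvent:
    """A synthetically embedded event with its true parameters.

    ``snr`` is filled in by :func:`embed_events` with the realized
    band-limited RMS ratio (see module docstring); it is NaN until then.
    Intervals are half-open ``[onset_sample, offset_sample)``.
    """

    channel: str
    onset_sample: int
    offset_sample: int
    frequency_hz: float
    amplitude_uv: float
    n_cycles: int
    kind: str = "ripple_like"
    snr: float = float("nan")

    def __post_init__(self) -> None:
        if self.onset_sample >= self.offset_sample:
            raise ValueError("onset must precede offset")
        if self.kind not in EVENT_KINDS:
            raise ValueError(f"unknown event kind {self.kind!r}")
        if self.kind == "ripple_like" and not 80 <= self.frequency_hz < 250:
            raise ValueError("ripple_like events must lie in [80, 250) Hz")
        # 250 Hz itself belongs to the upper class, mirroring the label
        # boundary decision (peak frequency >= 250 -> fast ripple)
        if self.kind == "fast_ripple_like" and not 250 <= self.frequency_hz <= 500:
            raise ValueError("fast_ripple_like events must lie in [250, 500] Hz")

    @property
    def n_samples(self) -> int:
        return self.offset_sample - self.onset_sample


def make_burst_event(
    channel: str,
    onset_sample: int,
    frequency_hz: float,
    amplitude_uv: float,
    n_cycles: int,
    fs: float,
    kind: str | None = None,
) -> GroundTruthEvent:
    """Build a burst whose duration is ``n_cycles`` periods (half-up rounded)."""
    n = int(np.floor(n_cycles * fs / frequency_hz + 0.5))
    if kind is None:
        kind = "ripple_like" if frequency_hz < 250 else "fast_ripple_like"
    return GroundTruthEvent(
        channel=channel,
        onset_sample=onset_sample,
        offset_sample=onset_sample + n,
        frequency_hz=frequency_hz,
        amplitude_uv=amplitude_uv,
        n_cycles=n_cycles,
        kind=kind,
    )


# ---------------------------------------------------------------------------
# Background
# ---------------------------------------------------------------------------

def _powerlaw_noise(rng: np.random.Generator, n: int, fs: float,
                    beta: float) -> np.ndarray:
    """Unit-RMS Gaussian noise with power spectrum proportional to 1/f^beta."""
    white = rng.standard_normal(n)
    if beta == 0:
        out = white
    else:
        spec = np.fft.rfft(white)
        f = np.fft.rfftfreq(n, d=1.0 / fs)
        shaping = np.ones_like(f)
        nz = f > 0
        shaping[nz] = f[nz] ** (-beta / 2.0)
        shaping[0] = 0.0  # no DC
        out = np.fft.irfft(spec * shaping, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def _bandlimited_noise(rng: np.random.Generator, n: int, fs: float,
                       lo: float, hi: float) -> np.ndarray:
    """Unit-RMS Gaussian noise confined to [lo, hi] Hz (FFT brick-wall)."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n, d=1.0 / fs)
    spec[(f < lo) | (f > hi)] = 0.0
    out = np.fft.irfft(spec, n)
    rms = np.sqrt(np.mean(out**2))
    return out / rms if rms > 0 else out


def generate_background(config: SimulationConfig) -> EEGRecording:
    """Generate the multichannel background process.

    Each channel is an independent draw of 1/f^beta noise at
    ``background_rms_uv`` RMS plus a 0.5–2 Hz slow-wave component at
    ``slow_wave_amp_uv`` RMS.  Bit-identical for a fixed ``rng_seed``.
    """
    rng = config.rng()
    n = config.n_samples
    data = np.empty((len(config.channel_labels), n))
    for i in range(len(config.channel_labels)):
        bg = config.background_rms_uv * _powerlaw_noise(
            rng, n, config.fs, config.background_exponent
        )
        if config.slow_wave_amp_uv > 0:
            bg = bg + config.slow_wave_amp_uv * _bandlimited_noise(
                rng, n, config.fs, 0.5, 2.0
            )
        data[i] = bg
    return EEGRecording(
        data=data, fs=config.fs, channel_labels=list(config.channel_labels)
    )


# ---------------------------------------------------------------------------
# Event and artifact embedding
# ---------------------------------------------------------------------------

def _taper_window(n: int, taper: str) -> np.ndarray:
    if taper == "hann":
        return _sig.windows.hann(n, sym=True)
    if taper == "tukey":
        return _sig.windows.tukey(n, alpha=0.5, sym=True)
    if taper in ("rect", "boxcar"):
        return np.ones(n)
    raise ValueError(f"unknown taper {taper!r}")


def _check_fits(recording: EEGRecording, ev: GroundTruthEvent) -> None:
    if ev.channel not in recording.channel_labels:
        raise ValueError(f"event channel {ev.channel!r} not in recording")
    if ev.onset_sample < 0 or ev.offset_sample > recording.n_samples:
        raise ValueError(
            f"event [{ev.onset_sample}, {ev.offset_sample}) exceeds recording"
        )


def _warn_overlaps(events: list[GroundTruthEvent]) -> None:
    by_ch: dict[str, list[GroundTruthEvent]] = {}
    for ev in events:
        by_ch.setdefault(ev.channel, []).append(ev)
    for chan, evs in by_ch.items():
        evs = sorted(evs, key=lambda e: e.onset_sample)
        for a, b in zip(evs, evs[1:]):
            if b.onset_sample < a.offset_sample:
                warnings.warn(
                    f"overlapping events on {chan}: both embedded additively",
                    stacklevel=3,
                )


def realized_snr(
    recording: EEGRecording,
    event: GroundTruthEvent,
    band: tuple[float, float] = (80.0, 500.0),
    context_s: float = 1.0,
) -> float:
    """Band-limited RMS of the event over band-limited RMS of its surround.

    The surround is ``context_s`` seconds centred on the event with the
    event interval itself excluded.
    """
    x = recording.channel(event.channel)
    taps = design_bandpass(recording.fs, band[0], band[1])
    a, b = event.onset_sample, event.offset_sample
    half = int(round(context_s * recording.fs / 2))
    lo = max(a - half, 0)
    hi = min(b + half, x.size)
    seg = _sig.filtfilt(taps, [1.0], x[lo:hi])
    ev = seg[a - lo : b - lo]
    bg = np.concatenate([seg[: a - lo], seg[b - lo :]])
    bg_rms = np.sqrt(np.mean(bg**2)) if bg.size else 0.0
    ev_rms = np.sqrt(np.mean(ev**2))
    return float(ev_rms / bg_rms) if bg_rms > 0 else float("inf")


def embed_events(
    recording: EEGRecording,
    events: list[GroundTruthEvent],
    taper: str = "hann",
) -> tuple[EEGRecording, list[GroundTruthEvent]]:
    """Add tapered sinusoidal bursts to their channels.

    Each event contributes ``amplitude_uv * taper(t) * sin(2*pi*f*t)`` over
    ``[onset, offset)``.  Purely additive: overlapping events raise a
    warning but are both embedded, and untouched channels are bit-identical
    to the input.  Returns the new recording and a ground-truth list with
    the realized SNR filled in.
    """
    for ev in events:
        _check_fits(recording, ev)
    _warn_overlaps(events)
    out = recording.copy()
    for ev in events:
        n = ev.n_samples
        t = np.arange(n) / recording.fs
        burst = ev.amplitude_uv * _taper_window(n, taper) * np.sin(
            2 * np.pi * ev.frequency_hz * t
        )
        out.channel(ev.channel)[ev.onset_sample : ev.offset_sample] += burst
    realized = [
        replace(ev, snr=realized_snr(out, ev)) for ev in events
    ]
    return out, realized


def _emg_burst(rng: np.random.Generator, n: int, fs: float,
               amplitude: float) -> np.ndarray:
    """Broadband 60–300 Hz muscle-like burst, Hann enveloped."""
    noise = _bandlimited_noise(rng, max(n, 64), fs, 60.0, 300.0)[:n]
    w = _sig.windows.hann(n, sym=True)
    out = noise * w
    rms = np.sqrt(np.mean(out**2))
    return amplitude / np.sqrt(2) * out / rms if rms > 0 else out


def _spike_transient(n: int, fs: float, amplitude: float) -> np.ndarray:
    """Biphasic sharp transient (derivative-of-Gaussian) of peak ``amplitude``.

    After the 80–500 Hz band-pass this produces the oscillatory ringing
    known as a "false ripple".
    """
    t = (np.arange(n) - n / 2) / fs
    sigma = max(n / 8, 2) / fs
    wave = -t * np.exp(-(t**2) / (2 * sigma**2))
    peak = np.max(np.abs(wave))
    return amplitude * wave / peak if peak > 0 else wave


def embed_artifacts(
    recording: EEGRecording,
    events: list[GroundTruthEvent],
    rng: np.random.Generator | None = None,
) -> EEGRecording:
    """Add artifact waveforms (EMG burst, spike transient, line sinusoid).

    Ground-truth ``kind`` must be one of the ``artifact_*`` kinds; the
    events mark intervals that a correct classifier should *not* validate
    as HFOs.  An empty list is the identity.
    """
    rng = rng or np.random.default_rng(0)
    for ev in events:
        _check_fits(recording, ev)
        if ev.kind not in ARTIFACT_KINDS:
            raise ValueError(f"{ev.kind!r} is not an artifact kind")
    _warn_overlaps(events)
    out = recording.copy()
    for ev in events:
        n = ev.n_samples
        if ev.kind == "artifact_emg":
            wave = _emg_burst(rng, n, recording.fs, ev.amplitude_uv)
        elif ev.kind == "artifact_spike":
            wave = _spike_transient(n, recording.fs, ev.amplitude_uv)
        else:  # artifact_line
            t = np.arange(n) / recording.fs
            # mild Tukey envelope: an abrupt start/stop would itself be a
            # broadband click leaking through any band-pass
            env = _sig.windows.tukey(n, alpha=0.2, sym=True)
            wave = ev.amplitude_uv * env * np.sin(
                2 * np.pi * ev.frequency_hz * t
            )
        out.channel(ev.channel)[ev.onset_sample : ev.offset_sample] += wave
    return out


# ---------------------------------------------------------------------------
# Task triggers
# ---------------------------------------------------------------------------

def generate_task_triggers(
    config: SimulationConfig,
    n_trials: int,
    trial_s: float,
    keys_per_trial: int,
    resting_interval_s: float = 2.0,
) -> TriggerRecord:
    """Alternating typing/resting blocks with trigger marks.

    Blocks of ``trial_s`` seconds alternate typing-first.  Typing blocks
    carry ``keys_per_trial`` evenly spaced keypress triggers; resting
    blocks carry triggers every ``resting_interval_s`` seconds.  The
    default study-like session is 17 trials of 30 s plus equal resting.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    total_s = 2 * n_trials * trial_s
    if total_s > config.duration_s + 1e-9:
        raise ValueError(
            f"session of {total_s} s exceeds recording of {config.duration_s} s"
        )
    fs = config.fs
    entries: list[tuple[int, str]] = []
    for trial in range(n_trials):
        t0 = 2 * trial * trial_s
        for j in range(keys_per_trial):
            t = t0 + (j + 0.5) / keys_per_trial * trial_s
            entries.append((int(round(t * fs)), "typing"))
        r0 = t0 + trial_s
        n_rest = int(np.floor(trial_s / resting_interval_s))
        for j in range(n_rest):
            t = r0 + (j + 0.5) * resting_interval_s
            entries.append((int(round(t * fs)), "resting"))
    entries.sort(key=lambda e: e[0])
    return TriggerRecord(entries=entries)


# ---------------------------------------------------------------------------
# Random placement and cohort-level rate simulation
# ---------------------------------------------------------------------------

def place_random_events(
    config: SimulationConfig,
    rng: np.random.Generator,
    n_events: int,
    frequencies_hz: list[float],
    amplitude_uv: float,
    n_cycles: int = 8,
    channels: list[str] | None = None,
    min_separation_s: float = 0.5,
) -> list[GroundTruthEvent]:
    """Draw non-overlapping burst events at random positions.

    Positions keep ``EDGE_MARGIN_S`` clear of the recording edges (filter
    transients) and ``min_separation_s`` between events on one channel.
    """
    channels = channels or config.channel_labels
    n_total = config.n_samples
    margin = int(EDGE_MARGIN_S * config.fs)
    sep = int(min_separation_s * config.fs)
    placed: dict[str, list[tuple[int, int]]] = {c: [] for c in channels}
    events: list[GroundTruthEvent] = []
    attempts = 0
    while len(events) < n_events:
        attempts += 1
        if attempts > 200 * n_events:
            raise RuntimeError("could not place events without overlap")
        chan = channels[rng.integers(len(channels))]
        f = float(frequencies_hz[rng.integers(len(frequencies_hz))])
        dur = int(np.floor(n_cycles * config.fs / f + 0.5))
        lo, hi = margin, n_total - margin - dur
        if hi <= lo:
            raise ValueError("recording too short for event placement")
        onset = int(rng.integers(lo, hi))
        if any(onset < b + sep and a - sep < onset + dur
               for a, b in placed[chan]):
            continue
        placed[chan].append((onset, onset + dur))
        events.append(
            make_burst_event(chan, onset, f, amplitude_uv, n_cycles, config.fs)
        )
    events.sort(key=lambda e: (e.channel, e.onset_sample))
    return events


def simulate_cohort_rates(
    n_epilepsy: int = 18,
    n_control: int = 6,
    seed: int = 0,
    interaction: float = 0.010,
    ripple_mean: tuple[float, float] = (0.007, 0.005),
    subject_sd: tuple[float, float] = (0.008, 0.004),
    noise_sd: tuple[float, float] = (0.005, 0.003),
):
    """Per-subject ripple/fast-ripple rates for a study-like cohort.

    Emulates the factorial structure of the sleep analysis: a between
    factor (epilepsy vs control) crossed with a within factor (ripple vs
    fast ripple).  Each subject has a shared quality offset (``subject_sd``)
    plus cell noise (``noise_sd``); the epilepsy group carries a
    fast-ripple excess of ``interaction`` events/min relative to control.
    Rates are clipped at zero.  Returns a tidy DataFrame with columns
    subject_id, group, ripple, fast_ripple.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    rows = []
    # group cell means: control fast ripple sits below its ripple mean;
    # the epilepsy fast-ripple excess carries the interaction
    cell_means = {
        "epilepsy": (ripple_mean[0], ripple_mean[0] + interaction - 0.003),
        "control": (ripple_mean[1], ripple_mean[1] - 0.003),
    }
    sizes = {"epilepsy": n_epilepsy, "control": n_control}
    sds = {"epilepsy": (subject_sd[0], noise_sd[0]),
           "control": (subject_sd[1], noise_sd[1])}
    for group in ("epilepsy", "control"):
        mu_r, mu_f = cell_means[group]
        s_sub, s_eps = sds[group]
        for i in range(sizes[group]):
            b = rng.normal(0, s_sub)
            r = max(0.0, mu_r + b + rng.normal(0, s_eps))
            f = max(0.0, mu_f + b + rng.normal(0, s_eps))
            rows.append(
                {"subject_id": f"{group[:1].upper()}{i:02d}", "group": group,
                 "ripple": r, "fast_ripple": f}
            )
    return pd.DataFrame(rows)
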