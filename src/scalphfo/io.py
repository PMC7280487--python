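"""Reading and writing EEG recordings and trigger records.

Recordings are plain in-memory containers (channels x samples, microvolts).
Two on-disk formats are supported: EDF (16-bit, the clinical interchange
format) and a simple tab-separated matrix dialect with a header carrying the
sampling rate and channel labels.  Sample indexing is 0-based everywhere and
intervals are half-open ``[onset, offset)``.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

__all__ = [
    "EEGRecording",
    "TriggerRecord",
    "read_recording",
    "write_tsv_matrix",
    "write_edf",
    "read_triggers",
    "write_triggers",
]


@dataclass
class EEGRecording:
    """Multichannel EEG signal in microvolts.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
        One 10–20 style label per row of ``data``.
    t0_sample : int
        Sample index of the first column (0-based), for excerpts.
    """

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    t0_sample: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (n_channels, n_samples)")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} channels"
            )
        if not self.fs > 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        if np.isnan(self.data).any():
            raise ValueError("recording contains NaNs")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return the 1-D signal of one channel (view, not a copy)."""
        try:
            idx = self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.data[idx]

    def copy(self) -> "EEGRecording":
        return replace(self, data=self.data.copy(),
                       channel_labels=list(self.channel_labels))


@dataclass
class TriggerRecord:
    """Task trigger train: (sample index, kind) with kind in {typing, resting}."""

    entries: list[tuple[int, str]] = field(default_factory=list)

    KINDS = ("typing", "resting")

    def __post_init__(self) -> None:
        samples = [s for s, _ in self.entries]
        if any(b <= a for a, b in zip(samples, samples[1:])):
            raise ValueError("trigger samples must be strictly increasing")
        bad = {k for _, k in self.entries} - set(self.KINDS)
        if bad:
            raise ValueError(f"unknown trigger kinds: {sorted(bad)}")

    def samples(self, kind: str | None = None) -> np.ndarray:
        return np.array(
            [s for s, k in self.entries if kind is None or k == kind], dtype=int
        )

    def count(self, kind: str) -> int:
        return sum(1 for _, k in self.entries if k == kind)

    def __len__(self) -> int:
        return len(self.entries)


# ---------------------------------------------------------------------------
# TSV matrix dialect: two comment header lines, then one row per sample.
# ---------------------------------------------------------------------------

def write_tsv_matrix(recording: EEGRecording, path: str | Path) -> None:
    """Write a recording as a tab-separated sample matrix.

    Line 1: ``# fs=<Hz>``; line 2: tab-separated channel labels; then one
    row per sample (samples x channels), µV.
    """
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs={recording.fs:g}\n")
        fh.write("\t".join(recording.channel_labels) + "\n")
        np.savetxt(fh, recording.data.T, fmt="%.6f", delimiter="\t")


def _read_tsv_matrix(path: Path) -> EEGRecording:
    with path.open() as fh:
        header = fh.readline().strip()
        if not header.startswith("# fs="):
            raise ValueError(f"{path}: missing '# fs=' header line")
        fs = float(header.split("=", 1)[1])
        labels = fh.readline().strip().split("\t")
        data = np.loadtxt(fh, delimiter="\t", ndmin=2)
    if not labels or labels == [""]:
        raise ValueError(f"{path}: empty channel label line")
    return EEGRecording(data=data.T, fs=fs, channel_labels=labels)


# ---------------------------------------------------------------------------
# EDF.  Reading goes through MNE; writing is a minimal EDF encoder (16-bit,
# physical dimension µV, one data record per second) because no EDF writer
# is otherwise available in the stack.
# ---------------------------------------------------------------------------

def write_edf(recording: EEGRecording, path: str | Path) -> None:
    """Write an EDF file (16-bit integers, physical dimension uV).

    Data are padded with zeros to a whole number of 1-s data records.
    Physical min/max are the per-channel data extrema, so the quantization
    step is ``(max - min) / 65535`` per channel.
    """
    path = Path(path)
    fs = recording.fs
    if abs(fs - round(fs)) > 1e-9:
        raise ValueError("EDF export requires an integer sampling rate")
    spr = int(round(fs))  # samples per 1-s record per channel
    n_ch = recording.n_channels
    n_rec = int(np.ceil(recording.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, : recording.n_samples] = recording.data

    phys_min = data.min(axis=1)
    phys_max = data.max(axis=1)
    # avoid a degenerate range on constant channels
    flat = phys_max - phys_min < 1e-12
    phys_max[flat] = phys_min[flat] + 1.0
    dig_min, dig_max = -32768, 32767

    def _f(text: str, width: int) -> bytes:
        b = text.encode("ascii")
        if len(b) > width:
            b = b[:width]
        return b.ljust(width)

    now = _dt.datetime(2000, 1, 1)
    header = b"".join(
        [
            _f("0", 8),
            _f("X X X X", 80),
            _f("Startdate 01-JAN-2000 X X X", 80),
            _f(now.strftime("%d.%m.%y"), 8),
            _f(now.strftime("%H.%M.%S"), 8),
            _f(str(256 * (1 + n_ch)), 8),
            _f("", 44),
            _f(str(n_rec), 8),
            _f("1", 8),
            _f(str(n_ch), 4),
        ]
    )
    sig = b"".join(_f(lab, 16) for lab in recording.channel_labels)
    sig += b"".join(_f("", 80) for _ in range(n_ch))  # transducer
    sig += b"".join(_f("uV", 8) for _ in range(n_ch))
    sig += b"".join(_f(f"{v:.6g}", 8) for v in phys_min)
    sig += b"".join(_f(f"{v:.6g}", 8) for v in phys_max)
    sig += b"".join(_f(str(dig_min), 8) for _ in range(n_ch))
    sig += b"".join(_f(str(dig_max), 8) for _ in range(n_ch))
    sig += b"".join(_f("", 80) for _ in range(n_ch))  # prefiltering
    sig += b"".join(_f(str(spr), 8) for _ in range(n_ch))
    sig += b"".join(_f("", 32) for _ in range(n_ch))

    scale = (dig_max - dig_min) / (phys_max - phys_min)
    digital = np.rint((data - phys_min[:, None]) * scale[:, None] + dig_min)
    digital = np.clip(digital, dig_min, dig_max).astype("<i2")

    with path.open("wb") as fh:
        fh.write(header + sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr : (r + 1) * spr].tobytes())


def _read_edf(path: Path, channels: list[str] | None) -> EEGRecording:
    import mne

    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    labels = list(raw.ch_names)
    if channels is not None:
        if not channels:
            raise ValueError("empty channel selection")
        missing = [c for c in channels if c not in labels]
        if missing:
            raise ValueError(f"channels not in file: {missing}")
        raw.pick(channels)
        labels = list(raw.ch_names)
    rates = set(raw.info["sfreq"] for _ in [0])
    fs = float(raw.info["sfreq"])
    if len(rates) != 1:
        raise ValueError("mixed sampling rates in EDF selection")
    data = raw.get_data() * 1e6  # MNE returns volts
    return EEGRecording(data=data, fs=fs, channel_labels=labels)


def read_recording(
    path: str | Path,
    format: str = "edf",
    channels: list[str] | None = None,
) -> EEGRecording:
    """Read a recording from ``edf`` or ``tsv_matrix`` format, in µV.

    Fails loudly on NaNs, unknown formats, or missing channels.
    """
    path = Path(path)
    if format == "edf":
        return _read_edf(path, channels)
    if format == "tsv_matrix":
        rec = _read_tsv_matrix(path)
        if channels is not None:
            if not channels:
                raise ValueError("empty channel selection")
            idx = [rec.channel_labels.index(c) for c in channels]
            rec = EEGRecording(rec.data[idx], rec.fs, list(channels))
        return rec
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# Trigger TSV: two columns (sample, kind), one header line.
# ---------------------------------------------------------------------------

def write_triggers(triggers: TriggerRecord, path: str | Path) -> None:
    with Path(path).open("w") as fh:
        fh.write("sample\tkind\n")
        for s, k in triggers.entries:
            fh.write(f"{s}\t{k}\n")


def read_triggers(path: str | Path) -> TriggerRecord:
    entries: list[tuple[int, str]] = []
    with Path(path).open() as fh:
        header = fh.readline()
        if not header.startswith("sample"):
            raise ValueError(f"{path}: missing trigger header")
        for line in fh:
            if not line.strip():
                continue
            s, k = line.split("\t")
            entries.append((int(s), k.strip()))
    return TriggerRecord(entries=entries)
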