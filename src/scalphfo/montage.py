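"""Bipolar montage derivation for 10–20 scalp EEG.

Bipolar referencing (anode minus cathode of neighbouring electrodes) reduces
common-mode noise from ocular and facial muscle sources, which is why it is
the montage of choice for scalp HFO review.  The default here is the
standard longitudinal ("double banana") chain set, restricted to whatever
labels a recording actually has.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import EEGRecording

__all__ = [
    "BipolarMontage",
    "to_bipolar",
    "default_longitudinal_montage",
    "hemisphere_of",
    "STUDY_CHANNELS_29",
    "TEN_TWENTY_19",
]

#: The classic 19-electrode 10–20 set (modern T7/T8/P7/P8 naming).
TEN_TWENTY_19 = [
    "Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8",
    "T7", "C3", "Cz", "C4", "T8",
    "P7", "P3", "Pz", "P4", "P8", "O1", "O2",
]

#: A 29-electrode extended 10–20 layout of the kind used on epilepsy
#: monitoring units (19 standard positions plus an inferior temporal row).
#: Shipped as a convenience constant; any label set is accepted.
STUDY_CHANNELS_29 = TEN_TWENTY_19 + [
    "F9", "F10", "FT9", "FT10", "T9", "T10", "TP9", "TP10", "P9", "P10",
]

# legacy aliases still common in clinical systems
_ALIASES = {"T3": "T7", "T4": "T8", "T5": "P7", "T6": "P8"}

_CHAINS = [
    ["Fp1", "F7", "T7", "P7", "O1"],   # left temporal
    ["Fp1", "F3", "C3", "P3", "O1"],   # left parasagittal
    ["Fz", "Cz", "Pz"],                # midline
    ["Fp2", "F4", "C4", "P4", "O2"],   # right parasagittal
    ["Fp2", "F8", "T8", "P8", "O2"],   # right temporal
    ["F9", "T9", "P9"],                # left inferior temporal
    ["F10", "T10", "P10"],             # right inferior temporal
]


@dataclass
class BipolarMontage:
    """Ordered list of (anode, cathode) derivations."""

    derivations: list[tuple[str, str]]

    def __post_init__(self) -> None:
        if len(set(self.derivations)) != len(self.derivations):
            raise ValueError("duplicate derivations in montage")

    @property
    def labels(self) -> list[str]:
        return [f"{a}-{c}" for a, c in self.derivations]

    def __len__(self) -> int:
        return len(self.derivations)


def to_bipolar(recording: EEGRecording, montage: BipolarMontage) -> EEGRecording:
    """Re-reference a recording: output channel = anode − cathode.

    Raises a KeyError naming the first label absent from the recording.
    """
    rows = []
    for anode, cathode in montage.derivations:
        rows.append(recording.channel(anode) - recording.channel(cathode))
    data = np.array(rows) if rows else np.empty((0, recording.n_samples))
    return EEGRecording(
        data=data,
        fs=recording.fs,
        channel_labels=montage.labels,
        t0_sample=recording.t0_sample,
    )


def default_longitudinal_montage(channel_labels: list[str]) -> BipolarMontage:
    """Longitudinal bipolar chains restricted to the available labels.

    Chains run anterior to posterior (left temporal, left parasagittal,
    midline, right parasagittal, right temporal, then inferior rows); a pair
    is included only when both electrodes are present, so sparse label sets
    yield a correspondingly sparse — possibly empty — montage.  Legacy
    T3/T4/T5/T6 names are treated as T7/T8/P7/P8.
    """
    canonical = {}
    for lab in channel_labels:
        canonical[_ALIASES.get(lab, lab)] = lab
    derivations = []
    for chain in _CHAINS:
        for a, c in zip(chain, chain[1:]):
            if a in canonical and c in canonical:
                pair = (canonical[a], canonical[c])
                if pair not in derivations:
                    derivations.append(pair)
    return BipolarMontage(derivations=derivations)


def hemisphere_of(label: str) -> str:
    """Classify an electrode or derivation label as left/right/midline.

    By 10–20 convention odd indices are left, even are right, 'z' is
    midline.  A bipolar label ('F3-C3') is classified by its anode.
    """
    head = label.split("-")[0].strip()
    trailing = "".join(ch for ch in head if ch.isdigit())
    if not trailing:
        if head and head[-1].lower() == "z":
            return "midline"
        raise ValueError(f"cannot classify label {label!r}")
    return "left" if int(trailing) % 2 == 1 else "right"
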