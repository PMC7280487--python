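"""ROI event rates and task-trigger coupling.

Validated events are aggregated two ways: per-minute rates over a region
of interest (all channels, or grouped by hemisphere with midline
derivations excluded), and trigger-normalized rates in which each event is
assigned to the typing or resting trigger whose sampling window contains
its onset.

The rate convention is channel-averaged — events / minutes / channels — so
a rate is comparable across ROIs of different sizes; the total-count
alternative (events / minutes) is reported alongside in the table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .classify import ClassifiedEvent
from .io import TriggerRecord
from .montage import hemisphere_of

__all__ = [
    "ROIDefinition",
    "CoupledEvent",
    "compute_rates",
    "couple_triggers",
    "trigger_normalized_rates",
    "coupling_summary",
    "coupled_to_frame",
]


@dataclass
class ROIDefinition:
    """A named channel set with a hemisphere map.

    Default hemisphere assignment follows the 10–20 odd/even/z convention;
    entries in ``hemisphere_map`` override it.  ROI memberships are a
    configuration choice, not a fixed fact of the method.
    """

    name: str
    channels: list[str]
    hemisphere_map: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.channels:
            raise ValueError("ROI channel list must be non-empty")

    def hemisphere(self, channel: str) -> str:
        if channel in self.hemisphere_map:
            return self.hemisphere_map[channel]
        return hemisphere_of(channel)


@dataclass
class CoupledEvent:
    """An event with its trigger assignment (typing / resting / unrelated)."""

    event: ClassifiedEvent
    coupling: str
    trigger_sample: int | None = None
    offset_from_trigger: int | None = None

    def __post_init__(self) -> None:
        if self.coupling not in ("typing", "resting", "unrelated"):
            raise ValueError(f"unknown coupling {self.coupling!r}")


def compute_rates(
    events: list[ClassifiedEvent],
    roi: ROIDefinition,
    segment_minutes: float,
    group_by_hemisphere: bool = False,
    subject_id: str = "S00",
) -> pd.DataFrame:
    """Per-minute, channel-averaged event rates over an ROI.

    One row per HFO type (ripple, fast_ripple, all) and — in hemisphere
    mode — per hemisphere, midline channels excluded before counting.
    Columns include both the channel-averaged ``rate_per_min`` and the
    total-count alternative ``rate_per_min_total``.
    """
    if not segment_minutes > 0:
        raise ValueError("segment_minutes must be positive")
    in_roi = [e for e in events if e.eoi.channel in roi.channels]

    if group_by_hemisphere:
        groups = {}
        for hemi in ("left", "right"):
            chans = [c for c in roi.channels if roi.hemisphere(c) == hemi]
            groups[hemi] = chans
    else:
        groups = {"all": list(roi.channels)}

    rows = []
    for gname, chans in groups.items():
        evs = [e for e in in_roi if e.eoi.channel in chans]
        n_ch = len(chans)
        for hfo_type in ("ripple", "fast_ripple", "all"):
            sel = evs if hfo_type == "all" else [
                e for e in evs if e.label == hfo_type
            ]
            n = len(sel)
            rows.append(
                {
                    "subject_id": subject_id,
                    "roi_name": roi.name,
                    "hemisphere_or_all": gname,
                    "hfo_type": hfo_type,
                    "n_events": n,
                    "minutes": segment_minutes,
                    "n_channels": n_ch,
                    "rate_per_min": n / segment_minutes / n_ch if n_ch else 0.0,
                    "rate_per_min_total": n / segment_minutes,
                }
            )
    return pd.DataFrame(rows)


def couple_triggers(
    events: list[ClassifiedEvent],
    triggers: TriggerRecord,
    window_samples: int = 400,
    one_sided: bool = False,
) -> list[CoupledEvent]:
    """Assign each event to the trigger whose window contains its onset.

    Symmetric windows ``[t - w/2, t + w/2)`` by default (``[t, t + w)``
    with ``one_sided``).  When several windows cover an onset the nearest
    trigger wins, ties going to the earlier trigger; onsets covered by no
    window are ``unrelated``.  The assignment partitions the events.
    """
    trig = np.array([s for s, _ in triggers.entries], dtype=int)
    kinds = [k for _, k in triggers.entries]
    half = window_samples // 2
    out = []
    for ev in events:
        onset = ev.eoi.onset_sample
        if trig.size == 0:
            out.append(CoupledEvent(ev, "unrelated"))
            continue
        offs = onset - trig
        if one_sided:
            inside = (offs >= 0) & (offs < window_samples)
        else:
            inside = (offs >= -half) & (offs < half)
        if not inside.any():
            out.append(CoupledEvent(ev, "unrelated"))
            continue
        cand = np.flatnonzero(inside)
        dist = np.abs(offs[cand])
        # nearest trigger; ties broken by the earlier (smaller sample) one
        best = cand[np.lexsort((trig[cand], dist))][0]
        out.append(
            CoupledEvent(ev, kinds[best], int(trig[best]), int(offs[best]))
        )
    return out


def trigger_normalized_rates(
    coupled: list[CoupledEvent],
    n_typing_triggers: int,
    n_resting_triggers: int,
) -> tuple[float, float]:
    """(typing, resting) event counts divided by their trigger counts.

    Unrelated events are discarded from both numerators.
    """
    if n_typing_triggers <= 0 or n_resting_triggers <= 0:
        raise ValueError("trigger counts must be positive")
    n_typing = sum(1 for c in coupled if c.coupling == "typing")
    n_resting = sum(1 for c in coupled if c.coupling == "resting")
    return n_typing / n_typing_triggers, n_resting / n_resting_triggers


def coupling_summary(coupled: list[CoupledEvent]) -> tuple[float, float, float]:
    """Percentages of events (coupled overall, typing-, resting-coupled)."""
    if not coupled:
        raise ValueError("empty event list")
    n = len(coupled)
    n_t = sum(1 for c in coupled if c.coupling == "typing")
    n_r = sum(1 for c in coupled if c.coupling == "resting")
    return (100.0 * (n_t + n_r) / n, 100.0 * n_t / n, 100.0 * n_r / n)


def coupled_to_frame(coupled: list[CoupledEvent]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "channel": c.event.eoi.channel,
                "onset_sample": c.event.eoi.onset_sample,
                "label": c.event.label,
                "coupling": c.coupling,
                "trigger_sample": c.trigger_sample,
                "offset_from_trigger": c.offset_from_trigger,
            }
            for c in coupled
        ],
        columns=["channel", "onset_sample", "label", "coupling",
                 "trigger_sample", "offset_from_trigger"],
    )
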