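"""End-to-end orchestration: configuration, staged execution, reporting.

A single :class:`PipelineConfig` (serializable to YAML) drives a full run:
simulate or load a recording, derive the bipolar montage, detect events of
interest, classify and validate them, aggregate ROI rates and trigger
coupling, and — across a simulated cohort — fit the Wald-type factorial
models.  Every stage writes its table as TSV into the output directory and
the run closes with a JSON manifest of per-stage counts.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from .classify import ClassifierParams, classified_to_frame, classify_events, \
    validate_events
from .detect import DetectorParams, detect, events_to_frame
from .io import read_recording, read_triggers
from .montage import default_longitudinal_montage, to_bipolar
from .rates import ROIDefinition, compute_rates, couple_triggers, \
    coupled_to_frame, coupling_summary, trigger_normalized_rates
from .simulate import SimulationConfig, embed_events, generate_background, \
    generate_task_triggers, place_random_events

logger = logging.getLogger("scalphfo")

__all__ = ["PipelineConfig", "run_pipeline", "make_report"]

#: default ROI conventions (editable configuration, not method constants):
#: sleep ROI = all longitudinal derivations, task ROI = central derivations
DEFAULT_ROI_TASK = ["F3-C3", "C3-P3", "Fz-Cz", "Cz-Pz", "F4-C4", "C4-P4"]


@dataclass
class PipelineConfig:
    """Validated configuration for a full pipeline run."""

    out_dir: str = "scalphfo_out"
    seed: int = 0
    # input: either a file, or simulation parameters
    input_path: str | None = None
    input_format: str = "edf"
    trigger_path: str | None = None
    simulation: dict = field(default_factory=dict)
    n_events: int = 30
    event_amplitude_uv: float = 60.0
    # stages
    use_bipolar: bool = True
    detector: dict = field(default_factory=dict)
    classifier: dict = field(default_factory=dict)
    roi_name: str = "ROI_Sleep"
    roi_channels: list[str] | None = None
    coupling_window_samples: int = 400
    # statistics
    n_boot: int = 1000
    alpha: float = 0.05

    def detector_params(self) -> DetectorParams:
        return DetectorParams(**self.detector)

    def classifier_params(self) -> ClassifierParams:
        return ClassifierParams(**self.classifier)

    def simulation_config(self) -> SimulationConfig:
        sim = dict(self.simulation)
        sim.setdefault("rng_seed", self.seed)
        return SimulationConfig(**sim)

    def validate(self) -> None:
        fs = self.simulation_config().fs if self.input_path is None else None
        if fs is not None:
            self.detector_params().validate(fs)
        if self.coupling_window_samples <= 0:
            raise ValueError("coupling_window_samples must be positive")
        if self.n_boot and self.n_boot < 100:
            raise ValueError("n_boot must be 0 or >= 100")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            payload = yaml.safe_load(fh) or {}
        return cls(**payload)

    def to_yaml(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _acquire(config: PipelineConfig):
    """Return (recording, triggers, truth_events) from file or simulation."""
    if config.input_path is not None:
        rec = read_recording(config.input_path, config.input_format)
        trig = (read_triggers(config.trigger_path)
                if config.trigger_path else None)
        return rec, trig, None
    sim = config.simulation_config()
    rng = np.random.default_rng(config.seed)
    bg = generate_background(sim)
    truths = place_random_events(
        sim, rng, config.n_events,
        [100.0, 150.0, 200.0, 300.0, 350.0, 400.0],
        amplitude_uv=config.event_amplitude_uv,
    )
    rec, truths = embed_events(bg, truths)
    n_trials = int(sim.duration_s // 60)
    trig = (generate_task_triggers(sim, n_trials, 30.0, 10)
            if n_trials >= 1 else None)
    return rec, trig, truths


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute the full chain and write TSVs plus a JSON manifest.

    Returns the manifest (also saved as ``manifest.json``).
    """
    from . import __version__

    config.validate()
    t_start = time.time()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    config.to_yaml(out / "config.yaml")
    manifest: dict = {"version": __version__, "seed": config.seed,
                      "stages": {}}

    def stage(name: str, **counts) -> None:
        manifest["stages"][name] = counts
        logger.info("%s: %s", name,
                    ", ".join(f"{k}={v}" for k, v in counts.items()))

    rec, triggers, truths = _acquire(config)
    stage("input", n_channels=rec.n_channels, n_samples=rec.n_samples,
          fs=rec.fs)

    if config.use_bipolar:
        montage = default_longitudinal_montage(rec.channel_labels)
        if len(montage):
            rec = to_bipolar(rec, montage)
        stage("montage", n_derivations=rec.n_channels)

    dp = config.detector_params()
    eois = detect(rec, dp)
    events_to_frame(eois).to_csv(out / "eois.tsv", sep="\t", index=False)
    stage("detect", n_eois=len(eois))

    cp = config.classifier_params()
    classified = classify_events(eois, rec, cp, dp)
    validated = validate_events(classified, cp)
    classified_to_frame(classified).to_csv(out / "classified.tsv", sep="\t",
                                           index=False)
    classified_to_frame(validated).to_csv(out / "validated.tsv", sep="\t",
                                          index=False)
    stage("classify", n_classified=len(classified), n_validated=len(validated),
          n_artifact=sum(1 for c in classified if c.label == "artifact"))

    roi_channels = config.roi_channels or [
        c for c in rec.channel_labels
    ]
    roi = ROIDefinition(config.roi_name, roi_channels)
    minutes = rec.n_samples / rec.fs / 60.0
    rates_all = compute_rates(validated, roi, minutes)
    rates_hemi = compute_rates(validated, roi, minutes,
                               group_by_hemisphere=True)
    import pandas as pd

    rates = pd.concat([rates_all, rates_hemi], ignore_index=True)
    rates.to_csv(out / "rates.tsv", sep="\t", index=False)
    stage("rates", n_rows=len(rates))

    if triggers is not None and len(triggers):
        coupled = couple_triggers(validated, triggers,
                                  config.coupling_window_samples)
        coupled_to_frame(coupled).to_csv(out / "coupled.tsv", sep="\t",
                                         index=False)
        n_t = triggers.count("typing")
        n_r = triggers.count("resting")
        if n_t and n_r:
            tr, rr = trigger_normalized_rates(coupled, n_t, n_r)
        else:
            tr = rr = float("nan")
        if coupled:
            pc, pt, pr = coupling_summary(coupled)
        else:
            pc = pt = pr = float("nan")
        stage("coupling", n_coupled=sum(c.coupling != "unrelated"
                                        for c in coupled),
              typing_rate=tr, resting_rate=rr, pct_coupled=pc)

    if truths is not None:
        # after bipolar re-referencing an embedded event appears on every
        # derivation containing its electrode
        tol = int(round(10 * rec.fs / 1000.0))
        n_rec = 0
        for t in truths:
            for v in validated:
                parts = v.eoi.channel.split("-")
                if t.channel not in parts and t.channel != v.eoi.channel:
                    continue
                if (v.eoi.onset_sample < t.offset_sample + tol
                        and t.onset_sample - tol < v.eoi.offset_sample):
                    n_rec += 1
                    break
        stage("ground_truth", n_embedded=len(truths), n_recovered=n_rec)

    manifest["wall_time_s"] = round(time.time() - t_start, 3)
    with (out / "manifest.json").open("w") as fh:
        json.dump(manifest, fh, indent=2, default=float)
    return manifest


def make_report(manifest: dict | str | Path) -> str:
    """Human-readable per-stage summary of a completed run."""
    if not isinstance(manifest, dict):
        path = Path(manifest)
        if not path.exists():
            raise FileNotFoundError(f"missing manifest: {path}")
        with path.open() as fh:
            manifest = json.load(fh)
    lines = [
        f"scalphfo run (version {manifest.get('version', '?')}, "
        f"seed {manifest.get('seed', '?')})",
    ]
    for name, counts in manifest.get("stages", {}).items():
        pretty = ", ".join(f"{k}={v}" for k, v in counts.items())
        lines.append(f"  {name:<14} {pretty}")
    lines.append(f"  wall time      {manifest.get('wall_time_s', '?')} s")
    return "\n".join(lines)
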