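"""End-to-end analysis, training and evaluation runs.

One well flows spikes -> reverberations -> bursts -> network
reverberations -> network bursts -> metrics, with the detector driven
either by fixed MaxInterval parameters ("default" mode) or by per-window
parameters predicted by a trained model. Runs emit an event CSV, a
metric CSV and a JSON manifest (config snapshot, input digests, seed,
per-well counts) so an identical manifest reproduces identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .io import (Recording, SpikeTrainSet, load_training_dataset,
                 read_recording, read_spike_table, write_event_table,
                 write_metric_table)
from .maxinterval import EventInterval, MaxIntervalParams, merge_events
from .metrics import MetricConfig, WellMetrics, compute_well_metrics
from .model import (LearningCurves, ParamModel, TrainConfig, burst_occupancy,
                    burst_overlap_error, evaluate_model, predict_reverberations,
                    split_dataset, train_model)
from .maxinterval import detect_reverberations
from .network import (NetworkCriteria, active_channels,
                      detect_network_bursts, detect_network_reverberations)
from .spikes import SpikeDetectConfig, bandpass, detect_spikes, estimate_baseline

log = logging.getLogger(__name__)


@dataclass
class AnalysisConfig:
    """Everything one analysis run needs; mirrors the YAML sections
    spikes / maxinterval / network / metrics / model."""

    spikes: SpikeDetectConfig = field(default_factory=SpikeDetectConfig)
    maxinterval: MaxIntervalParams = field(default_factory=MaxIntervalParams)
    network: NetworkCriteria = field(default_factory=NetworkCriteria)
    metrics: MetricConfig = field(default_factory=MetricConfig)
    filter_first: bool = False
    window_s: float = 5.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kw = {}
        sections = {"spikes": SpikeDetectConfig,
                    "maxinterval": MaxIntervalParams,
                    "network": NetworkCriteria,
                    "metrics": MetricConfig}
        for name, klass in sections.items():
            if name in raw:
                section = dict(raw[name])
                if name == "maxinterval" and "preset" in section:
                    preset = MaxIntervalParams.preset(section.pop("preset"))
                    kw[name] = dataclasses.replace(preset, **section)
                else:
                    kw[name] = klass(**section)
        for key in ("filter_first", "window_s"):
            if key in raw:
                kw[key] = raw[key]
        return cls(**kw)

    def snapshot(self) -> dict:
        return {
            "spikes": dataclasses.asdict(self.spikes),
            "maxinterval": dataclasses.asdict(self.maxinterval),
            "network": dataclasses.asdict(self.network),
            "metrics": dataclasses.asdict(self.metrics),
            "filter_first": self.filter_first,
            "window_s": self.window_s,
        }


@dataclass
class WellAnalysis:
    """All per-well analysis products."""

    well_id: str
    spike_trains: SpikeTrainSet
    reverberations: dict[str, list[EventInterval]]
    bursts: dict[str, list[EventInterval]]
    network_reverberations: list[EventInterval]
    network_bursts: list[EventInterval]
    active: set[str]
    metrics: WellMetrics


def extract_spikes(recording: Recording,
                   config: SpikeDetectConfig = SpikeDetectConfig()
                   ) -> SpikeTrainSet:
    """Threshold spike detection on every channel of a recording."""
    trains = {}
    for c, ch in enumerate(recording.channel_ids):
        x = recording.signal[c]
        if config.apply_bandpass:
            x = bandpass(x, recording.sampling_rate_hz)
        baseline = estimate_baseline(x, recording.sampling_rate_hz, config)
        trains[ch] = detect_spikes(x, recording.sampling_rate_hz, baseline,
                                   config, t0_s=recording.t0_s)
    return SpikeTrainSet(well_id=recording.well_id, trains=trains,
                         t0_s=recording.t0_s,
                         duration_s=recording.duration_s)


def analyze_well(spike_trains: SpikeTrainSet, duration_s: float,
                 config: AnalysisConfig = AnalysisConfig(),
                 model: ParamModel | None = None,
                 recording: Recording | None = None) -> WellAnalysis:
    """Run the full event hierarchy and metrics for one well.

    With ``model`` set, reverberations are detected with per-window
    predicted parameters (5-s windows); otherwise with the fixed
    ``config.maxinterval`` parameters. Everything downstream of the
    reverberations is identical in both modes.
    """
    if model is not None:
        reverbs = predict_reverberations(spike_trains, model, duration_s,
                                         recording=recording,
                                         window_s=config.window_s)
    else:
        reverbs = {ch: detect_reverberations(t, config.maxinterval,
                                             channel=ch,
                                             filter_first=config.filter_first)
                   for ch, t in spike_trains.trains.items()}
    bursts = {ch: merge_events(evs) if evs else []
              for ch, evs in reverbs.items()}
    active = active_channels(spike_trains, duration_s, config.network)
    if active:
        net_rev = detect_network_reverberations(
            {ch: evs for ch, evs in reverbs.items()
             if ch in active and evs}, active, config.network)
        net_bursts = detect_network_bursts(net_rev, config.network)
    else:
        net_rev, net_bursts = [], []
    metrics = compute_well_metrics(spike_trains, net_rev, net_bursts,
                                   duration_s, active, config.metrics)
    return WellAnalysis(well_id=spike_trains.well_id,
                        spike_trains=spike_trains, reverberations=reverbs,
                        bursts=bursts, network_reverberations=net_rev,
                        network_bursts=net_bursts, active=active,
                        metrics=metrics)


# ---------------------------------------------------------------------------
# multi-file runs with manifest


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as f:
        for chunk in iter(lambda: f.read(1 << 16), b""):
            h.update(chunk)
    return h.hexdigest()[:16]


def run_analysis(inputs: list[str | Path], out_dir: str | Path,
                 config: AnalysisConfig = AnalysisConfig(),
                 mode: str = "default", seed: int = 0) -> dict:
    """Analyze recording HDF5 (.h5/.hdf5) and/or spike-table CSV inputs.

    ``mode`` is ``"default"`` or ``"model:<checkpoint dir>"``. Writes
    ``events.csv``, ``metrics.csv`` and ``manifest.json`` under
    ``out_dir`` and returns the manifest. Per-well failures are recorded
    in the manifest and do not stop other wells.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    model = None
    if mode.startswith("model:"):
        model = ParamModel.load(mode.split(":", 1)[1])
    elif mode != "default":
        raise ValueError(f"unknown mode {mode!r}")

    wells: list[tuple[SpikeTrainSet, float, Recording | None]] = []
    digests = {}
    for p in map(Path, inputs):
        digests[str(p)] = _digest(p)
        if p.suffix.lower() in (".h5", ".hdf5"):
            rec = read_recording(p, layout="hdf5")
            trains = extract_spikes(rec, config.spikes)
            wells.append((trains, rec.duration_s, rec))
        else:
            for trains in read_spike_table(p).values():
                dur = trains.duration_s
                if dur is None:
                    last = max((t[-1] for t in trains.trains.values()
                                if t.size), default=0.0)
                    dur = float(np.ceil(last)) or 1.0
                wells.append((trains, dur, None))

    event_rows_by_level: dict[str, list] = {}
    metric_rows, failures, counts = [], {}, {}
    events_csv = out_dir / "events.csv"
    frames = []
    for trains, dur, rec in wells:
        try:
            res = analyze_well(trains, dur, config, model=model,
                               recording=rec)
        except Exception as exc:  # keep other wells running
            log.error("well %s failed: %s", trains.well_id, exc)
            failures[trains.well_id] = str(exc)
            continue
        tmp = out_dir / f".events-{res.well_id}.csv"
        write_event_table(
            {"burst": [b for evs in res.bursts.values() for b in evs],
             "network_burst": res.network_bursts},
            res.well_id, tmp)
        frames.append(pd.read_csv(tmp, keep_default_na=False))
        tmp.unlink()
        metric_rows.append(res.metrics.as_row())
        counts[res.well_id] = {
            "n_spikes": res.spike_trains.n_spikes,
            "n_reverberations": sum(len(v) for v in res.reverberations.values()),
            "n_bursts": sum(len(v) for v in res.bursts.values()),
            "n_network_reverberations": len(res.network_reverberations),
            "n_network_bursts": len(res.network_bursts),
        }
        log.info("well %s: %s", res.well_id, counts[res.well_id])
    if frames:
        pd.concat(frames, ignore_index=True).to_csv(events_csv, index=False)
    else:
        write_event_table({}, "", events_csv)
    write_metric_table(metric_rows, out_dir / "metrics.csv")

    manifest = {
        "software": {"name": "meaburst", "version": __version__},
        "mode": mode,
        "seed": seed,
        "config": config.snapshot(),
        "inputs": digests,
        "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        "wells": counts,
        "failures": failures,
    }
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    if failures:
        raise RuntimeError(
            f"{len(failures)} well(s) failed: {sorted(failures)}")
    return manifest


# ---------------------------------------------------------------------------
# training / evaluation runs


def run_train(dataset_path: str | Path, out_dir: str | Path,
              config: TrainConfig = TrainConfig(),
              variant: str = "signal30") -> tuple[ParamModel, LearningCurves]:
    """Train a parameter model from a training container and write the
    checkpoint plus a per-epoch curves CSV."""
    samples = load_training_dataset(dataset_path)
    model, curves = train_model(samples, config, variant)
    out_dir = Path(out_dir)
    model.save(out_dir / "checkpoint")
    pd.DataFrame(curves.as_rows()).to_csv(out_dir / "curves.csv", index=False)
    return model, curves


def run_evaluate(dataset_path: str | Path, checkpoint: str | Path,
                 split: str = "test") -> dict:
    """Evaluate a checkpoint on one split of a dataset (never the
    training split unless explicitly asked)."""
    samples = load_training_dataset(dataset_path)
    model = ParamModel.load(checkpoint)
    tr, va, te = split_dataset(len(samples), model.config.split,
                               model.config.seed)
    idx = {"train": tr, "validation": va, "test": te}[split]
    report = evaluate_model(model, samples, idx)
    report["split"] = split
    return report


def score_event_tables(predicted_csv: str | Path, target_csv: str | Path,
                       duration_s: float,
                       sampling_rate_hz: float = 10_000.0,
                       level: str = "burst") -> float:
    """Timestamp-wise overlap error between the ``level`` rows of two
    event CSVs, rasterized at the sampling rate."""
    from .io import read_event_table

    n = int(round(duration_s * sampling_rate_hz))

    def occupancy(path):
        df = read_event_table(path)
        df = df[df["level"] == level]
        events = [EventInterval(start_s=r.start_s, end_s=r.end_s,
                                spike_count=int(r.n_spikes))
                  for r in df.itertuples()]
        return burst_occupancy(events, n, sampling_rate_hz)

    return burst_overlap_error(occupancy(predicted_csv),
                               occupancy(target_csv))
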