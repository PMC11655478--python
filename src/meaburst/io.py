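"""Readers and writers for recordings, spike tables, event tables and
training containers.

All on-disk timestamps are seconds; MaxInterval parameters travel in
milliseconds (the units the detector literature prints). Event intervals
are half-open ``[start_s, end_s)`` where ``end_s`` is the time of the
event's last spike.

Formats
-------
Recording HDF5
    dataset ``/signal`` (channels x samples, float, microvolts),
    dataset ``/channel_ids`` (strings), root attributes
    ``sampling_rate_hz`` and ``well_id``.
Spike CSV
    header ``well,channel,time_s``.
Event CSV
    header ``well,level,event_id,parent_id,channel,start_s,end_s,n_spikes``
    with ``level`` one of reverberation, burst, network_reverberation,
    network_burst; ``channel`` empty for network-level rows.
Metric CSV
    header ``well,mfr_hz,pct_random_spikes,nbr_per_min,nibi_s,cov_nibi,
    nbd_s,net_reverb_dur_s,nbc``; undefined metrics are empty cells.
Training container HDF5
    datasets ``signal``, ``spikes``, ``bursts`` (n x 50000) and
    ``params_ms`` (n x 3), root attribute ``count``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: samples in one 5-s training window at 10 kHz
WINDOW_LEN = 50_000

METRIC_COLUMNS = [
    "well", "mfr_hz", "pct_random_spikes", "nbr_per_min", "nibi_s",
    "cov_nibi", "nbd_s", "net_reverb_dur_s", "nbc",
]

EVENT_LEVELS = ("reverberation", "burst", "network_reverberation",
                "network_burst")


class FormatError(ValueError):
    """File does not conform to the documented layout."""


class ValidationError(ValueError):
    """File parses but violates a data invariant."""


# ---------------------------------------------------------------------------
# domain types


@dataclass
class Recording:
    """Multi-channel extracellular voltage trace for one well."""

    well_id: str
    channel_ids: list[str]
    signal: np.ndarray          # (channels, samples), microvolts
    sampling_rate_hz: float = 10_000.0
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        if self.signal.ndim != 2:
            raise ValidationError("signal must be 2-D (channels x samples)")
        if len(self.channel_ids) != self.signal.shape[0]:
            raise ValidationError(
                f"{len(self.channel_ids)} channel ids for "
                f"{self.signal.shape[0]} signal rows")
        if self.sampling_rate_hz <= 0:
            raise ValidationError("sampling_rate_hz must be positive")
        bad = ~np.isfinite(self.signal)
        if bad.any():
            ch, idx = np.argwhere(bad)[0]
            raise ValidationError(
                f"non-finite sample in channel {self.channel_ids[ch]!r} "
                f"at index {idx}")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def duration_s(self) -> float:
        return self.signal.shape[1] / self.sampling_rate_hz

    def times(self) -> np.ndarray:
        return self.t0_s + np.arange(self.signal.shape[1]) / self.sampling_rate_hz


@dataclass
class SpikeTrainSet:
    """Per-channel sorted spike timestamps (seconds) for one well."""

    well_id: str
    trains: dict[str, np.ndarray] = field(default_factory=dict)
    t0_s: float = 0.0
    duration_s: float | None = None

    def __post_init__(self) -> None:
        for ch, t in list(self.trains.items()):
            t = np.asarray(t, dtype=float)
            if t.size and np.any(np.diff(t) <= 0):
                raise ValidationError(
                    f"spike times on channel {ch!r} not strictly increasing")
            if t.size and t[0] < self.t0_s:
                raise ValidationError(
                    f"spike before t0 on channel {ch!r}")
            self.trains[ch] = t

    @property
    def channel_ids(self) -> list[str]:
        return list(self.trains)

    @property
    def n_spikes(self) -> int:
        return int(sum(t.size for t in self.trains.values()))

    def all_times(self) -> np.ndarray:
        """Pooled spike times of every channel, sorted."""
        if not self.trains:
            return np.empty(0)
        return np.sort(np.concatenate(list(self.trains.values())))


@dataclass
class TrainingSample:
    """One 5-s window: signal, binary spikes/bursts, 3 target parameters.

    ``params_ms`` orders the three learnable MaxInterval parameters as
    (max interval to start, max interval to end, min interval between).
    """

    signal: np.ndarray
    spikes: np.ndarray
    bursts: np.ndarray
    params_ms: np.ndarray

    def __post_init__(self) -> None:
        self.signal = np.asarray(self.signal, dtype=float)
        self.spikes = np.asarray(self.spikes)
        self.bursts = np.asarray(self.bursts)
        self.params_ms = np.asarray(self.params_ms, dtype=float)
        for name in ("signal", "spikes", "bursts"):
            arr = getattr(self, name)
            if arr.shape != (WINDOW_LEN,):
                raise ValidationError(
                    f"{name} must have shape ({WINDOW_LEN},), got {arr.shape}")
        for name in ("spikes", "bursts"):
            arr = getattr(self, name)
            if not np.isin(arr, (0, 1)).all():
                raise ValidationError(f"{name} must be binary")
        if self.params_ms.shape != (3,) or not (self.params_ms > 0).all():
            raise ValidationError("params_ms must be 3 positive values")


# ---------------------------------------------------------------------------
# recordings


def write_recording(rec: Recording, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("signal", data=rec.signal)
        f.create_dataset("channel_ids",
                         data=np.array(rec.channel_ids, dtype=object),
                         dtype=h5py.string_dtype())
        f.attrs["sampling_rate_hz"] = rec.sampling_rate_hz
        f.attrs["well_id"] = rec.well_id
        f.attrs["t0_s"] = rec.t0_s


def _read_recording_hdf5(path: Path) -> Recording:
    with h5py.File(path, "r") as f:
        if "signal" not in f:
            raise FormatError(f"{path}: missing /signal dataset")
        if "sampling_rate_hz" not in f.attrs:
            raise FormatError(f"{path}: missing sampling_rate_hz attribute")
        signal = f["signal"][()]
        if signal.ndim != 2:
            raise FormatError(f"{path}: /signal must be 2-D")
        if "channel_ids" in f:
            channel_ids = [c.decode() if isinstance(c, bytes) else str(c)
                           for c in f["channel_ids"][()]]
        else:
            channel_ids = [f"ch{i:02d}" for i in range(signal.shape[0])]
        return Recording(
            well_id=str(f.attrs.get("well_id", path.stem)),
            channel_ids=channel_ids,
            signal=signal,
            sampling_rate_hz=float(f.attrs["sampling_rate_hz"]),
            t0_s=float(f.attrs.get("t0_s", 0.0)),
        )


def _read_recording_delimited(path: Path) -> Recording:
    """Delimited dump: '# sampling_rate_hz=...' header line, then one
    whitespace/comma separated row per channel."""
    rate = None
    well_id = path.stem
    rows: list[np.ndarray] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                for tok in line[1:].replace(",", " ").split():
                    if "=" in tok:
                        k, v = tok.split("=", 1)
                        if k == "sampling_rate_hz":
                            rate = float(v)
                        elif k == "well_id":
                            well_id = v
                continue
            rows.append(np.fromstring(line.replace(",", " "), sep=" "))
    if rate is None:
        raise FormatError(f"{path}: no '# sampling_rate_hz=' header line")
    if not rows:
        raise FormatError(f"{path}: no signal rows")
    if len({r.size for r in rows}) != 1:
        raise FormatError(f"{path}: channels have unequal length")
    return Recording(well_id=well_id,
                     channel_ids=[f"ch{i:02d}" for i in range(len(rows))],
                     signal=np.vstack(rows), sampling_rate_hz=rate)


def read_recording(path: str | Path, layout: str = "hdf5") -> Recording:
    """Load a recording from the documented HDF5 or delimited-text layout."""
    path = Path(path)
    if layout == "hdf5":
        return _read_recording_hdf5(path)
    if layout == "delimited":
        return _read_recording_delimited(path)
    raise ValueError(f"unknown layout {layout!r}")


# ---------------------------------------------------------------------------
# spike tables


def write_spike_table(trains: SpikeTrainSet | Iterable[SpikeTrainSet],
                      path: str | Path) -> None:
    sets = [trains] if isinstance(trains, SpikeTrainSet) else list(trains)
    frames = []
    for s in sets:
        for ch, times in s.trains.items():
            frames.append(pd.DataFrame(
                {"well": s.well_id, "channel": ch, "time_s": times}))
    if frames:
        df = pd.concat(frames, ignore_index=True)
    else:
        df = pd.DataFrame(columns=["well", "channel", "time_s"])
    df.to_csv(path, index=False, float_format="%.9f")


def read_spike_table(path: str | Path) -> dict[str, SpikeTrainSet]:
    """Read a ``well,channel,time_s`` CSV, grouped per well.

    Times are sorted per channel; duplicate (well, channel, time) rows are
    collapsed with a warning; unknown columns are ignored with a warning.
    """
    df = pd.read_csv(path, dtype={"well": str, "channel": str})
    required = {"well", "channel", "time_s"}
    missing = required - set(df.columns)
    if missing:
        raise FormatError(f"{path}: missing columns {sorted(missing)}")
    extra = set(df.columns) - required
    if extra:
        log.warning("%s: ignoring unknown columns %s", path, sorted(extra))
    if len(df) and (df["time_s"] < 0).any():
        raise ValidationError(f"{path}: negative spike times")
    n0 = len(df)
    df = df.drop_duplicates(subset=["well", "channel", "time_s"])
    if len(df) < n0:
        log.warning("%s: collapsed %d duplicate spike rows", path, n0 - len(df))
    out: dict[str, SpikeTrainSet] = {}
    for well, wdf in df.groupby("well", sort=True):
        trains = {str(ch): np.sort(g["time_s"].to_numpy(dtype=float))
                  for ch, g in wdf.groupby("channel", sort=True)}
        out[str(well)] = SpikeTrainSet(well_id=str(well), trains=trains)
    return out


# ---------------------------------------------------------------------------
# event tables


def _flatten_events(events, level_names: Sequence[str], well_id: str,
                    counter: list[int]) -> list[dict]:
    """Depth-first rows from a forest of EventInterval-like objects;
    ``level_names`` maps depth to a level label, outermost first.
    ``counter`` keeps event ids unique across calls on one file."""
    rows: list[dict] = []

    def visit(ev, depth, parent_id):
        eid = counter[0]
        counter[0] += 1
        rows.append({
            "well": well_id,
            "level": level_names[depth],
            "event_id": eid,
            "parent_id": parent_id if parent_id is not None else "",
            "channel": ev.channel if ev.channel is not None else "",
            "start_s": ev.start_s,
            "end_s": ev.end_s,
            "n_spikes": ev.spike_count,
        })
        if depth + 1 < len(level_names):  # deeper levels (e.g. the channel
            for child in ev.children:     # reverberations under a network
                visit(child, depth + 1, eid)  # reverberation) have their own
                                              # rows in the channel hierarchy

    for ev in events:
        visit(ev, 0, None)
    return rows


def write_event_table(events_by_level: dict[str, list], well_id: str,
                      path: str | Path) -> None:
    """Write the event hierarchy of one well to CSV.

    ``events_by_level`` maps a top level name (``"burst"`` or
    ``"network_burst"``) to a list of parent events whose children are one
    level down. Multiple top levels may be written to one file; event ids
    are unique within the file and parent_id links children to parents.
    """
    child_of = {"burst": "reverberation",
                "network_burst": "network_reverberation"}
    rows: list[dict] = []
    counter = [0]
    for level, events in events_by_level.items():
        if level in child_of:
            names = (level, child_of[level])
        elif level in EVENT_LEVELS:
            names = (level,)
        else:
            raise ValueError(f"unknown event level {level!r}")
        rows.extend(_flatten_events(events, names, well_id, counter))
    df = pd.DataFrame(rows, columns=["well", "level", "event_id", "parent_id",
                                     "channel", "start_s", "end_s",
                                     "n_spikes"])
    df.to_csv(path, index=False, float_format="%.9f")


def read_event_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well": str, "level": str, "channel": str},
                     keep_default_na=False)
    required = {"well", "level", "event_id", "parent_id", "channel",
                "start_s", "end_s", "n_spikes"}
    if not required <= set(df.columns):
        raise FormatError(f"{path}: missing event-table columns")
    bad = ~df["level"].isin(EVENT_LEVELS)
    if len(df) and bad.any():
        raise FormatError(f"{path}: unknown level {df['level'][bad].iloc[0]!r}")
    for col in ("start_s", "end_s"):
        df[col] = pd.to_numeric(df[col])
    return df


# ---------------------------------------------------------------------------
# metric tables


def write_metric_table(rows: Iterable[dict], path: str | Path) -> None:
    """Write one WellMetrics row per well; NaN metrics become empty cells."""
    df = pd.DataFrame(list(rows), columns=METRIC_COLUMNS)
    df.to_csv(path, index=False, float_format="%.9f")


def read_metric_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"well": str})
    if list(df.columns) != METRIC_COLUMNS:
        raise FormatError(f"{path}: unexpected metric-table header")
    return df


# ---------------------------------------------------------------------------
# training containers


def save_training_dataset(samples: Sequence[TrainingSample],
                          path: str | Path) -> None:
    n = len(samples)
    with h5py.File(path, "w") as f:
        f.create_dataset("signal",
                         data=np.stack([s.signal for s in samples])
                         if n else np.empty((0, WINDOW_LEN)))
        f.create_dataset("spikes",
                         data=np.stack([s.spikes for s in samples]).astype(np.uint8)
                         if n else np.empty((0, WINDOW_LEN), np.uint8))
        f.create_dataset("bursts",
                         data=np.stack([s.bursts for s in samples]).astype(np.uint8)
                         if n else np.empty((0, WINDOW_LEN), np.uint8))
        # detector parameters are stored rounded to whole milliseconds
        f.create_dataset("params_ms",
                         data=np.rint([s.params_ms for s in samples]).astype(np.int64)
                         if n else np.empty((0, 3), np.int64))
        f.attrs["count"] = n


def load_training_dataset(path: str | Path) -> list[TrainingSample]:
    with h5py.File(path, "r") as f:
        for block in ("signal", "spikes", "bursts", "params_ms"):
            if block not in f:
                raise FormatError(f"{path}: missing {block!r} block")
        signal = f["signal"][()]
        spikes = f["spikes"][()]
        bursts = f["bursts"][()]
        params = f["params_ms"][()]
    n = signal.shape[0]
    shapes = {signal.shape, spikes.shape, bursts.shape}
    if shapes != {(n, WINDOW_LEN)} or params.shape != (n, 3):
        raise FormatError(f"{path}: inconsistent block shapes")
    return [TrainingSample(signal=signal[i], spikes=spikes[i],
                           bursts=bursts[i], params_ms=params[i].astype(float))
            for i in range(n)]
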