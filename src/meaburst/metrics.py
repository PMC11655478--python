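"""The eight per-well network-dynamics outcome measures.

Four categories: spiking activity (MFR), network synchronicity (%RS and
network burst rate), network rhythmicity (NIBI and its coefficient of
variation), and network burst characteristics (network burst duration,
network reverberation duration, network burst composition).

Undefined values (too few network bursts to measure) are NaN, never 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np

from .io import SpikeTrainSet
from .maxinterval import EventInterval


@dataclass(frozen=True)
class MetricConfig:
    mfr_over_active_only: bool = True
    nibi_mode: str = "end_to_start"      # or "start_to_start"

    def __post_init__(self) -> None:
        if self.nibi_mode not in ("end_to_start", "start_to_start"):
            raise ValueError("nibi_mode must be end_to_start or start_to_start")


@dataclass(frozen=True)
class WellMetrics:
    """One well's outcome measures; NaN marks an undefined field."""

    well_id: str
    mfr_hz: float
    pct_random_spikes: float
    nbr_per_min: float
    nibi_s: float
    cov_nibi: float
    nbd_s: float
    net_reverb_dur_s: float
    nbc: float

    def as_row(self) -> dict:
        row = asdict(self)
        row["well"] = row.pop("well_id")
        return {k: ("" if isinstance(v, float) and math.isnan(v) else v)
                for k, v in row.items()}


def _nan() -> float:
    return float("nan")


def compute_well_metrics(spike_trains: SpikeTrainSet,
                         network_reverberations: list[EventInterval],
                         network_bursts: list[EventInterval],
                         duration_s: float,
                         active: set[str],
                         config: MetricConfig = MetricConfig()) -> WellMetrics:
    """Compute the eight outcome measures for one well.

    MFR averages spike rate over the active channels (all channels with
    ``mfr_over_active_only=False``); a well with no active channel has
    MFR 0. %RS is the percentage of all recorded spikes, any channel,
    falling outside every network-burst span. NIBI is the quiescent gap
    from one network burst's end to the next one's start (start-to-start
    with ``nibi_mode='start_to_start'``); its CoV uses the sample (n-1)
    standard deviation. NIBI needs >= 2 network bursts, the CoV >= 3
    (two intervals); NBD, network reverberation duration and NBC need
    >= 1 network burst / reverberation — otherwise NaN.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")

    # (1) spiking activity
    if config.mfr_over_active_only:
        rates = [spike_trains.trains[ch].size / duration_s
                 for ch in active if ch in spike_trains.trains]
    else:
        rates = [t.size / duration_s for t in spike_trains.trains.values()]
    mfr = float(np.mean(rates)) if rates else 0.0

    # (2) synchronicity
    all_times = spike_trains.all_times()
    total = all_times.size
    if total == 0:
        pct_rs = _nan()
    elif not network_bursts:
        pct_rs = 100.0
    else:
        inside = np.zeros(total, dtype=bool)
        for nb in network_bursts:
            inside |= (all_times >= nb.start_s) & (all_times <= nb.end_s)
        pct_rs = 100.0 * (total - int(inside.sum())) / total
    nbr = len(network_bursts) / duration_s * 60.0

    # (3) rhythmicity
    if len(network_bursts) >= 2:
        nbs = sorted(network_bursts, key=lambda e: e.start_s)
        if config.nibi_mode == "end_to_start":
            gaps = np.array([b.start_s - a.end_s for a, b in zip(nbs, nbs[1:])])
        else:
            gaps = np.array([b.start_s - a.start_s for a, b in zip(nbs, nbs[1:])])
        nibi = float(np.mean(gaps))
        cov = (float(np.std(gaps, ddof=1) / nibi)
               if gaps.size >= 2 and nibi > 0 else _nan())
    else:
        nibi, cov = _nan(), _nan()

    # (4) network burst characteristics
    nbd = (float(np.mean([e.duration_s for e in network_bursts]))
           if network_bursts else _nan())
    nrd = (float(np.mean([e.duration_s for e in network_reverberations]))
           if network_reverberations else _nan())
    nbc = (float(np.mean([len(e.children) for e in network_bursts]))
           if network_bursts else _nan())

    return WellMetrics(well_id=spike_trains.well_id, mfr_hz=mfr,
                       pct_random_spikes=pct_rs, nbr_per_min=nbr,
                       nibi_s=nibi, cov_nibi=cov, nbd_s=nbd,
                       net_reverb_dur_s=nrd, nbc=nbc)
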