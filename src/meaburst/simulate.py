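"""Synthetic multi-well MEA activity with exact ground truth.

Emulates mature hippocampal network dynamics on a 12-electrode well:
network bursts recur quasi-rhythmically (inter-burst quiescence drawn
from a Gamma distribution), each burst consists of one or more
*reverberations* — short high-frequency spike clusters — realized on
most channels with small onset jitter, and isolated noise spikes fall in
the quiet gaps. Every generated spike is placed on the 10-kHz sample
grid so binary occupancy arrays, rendered signal and spike-time lists
describe exactly the same events.

The generating MaxInterval parameters are the ground-truth "optimal"
parameters: spike placement keeps intra-reverberation ISIs at most 80%
of the start/end thresholds, inter-reverberation gaps and noise-spike
clearances at least 110% of the relevant thresholds, and durations and
counts above the minima, so the detector run with the generating
parameters reproduces the ground-truth reverberations exactly — the
synthetic analogue of an expert's optimal parameter choice.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .io import Recording, SpikeTrainSet, TrainingSample, WINDOW_LEN
from .maxinterval import (EventInterval, MaxIntervalParams, detect_reverberations,
                          merge_events)
from .network import (NetworkCriteria, active_channels,
                      detect_network_bursts, detect_network_reverberations)

#: default ranges the training-window parameters are drawn from (ms)
DEFAULT_PARAM_RANGES = {"max_start_ms": (8, 30),
                        "max_end_ms": (10, 40),
                        "min_between_ms": (15, 60)}

#: safety margins making the generating parameters comfortably optimal
ISI_MARGIN = 0.8        # intra-reverberation ISIs <= 0.8 * min(start, end)
GAP_MARGIN = 1.1        # gaps and clearances >= 1.1 * relevant thresholds


@dataclass(frozen=True)
class SimConfig:
    """Study conditions for the simulated wells (defaults are the
    package's reference conditions; see docs/methods.md for rationale)."""

    n_channels: int = 12
    duration_s: float = 600.0
    sampling_rate_hz: float = 10_000.0
    background_rate_hz: float = 0.1      # per channel, anywhere in time
    nibi_mean_s: float = 5.0             # Gamma quiescence between bursts
    nibi_shape: float = 16.0
    reverbs_per_burst_lambda: float = 2.0    # 1 + Poisson(lambda)
    intra_isi_mean_ms: float = 4.0
    reverb_gap_ms: tuple[float, float] = (40.0, 150.0)
    participation: float = 0.9
    jitter_sd_ms: float = 5.0
    spike_amp_uv: float = 40.0
    spike_amp_sd_uv: float = 8.0
    noise_sd_uv: float = 3.0
    noise_spike_rate_hz: float = 0.2     # isolated spikes in quiet gaps
    params: MaxIntervalParams = field(default_factory=MaxIntervalParams)
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.participation <= 1:
            raise ValueError("participation must be in [0, 1]")
        for name in ("duration_s", "sampling_rate_hz"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("background_rate_hz", "noise_spike_rate_hz",
                     "jitter_sd_ms", "noise_sd_uv", "spike_amp_sd_uv"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        lo, hi = self.reverb_gap_ms
        if not 0 < lo <= hi:
            raise ValueError("reverb_gap_ms must be an increasing positive range")
        p = self.params
        max_isi = ISI_MARGIN * min(p.max_start_ms, p.max_end_ms)
        if max_isi * self.sampling_rate_hz / 1e3 < 2:
            raise ValueError(
                "infeasible config: ISI budget below the sample grid "
                f"({max_isi:.2f} ms at {self.sampling_rate_hz:g} Hz)")


@dataclass
class GroundTruth:
    """Everything the generator knows about a simulated well."""

    reverberations: dict[str, list[EventInterval]]
    bursts: dict[str, list[EventInterval]]
    network_reverberations: list[EventInterval]
    network_bursts: list[EventInterval]
    params: MaxIntervalParams
    active: set[str]


# ---------------------------------------------------------------------------
# spike-pattern primitives (integer sample indices throughout)


def _reverb_pattern(rng: np.random.Generator, params: MaxIntervalParams,
                    rate: float, isi_mean_ms: float = 4.0) -> np.ndarray:
    """Spike offsets (samples, starting at 0) for one reverberation.

    ISIs are exponential with the configured mean, truncated into
    [1 ms, ISI_MARGIN * min(max_start, max_end)]; spikes are appended
    until both the minimum count and GAP_MARGIN times the minimum
    duration are exceeded, plus a couple of extras.
    """
    max_isi = int(np.floor(ISI_MARGIN * min(params.max_start_ms,
                                            params.max_end_ms) * rate / 1e3))
    min_isi = min(int(round(1e-3 * rate)), max_isi - 1)
    min_isi = max(min_isi, 1)
    min_dur = int(np.ceil(GAP_MARGIN * params.min_duration_ms * rate / 1e3))
    offsets = [0]
    scale = isi_mean_ms * rate / 1e3
    extra = int(rng.integers(0, 3))
    while (len(offsets) < params.min_spikes + extra
           or offsets[-1] < min_dur):
        isi = int(np.clip(round(rng.exponential(scale)), min_isi, max_isi))
        offsets.append(offsets[-1] + isi)
    return np.asarray(offsets, dtype=np.int64)


def _burst_template(rng: np.random.Generator, params: MaxIntervalParams,
                    gap_range_ms: tuple[float, float], rate: float,
                    n_reverbs: int, n_channels: int, participation: float,
                    jitter_sd_ms: float, isi_mean_ms: float = 4.0):
    """One network-burst realization across channels.

    Returns (per-channel list of reverberation offset arrays relative to
    the burst origin, total template length in samples). Participating
    channels share reverberation onsets up to one per-channel jitter.
    """
    # per-channel spike patterns for each reverberation
    patterns = [[_reverb_pattern(rng, params, rate, isi_mean_ms)
                 for _ in range(n_channels)]
                for _ in range(n_reverbs)]
    participates = rng.random(n_channels) < participation
    if not participates.any():
        participates[int(rng.integers(n_channels))] = True
    jitter = np.round(rng.normal(0.0, jitter_sd_ms * rate / 1e3,
                                 size=n_channels)).astype(np.int64)

    gap_lo = max(gap_range_ms[0],
                 GAP_MARGIN * max(params.max_start_ms, params.max_end_ms,
                                  params.min_between_ms))
    gap_span = gap_range_ms[1] - gap_range_ms[0]

    onsets = [0]
    for k in range(1, n_reverbs):
        longest = max(int(p[-1]) for p in patterns[k - 1])
        gap = int(np.ceil((gap_lo + rng.uniform(0, gap_span)) * rate / 1e3))
        onsets.append(onsets[k - 1] + longest + gap)

    per_channel: list[list[np.ndarray]] = [[] for _ in range(n_channels)]
    length = 0
    for c in range(n_channels):
        if not participates[c]:
            continue
        for k in range(n_reverbs):
            offs = onsets[k] + jitter[c] + patterns[k][c]
            per_channel[c].append(offs)
            length = max(length, int(offs[-1]))
    return per_channel, length


def _isolated_indices(rng: np.random.Generator, n_events: float,
                      duration_samples: int, occupied: np.ndarray,
                      clearance: int) -> np.ndarray:
    """Draw Poisson-many candidate indices and keep those at least
    ``clearance`` samples away from every occupied index and each other."""
    n = rng.poisson(n_events)
    if n == 0 or duration_samples <= 0:
        return np.empty(0, dtype=np.int64)
    cand = np.sort(rng.integers(0, duration_samples, size=n))
    kept: list[int] = []
    occupied = np.sort(occupied)
    for idx in cand:
        pos = np.searchsorted(occupied, idx)
        near = []
        if pos > 0:
            near.append(occupied[pos - 1])
        if pos < occupied.size:
            near.append(occupied[pos])
        if any(abs(idx - v) <= clearance for v in near):
            continue
        if kept and idx - kept[-1] <= clearance:
            continue
        kept.append(int(idx))
    return np.asarray(kept, dtype=np.int64)


# ---------------------------------------------------------------------------
# wells


def generate_well(config: SimConfig = SimConfig(),
                  well_id: str = "sim00") -> tuple[SpikeTrainSet, GroundTruth]:
    """Simulate one well and return its spike trains with ground truth.

    Network burst origins are spaced by Gamma-distributed quiescence;
    each burst carries ``1 + Poisson(lambda)`` reverberations realized on
    participating channels with per-channel onset jitter. Background
    Poisson spikes land anywhere; additional noise spikes are isolated
    (kept clear of reverberations by GAP_MARGIN times the ISI
    thresholds). Burst- and network-level ground truth is recomputed from
    the per-channel reverberations with the package's own merging and
    network rules, so there is a single source of truth. Fully
    reproducible from ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate_hz
    n_samples = int(round(config.duration_s * rate))
    params = config.params
    channels = [f"ch{i:02d}" for i in range(config.n_channels)]

    spikes: dict[str, list[np.ndarray]] = {ch: [] for ch in channels}
    gt_revs: dict[str, list[EventInterval]] = {ch: [] for ch in channels}

    # --- network bursts: Gamma quiescence precedes every burst
    t = int(round(1.0 * rate))  # settle-in second
    margin = int(round(0.5 * rate))
    while True:
        quiet = rng.gamma(config.nibi_shape,
                          config.nibi_mean_s / config.nibi_shape)
        if not np.isfinite(quiet) or t + quiet * rate >= n_samples:
            break
        t = t + int(round(quiet * rate))
        n_rev = 1 + int(rng.poisson(config.reverbs_per_burst_lambda))
        per_channel, length = _burst_template(
            rng, params, config.reverb_gap_ms, rate, n_rev,
            config.n_channels, config.participation, config.jitter_sd_ms,
            config.intra_isi_mean_ms)
        if t + length + margin >= n_samples:
            break
        for c, ch in enumerate(channels):
            for offs in per_channel[c]:
                idx = t + offs
                spikes[ch].append(idx)
                gt_revs[ch].append(EventInterval(
                    start_s=idx[0] / rate, end_s=idx[-1] / rate,
                    spike_count=idx.size, channel=ch))
        t = t + length

    # --- isolated noise spikes (clear of everything by the margin)
    clearance = int(np.ceil(GAP_MARGIN * max(params.max_start_ms,
                                             params.max_end_ms) * rate / 1e3))
    for ch in channels:
        occupied = (np.concatenate(spikes[ch]) if spikes[ch]
                    else np.empty(0, dtype=np.int64))
        noise = _isolated_indices(
            rng, config.noise_spike_rate_hz * config.duration_s,
            n_samples, occupied, clearance)
        if noise.size:
            spikes[ch].append(noise)
        # --- background Poisson spikes, anywhere
        n_bg = rng.poisson(config.background_rate_hz * config.duration_s)
        if n_bg:
            spikes[ch].append(rng.integers(0, n_samples, size=n_bg))

    trains = {}
    for ch in channels:
        idx = (np.unique(np.concatenate(spikes[ch])) if spikes[ch]
               else np.empty(0, dtype=np.int64))
        trains[ch] = idx / rate
    train_set = SpikeTrainSet(well_id=well_id, trains=trains,
                              duration_s=config.duration_s)

    # --- burst- and network-level ground truth, via the package's rules
    gt_bursts = {ch: merge_events(evs) if evs else []
                 for ch, evs in gt_revs.items()}
    criteria = NetworkCriteria()
    active = active_channels(train_set, config.duration_s, criteria)
    if active:
        net_rev = detect_network_reverberations(
            {ch: evs for ch, evs in gt_revs.items()
             if ch in active and evs}, active, criteria)
        net_bursts = detect_network_bursts(net_rev, criteria)
    else:
        net_rev, net_bursts = [], []

    return train_set, GroundTruth(
        reverberations=gt_revs, bursts=gt_bursts,
        network_reverberations=net_rev, network_bursts=net_bursts,
        params=params, active=active)


# ---------------------------------------------------------------------------
# signal rendering


def _spike_kernel(rate: float) -> np.ndarray:
    """Biphasic ~1 ms extracellular waveform, unit negative peak at its
    fourth sample (10 kHz reference shape, resampled for other rates)."""
    base = np.array([0.0, -0.25, -0.7, -1.0, -0.45, 0.2, 0.45, 0.3,
                     0.12, 0.04])
    if rate == 10_000.0:
        return base
    n = max(int(round(base.size * rate / 10_000.0)), 3)
    return np.interp(np.linspace(0, base.size - 1, n),
                     np.arange(base.size), base)


def render_signal(spike_trains: SpikeTrainSet, config: SimConfig = SimConfig()
                  ) -> Recording:
    """Render spike trains to a voltage trace: one biphasic ~1 ms
    waveform per spike with a per-spike amplitude draw, on Gaussian
    noise. Amplitudes are clipped from below so +-5 SD thresholding
    recovers the spikes. The waveform's extremum lands on the spike's
    sample."""
    rng = np.random.default_rng(config.seed + 1)
    rate = config.sampling_rate_hz
    duration = (config.duration_s if spike_trains.duration_s is None
                else spike_trains.duration_s)
    n = int(round(duration * rate))
    kernel = _spike_kernel(rate)
    peak = int(np.argmin(kernel))
    channels = spike_trains.channel_ids
    signal = np.zeros((len(channels), n), dtype=np.float32)
    if config.noise_sd_uv > 0:
        signal += rng.normal(0.0, config.noise_sd_uv,
                             size=signal.shape).astype(np.float32)
    floor_amp = 8.0 * config.noise_sd_uv
    for c, ch in enumerate(channels):
        idx = np.round(spike_trains.trains[ch] * rate).astype(np.int64)
        if idx.size == 0:
            continue
        amps = rng.normal(config.spike_amp_uv, config.spike_amp_sd_uv,
                          size=idx.size)
        amps = np.maximum(amps, floor_amp)
        for i, a in zip(idx, amps):
            lo = i - peak
            hi = lo + kernel.size
            klo, khi = max(0, -lo), kernel.size - max(0, hi - n)
            lo, hi = max(lo, 0), min(hi, n)
            if lo < hi:
                signal[c, lo:hi] += (a * kernel[klo:khi]).astype(np.float32)
    return Recording(well_id=spike_trains.well_id, channel_ids=list(channels),
                     signal=signal, sampling_rate_hz=rate)


# ---------------------------------------------------------------------------
# training windows


def _draw_params(rng: np.random.Generator, param_ranges: dict,
                 base: MaxIntervalParams) -> MaxIntervalParams:
    """Integer-ms draw of the three learnable parameters (the containers
    store whole milliseconds)."""
    def draw(key):
        lo, hi = param_ranges[key]
        return float(rng.integers(int(lo), int(hi) + 1))
    return replace(base, max_start_ms=draw("max_start_ms"),
                   max_end_ms=draw("max_end_ms"),
                   min_between_ms=draw("min_between_ms"))


def generate_training_window(rng: np.random.Generator,
                             params: MaxIntervalParams,
                             config: SimConfig) -> TrainingSample:
    """One single-channel 5-s window realizing ``params``: 2-4 bursts of
    reverberations whose structure makes the parameters optimal, isolated
    noise spikes in the quiescence, and the rendered signal."""
    rate = 10_000.0
    n = WINDOW_LEN
    margin = int(0.05 * rate)
    quiescence = (0.35, 0.9)  # s between bursts inside the window

    all_idx: list[np.ndarray] = []
    bursts = np.zeros(n, dtype=np.uint8)
    t = margin + int(rng.integers(0, int(0.15 * rate)))
    n_bursts = 0
    while True:
        n_rev = 1 + int(rng.poisson(1.5))
        if n_bursts == 0:
            n_rev = min(n_rev, 3)  # the first burst must always fit
        per_channel, length = _burst_template(
            rng, params, config.reverb_gap_ms, rate, n_rev,
            n_channels=1, participation=1.0, jitter_sd_ms=0.0,
            isi_mean_ms=config.intra_isi_mean_ms)
        if t + length + margin >= n or n_bursts >= 4:
            break
        for offs in per_channel[0]:
            idx = t + offs
            all_idx.append(idx)
            bursts[idx[0]:idx[-1] + 1] = 1
        n_bursts += 1
        t += length + int(rng.uniform(*quiescence) * rate)

    occupied = np.concatenate(all_idx) if all_idx else np.empty(0, np.int64)
    clearance = int(np.ceil(GAP_MARGIN * max(params.max_start_ms,
                                             params.max_end_ms) * rate / 1e3))
    noise = _isolated_indices(rng, config.noise_spike_rate_hz * 50.0,
                              n, occupied, clearance)

    spikes = np.zeros(n, dtype=np.uint8)
    idx = np.unique(np.concatenate([occupied, noise])) if (
        occupied.size or noise.size) else np.empty(0, np.int64)
    spikes[idx] = 1

    win_trains = SpikeTrainSet(well_id="window",
                               trains={"ch00": idx / rate}, duration_s=5.0)
    render_cfg = replace(config, seed=int(rng.integers(2 ** 31)))
    signal = render_signal(win_trains, render_cfg).signal[0]
    return TrainingSample(signal=signal, spikes=spikes, bursts=bursts,
                          params_ms=np.array([params.max_start_ms,
                                              params.max_end_ms,
                                              params.min_between_ms]))


def generate_training_dataset(n: int,
                              param_ranges: dict | None = None,
                              config: SimConfig = SimConfig(),
                              seed: int | None = None) -> list[TrainingSample]:
    """Generate ``n`` independent 5-s training windows whose generating
    parameters are drawn per window from ``param_ranges`` (whole ms).

    The bursts block is the binary occupancy of the window's
    ground-truth reverberations; the params block is the generating
    (start, end, between) triple — running the MaxInterval method with a
    window's own parameters on its own spikes reproduces its bursts
    block exactly.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    param_ranges = dict(DEFAULT_PARAM_RANGES if param_ranges is None
                        else param_ranges)
    rng = np.random.default_rng(config.seed if seed is None else seed)
    out = []
    for _ in range(n):
        params = _draw_params(rng, param_ranges, config.params)
        out.append(generate_training_window(rng, params, config))
    return out
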