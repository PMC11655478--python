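"""Baseline-noise estimation and threshold spike detection.

Baseline noise is taken as the mean and SD over two non-overlapping
200-ms segments without activity near the start of the analysis period;
"without activity" is operationalized as the two lowest-RMS windows
inside the search span. Spikes are voltage deflections exceeding
``threshold_sd`` (default 5) standard deviations from the baseline mean
in either polarity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps


class DegenerateBaselineError(ValueError):
    """Baseline SD is zero (flat signal) — thresholding is meaningless."""


@dataclass(frozen=True)
class SpikeDetectConfig:
    threshold_sd: float = 5.0
    refractory_ms: float = 1.0
    alignment: str = "extremum"          # or "crossing"
    search_span_s: float = 10.0          # quiet-segment search window
    segment_ms: float = 200.0
    apply_bandpass: bool = False         # mirror the acquisition chain

    def __post_init__(self) -> None:
        if self.threshold_sd <= 0:
            raise ValueError("threshold_sd must be positive")
        if self.refractory_ms <= 0:
            raise ValueError("refractory_ms must be positive")
        if self.alignment not in ("extremum", "crossing"):
            raise ValueError("alignment must be 'extremum' or 'crossing'")


@dataclass(frozen=True)
class BaselineEstimate:
    mean_uv: float
    sd_uv: float
    segment_starts_s: tuple[float, float]


def bandpass(channel_signal, sampling_rate_hz: float,
             high_pass_hz: float = 100.0,
             low_pass_hz: float = 3500.0) -> np.ndarray:
    """2nd-order high-pass + 4th-order low-pass, mirroring a typical MEA
    acquisition filter chain; for simulator-generated raw signal."""
    x = np.asarray(channel_signal, dtype=float)
    nyq = sampling_rate_hz / 2
    bh, ah = sps.butter(2, high_pass_hz / nyq, "highpass")
    bl, al = sps.butter(4, min(low_pass_hz / nyq, 0.99), "lowpass")
    return sps.filtfilt(bl, al, sps.filtfilt(bh, ah, x))


def estimate_baseline(channel_signal, sampling_rate_hz: float,
                      config: SpikeDetectConfig = SpikeDetectConfig()
                      ) -> BaselineEstimate:
    """Pick the two quietest non-overlapping 200-ms windows and estimate
    baseline mean/SD over their concatenation.

    Windows are ranked by root-mean-square amplitude inside the first
    ``config.search_span_s`` seconds (whole signal if shorter); the two
    lowest-RMS non-overlapping windows are chosen.
    """
    x = np.asarray(channel_signal, dtype=float)
    seg = int(round(config.segment_ms * 1e-3 * sampling_rate_hz))
    if x.size < 2 * seg:
        raise ValueError(
            f"signal too short for baseline estimation: need >= {2 * seg} "
            f"samples (2 x {config.segment_ms:g} ms), got {x.size}")
    span = min(x.size, int(round(config.search_span_s * sampling_rate_hz)))
    span = max(span, 2 * seg)
    y = x[:span]
    # RMS of every window starting on a half-segment grid
    step = max(seg // 2, 1)
    starts = np.arange(0, span - seg + 1, step)
    sq = np.concatenate([[0.0], np.cumsum(y * y)])
    rms = np.sqrt((sq[starts + seg] - sq[starts]) / seg)
    order = np.argsort(rms, kind="stable")
    first = starts[order[0]]
    second = None
    for k in order[1:]:
        if abs(int(starts[k]) - int(first)) >= seg:
            second = starts[k]
            break
    if second is None:  # cannot happen for span >= 2*seg, but be explicit
        raise ValueError("no two non-overlapping quiet segments found")
    chosen = np.concatenate([x[first:first + seg], x[second:second + seg]])
    sd = float(np.std(chosen))
    if sd == 0.0:
        raise DegenerateBaselineError(
            "baseline SD is zero; signal is flat in the quiet segments")
    a, b = sorted((first / sampling_rate_hz, second / sampling_rate_hz))
    return BaselineEstimate(mean_uv=float(np.mean(chosen)), sd_uv=sd,
                            segment_starts_s=(a, b))


def detect_spikes(channel_signal, sampling_rate_hz: float,
                  baseline: BaselineEstimate,
                  config: SpikeDetectConfig = SpikeDetectConfig(),
                  t0_s: float = 0.0) -> np.ndarray:
    """Detect spikes where |signal - baseline mean| exceeds
    ``threshold_sd * sd``.

    A spike is timestamped at the local extremum of the absolute
    deviation within 2 ms after the threshold crossing (or at the
    crossing itself with ``alignment='crossing'``); crossings within
    ``refractory_ms`` of the previous accepted crossing are suppressed.
    Returns strictly increasing times in seconds.
    """
    if baseline.sd_uv <= 0:
        raise DegenerateBaselineError("baseline SD must be positive")
    x = np.abs(np.asarray(channel_signal, dtype=float) - baseline.mean_uv)
    thr = config.threshold_sd * baseline.sd_uv
    above = x > thr
    crossings = np.flatnonzero(above & ~np.concatenate([[False], above[:-1]]))
    refractory = config.refractory_ms * 1e-3 * sampling_rate_hz
    align_span = int(round(2e-3 * sampling_rate_hz))

    times = []
    last = -np.inf
    for c in crossings:
        if c - last < refractory:
            continue
        last = c
        if config.alignment == "extremum":
            stop = min(c + align_span + 1, x.size)
            idx = c + int(np.argmax(x[c:stop]))
        else:
            idx = c
        times.append(t0_s + idx / sampling_rate_hz)
    out = np.asarray(times)
    if out.size > 1:  # extremum alignment could reorder; enforce invariant
        keep = np.concatenate([[True], np.diff(out) > 0])
        out = out[keep]
    return out
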