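"""MaxInterval reverberation detection and gap-based event merging.

The MaxInterval method classifies high-frequency spike clusters on a
single channel using five parameters: the maximum inter-spike interval
(ISI) allowed to start an event, the maximum ISI to extend it, the
minimum interval between events (closer events are merged), the minimum
event duration and the minimum spike count. In hippocampal cultures the
events this detects are *reverberations*; runs of reverberations whose
gaps are under 300 ms compose one *burst*.

Detection runs in three phases:

1. a candidate opens at spike ``i`` when ``ISI(i, i+1) <= max_start`` and
   extends while subsequent ISIs stay ``<= max_end`` (the opening pair is
   inside the event);
2. adjacent candidates separated by strictly less than ``min_between``
   are merged (gap measured next first-spike minus previous last-spike);
3. candidates shorter than ``min_duration`` or with fewer than
   ``min_spikes`` spikes are discarded.

Merge-then-filter is the default phase order; ``filter_first=True``
applies the duration/count filter before merging.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: hippocampal defaults: start/end/between/duration in ms, then spike count
HIPPOCAMPAL_DEFAULT = (15.0, 20.0, 25.0, 20.0, 5)
#: cortical variant: ISI thresholds at 100 ms, 200 ms between
CORTICAL_ISI100 = (100.0, 100.0, 200.0, 20.0, 5)

#: reverberation-to-burst (and network) merging gap, ms, strict <
BURST_MERGE_GAP_MS = 300.0


@dataclass(frozen=True)
class MaxIntervalParams:
    """The five MaxInterval parameters (ms except ``min_spikes``)."""

    max_start_ms: float = 15.0
    max_end_ms: float = 20.0
    min_between_ms: float = 25.0
    min_duration_ms: float = 20.0
    min_spikes: int = 5

    def __post_init__(self) -> None:
        for name in ("max_start_ms", "max_end_ms", "min_between_ms",
                     "min_duration_ms"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.min_spikes < 1:
            raise ValueError("min_spikes must be >= 1")

    @classmethod
    def preset(cls, name: str) -> "MaxIntervalParams":
        presets = {"hippocampal_default": HIPPOCAMPAL_DEFAULT,
                   "cortical_isi100": CORTICAL_ISI100}
        if name not in presets:
            raise KeyError(f"unknown preset {name!r}; "
                           f"have {sorted(presets)}")
        s, e, b, d, n = presets[name]
        return cls(s, e, b, d, n)

    def with_learned(self, params_ms) -> "MaxIntervalParams":
        """Replace the three learnable parameters (start, end, between)."""
        s, e, b = (float(v) for v in params_ms)
        return replace(self, max_start_ms=s, max_end_ms=e, min_between_ms=b)


@dataclass
class EventInterval:
    """A timed event: a reverberation, burst, or network-level event.

    ``[start_s, end_s)`` spans first to last member spike; ``children``
    are the constituent lower-level events (empty for reverberations).
    """

    start_s: float
    end_s: float
    spike_count: int
    channel: str | None = None
    children: list["EventInterval"] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.end_s < self.start_s:
            raise ValueError("end_s < start_s")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s

    def overlaps(self, other: "EventInterval") -> bool:
        return self.start_s < other.end_s and other.start_s < self.end_s


def detect_reverberations(spike_times_s, params: MaxIntervalParams,
                          channel: str | None = None,
                          filter_first: bool = False) -> list[EventInterval]:
    """Run the three-phase MaxInterval method on one channel's spike train.

    Parameters
    ----------
    spike_times_s
        Strictly increasing spike times, seconds.
    params
        The five detector parameters.
    channel
        Optional channel label copied onto the detected events.
    filter_first
        Apply the duration/spike-count filter before merging instead of
        after (both orders are in circulation; merge-then-filter is the
        convention followed here).

    Returns
    -------
    Ordered, disjoint `EventInterval` list with empty ``children``.
    """
    t = np.asarray(spike_times_s, dtype=float)
    if t.size and np.any(np.diff(t) <= 0):
        raise ValueError("spike times must be strictly increasing")
    max_start = params.max_start_ms / 1e3
    max_end = params.max_end_ms / 1e3
    min_between = params.min_between_ms / 1e3
    min_duration = params.min_duration_ms / 1e3

    # phase 1: candidates as (first_idx, last_idx) inclusive
    candidates: list[tuple[int, int]] = []
    i = 0
    n = t.size
    while i < n - 1:
        if t[i + 1] - t[i] <= max_start:
            j = i + 1
            while j < n - 1 and t[j + 1] - t[j] <= max_end:
                j += 1
            candidates.append((i, j))
            i = j + 1
        else:
            i += 1

    def _merge(cands):
        merged = []
        for c in cands:
            if merged and t[c[0]] - t[merged[-1][1]] < min_between:
                merged[-1] = (merged[-1][0], c[1])
            else:
                merged.append(list(c))
        return [tuple(c) for c in merged]

    def _filter(cands):
        return [(a, b) for a, b in cands
                if t[b] - t[a] >= min_duration
                and b - a + 1 >= params.min_spikes]

    if filter_first:
        candidates = _merge(_filter(candidates))
    else:
        candidates = _filter(_merge(candidates))

    return [EventInterval(start_s=float(t[a]), end_s=float(t[b]),
                          spike_count=b - a + 1, channel=channel)
            for a, b in candidates]


def merge_events(events: list[EventInterval],
                 max_gap_ms: float = BURST_MERGE_GAP_MS) -> list[EventInterval]:
    """Combine ordered events into parents when gaps are strictly under
    ``max_gap_ms``.

    Maximal runs whose successive gaps (next start minus previous end)
    are ``< max_gap_ms`` become one parent spanning the run, with the run
    members as children and spike counts summed. A single event becomes a
    parent with itself as only child. Re-merging the output changes no
    span or spike count (runs of parents are always singletons because
    surviving gaps are >= the threshold).
    """
    if max_gap_ms <= 0:
        raise ValueError("max_gap_ms must be positive")
    events = list(events)
    for prev, nxt in zip(events, events[1:]):
        if nxt.start_s < prev.end_s:
            raise ValueError("input events overlap or are unordered")
    max_gap = max_gap_ms / 1e3

    parents: list[EventInterval] = []
    run: list[EventInterval] = []

    def close(run):
        return EventInterval(
            start_s=run[0].start_s, end_s=run[-1].end_s,
            spike_count=sum(e.spike_count for e in run),
            channel=run[0].channel if len({e.channel for e in run}) == 1
            else None,
            children=list(run))

    for ev in events:
        if run and ev.start_s - run[-1].end_s < max_gap:
            run.append(ev)
        else:
            if run:
                parents.append(close(run))
            run = [ev]
    if run:
        parents.append(close(run))
    return parents
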