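"""Well-level network reverberation and network burst detection.

A network reverberation is synchronized reverberating activity: at least
two-thirds of the well's active channels contribute a reverberation to a
temporally connected cluster, and at least half of that required cohort
are reverberating at the same instant. Network reverberations closer
than 300 ms compose a network burst.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io import SpikeTrainSet
from .maxinterval import BURST_MERGE_GAP_MS, EventInterval, merge_events


@dataclass(frozen=True)
class NetworkCriteria:
    """Thresholds for accepting a synchronized cluster as a network event.

    ``participation_fraction`` of the active channels must contribute a
    reverberation; ``simultaneity_fraction`` of the required cohort
    (``simultaneity_base='required'``, the default) or of the actual
    participants (``'actual'``) must be reverberating concurrently.
    Channels with mean firing rate below ``active_mfr_hz`` are not
    counted as active.
    """

    participation_fraction: float = 2.0 / 3.0
    simultaneity_fraction: float = 0.5
    simultaneity_base: str = "required"
    active_mfr_hz: float = 0.1
    merge_gap_ms: float = BURST_MERGE_GAP_MS

    def __post_init__(self) -> None:
        for name in ("participation_fraction", "simultaneity_fraction"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.simultaneity_base not in ("required", "actual"):
            raise ValueError("simultaneity_base must be 'required' or 'actual'")
        if self.active_mfr_hz < 0:
            raise ValueError("active_mfr_hz must be >= 0")

    def participation_threshold(self, n_active: int) -> int:
        return math.ceil(self.participation_fraction * n_active)


def active_channels(spike_trains: SpikeTrainSet, duration_s: float,
                    criteria: NetworkCriteria = NetworkCriteria()
                    ) -> set[str]:
    """Channels whose mean firing rate is at least ``active_mfr_hz``.

    With a zero threshold, any channel with at least one spike counts.
    """
    if duration_s <= 0:
        raise ValueError("duration_s must be positive")
    out = set()
    for ch, t in spike_trains.trains.items():
        rate = t.size / duration_s
        if t.size and rate >= criteria.active_mfr_hz:
            out.add(ch)
    return out


def detect_network_reverberations(
        reverberations: dict[str, list[EventInterval]],
        active: set[str],
        criteria: NetworkCriteria = NetworkCriteria()
        ) -> list[EventInterval]:
    """Group overlapping active-channel reverberations into candidate
    clusters and keep those meeting the participation and simultaneity
    criteria.

    Candidates are connected components under temporal overlap (interval
    chaining, no fixed bins). A candidate with participants from ``k``
    distinct channels is accepted iff ``k >= ceil(pf * n_active)`` and the
    sweep-line maximum of concurrently open reverberations reaches
    ``ceil(sf * base)`` where ``base`` is the required cohort (default) or
    ``k``. The accepted event spans min child start to max child end and
    carries the member reverberations as children.
    """
    if not active:
        raise ValueError("active channel set is empty")
    extra = set(reverberations) - set(active)
    if extra:
        raise ValueError(
            f"reverberations supplied for non-active channels {sorted(extra)}")
    events = [ev for evs in reverberations.values() for ev in evs]
    if not events:
        return []
    events.sort(key=lambda e: (e.start_s, e.end_s))

    # connected components of temporal overlap via a running frontier;
    # strict < keeps half-open semantics (touching endpoints do not chain)
    components: list[list[EventInterval]] = []
    frontier = -np.inf
    for ev in events:
        if components and ev.start_s < frontier:
            components[-1].append(ev)
            frontier = max(frontier, ev.end_s)
        else:
            components.append([ev])
            frontier = ev.end_s

    need = criteria.participation_threshold(len(active))
    out: list[EventInterval] = []
    for comp in components:
        channels = {ev.channel for ev in comp}
        if len(channels) < need:
            continue
        base = need if criteria.simultaneity_base == "required" else len(channels)
        need_sim = math.ceil(criteria.simultaneity_fraction * base)
        # sweep line: max number of concurrently open reverberations
        bounds = sorted([(ev.start_s, 1) for ev in comp] +
                        [(ev.end_s, -1) for ev in comp],
                        key=lambda p: (p[0], p[1]))
        open_now = peak = 0
        for _, d in bounds:
            open_now += d
            peak = max(peak, open_now)
        if peak < need_sim:
            continue
        comp_sorted = sorted(comp, key=lambda e: (e.start_s, e.end_s))
        out.append(EventInterval(
            start_s=min(e.start_s for e in comp),
            end_s=max(e.end_s for e in comp),
            spike_count=sum(e.spike_count for e in comp),
            channel=None,
            children=comp_sorted))
    return out


def detect_network_bursts(network_reverberations: list[EventInterval],
                          criteria: NetworkCriteria = NetworkCriteria()
                          ) -> list[EventInterval]:
    """Merge network reverberations separated by < ``merge_gap_ms`` into
    network bursts (same rule as single-channel burst merging)."""
    return merge_events(network_reverberations, criteria.merge_gap_ms)
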