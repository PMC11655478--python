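"""Network reverberation / network burst criteria."""

import numpy as np
import pytest

from meaburst.io import SpikeTrainSet
from meaburst.maxinterval import EventInterval
from meaburst.network import (NetworkCriteria, active_channels,
                              detect_network_bursts,
                              detect_network_reverberations)

CRIT = NetworkCriteria()


def rev(start, end, channel, n=6):
    return EventInterval(start, end, n, channel=channel)


def channels(n):
    return [f"ch{i:02d}" for i in range(n)]


class TestActiveChannels:
    def test_silent_well_has_no_active_channels(self):
        trains = SpikeTrainSet("w", {c: np.empty(0) for c in channels(12)})
        assert active_channels(trains, 600.0, CRIT) == set()

    def test_rate_threshold_is_inclusive(self):
        # 60 spikes in 600 s is exactly 0.1 Hz
        trains = SpikeTrainSet("w", {"a": np.linspace(1, 599, 60),
                                     "b": np.linspace(1, 599, 59)})
        assert active_channels(trains, 600.0, CRIT) == {"a"}

    def test_zero_threshold_includes_any_spiking_channel(self):
        trains = SpikeTrainSet("w", {"a": np.array([1.0]), "b": np.empty(0)})
        crit = NetworkCriteria(active_mfr_hz=0.0)
        assert active_channels(trains, 600.0, crit) == {"a"}


class TestNetworkReverberations:
    def test_degenerate_single_channel_well_accepts_its_reverberation(self):
        evs = detect_network_reverberations(
            {"a": [rev(1.0, 1.1, "a")]}, {"a"}, CRIT)
        assert len(evs) == 1
        assert (evs[0].start_s, evs[0].end_s) == (1.0, 1.1)
        assert evs[0].channel is None

    def test_nine_of_twelve_overlapping_channels_accepted(self):
        active = set(channels(12))
        revs = {c: [rev(1.00, 1.10, c)] for c in channels(9)}
        evs = detect_network_reverberations(revs, active, CRIT)
        assert len(evs) == 1
        assert len(evs[0].children) == 9

    def test_five_of_twelve_rejected_by_participation(self):
        active = set(channels(12))
        revs = {c: [rev(1.00, 1.10, c)] for c in channels(5)}
        assert detect_network_reverberations(revs, active, CRIT) == []

    def test_participation_threshold_is_ceil_two_thirds(self):
        # 8 participants of 12 active: ceil(2/3 * 12) = 8 -> accepted
        active = set(channels(12))
        revs = {c: [rev(1.00, 1.10, c)] for c in channels(8)}
        assert len(detect_network_reverberations(revs, active, CRIT)) == 1
        revs7 = {c: [rev(1.00, 1.10, c)] for c in channels(7)}
        assert detect_network_reverberations(revs7, active, CRIT) == []

    def test_simultaneity_requires_concurrent_overlap(self):
        # 8 channels participate but intervals chain pairwise: at most 2
        # open at once < ceil(8/2) = 4 -> rejected
        active = set(channels(12))
        revs = {}
        for i, c in enumerate(channels(8)):
            start = 1.0 + 0.08 * i
            revs[c] = [rev(start, start + 0.1, c)]
        assert detect_network_reverberations(revs, active, CRIT) == []

    def test_simultaneity_base_actual_is_stricter_with_more_participants(self):
        # 12 of 12 participate, 5 concurrently open: required-base needs
        # ceil(8/2)=4 (accept), actual-base needs ceil(12/2)=6 (reject)
        active = set(channels(12))
        revs = {}
        for i, c in enumerate(channels(12)):
            start = 1.0 + 0.025 * i
            revs[c] = [rev(start, start + 0.12, c)]
        assert len(detect_network_reverberations(revs, active, CRIT)) == 1
        strict = NetworkCriteria(simultaneity_base="actual")
        assert detect_network_reverberations(revs, active, strict) == []

    def test_event_span_covers_all_children(self):
        active = set(channels(12))
        revs = {c: [rev(1.0 + 0.01 * i, 1.3 + 0.01 * i, c)]
                for i, c in enumerate(channels(10))}
        (ev,) = detect_network_reverberations(revs, active, CRIT)
        assert ev.start_s == min(c.start_s for c in ev.children)
        assert ev.end_s == max(c.end_s for c in ev.children)

    def test_reverberation_on_unknown_channel_rejected(self):
        with pytest.raises(ValueError, match="non-active"):
            detect_network_reverberations({"zz": [rev(0, 1, "zz")]},
                                          {"a"}, CRIT)

    def test_raising_participation_never_adds_events(self, small_well):
        _, _, truth = small_well
        revs = {ch: evs for ch, evs in truth.reverberations.items() if evs}
        active = truth.active
        counts = []
        for pf in (0.3, 0.5, 2 / 3, 0.8, 1.0):
            crit = NetworkCriteria(participation_fraction=pf)
            counts.append(len(detect_network_reverberations(
                {c: e for c, e in revs.items() if c in active},
                active, crit)))
        assert counts == sorted(counts, reverse=True)

    def test_every_event_meets_participation_postcondition(self, small_well):
        _, _, truth = small_well
        need = CRIT.participation_threshold(len(truth.active))
        for ev in truth.network_reverberations:
            assert len({c.channel for c in ev.children}) >= need


class TestNetworkBursts:
    def test_full_participation_low_jitter_count_is_exact(self):
        from meaburst.simulate import SimConfig, generate_well
        from meaburst.maxinterval import detect_reverberations

        config = SimConfig(seed=21, duration_s=120.0, participation=1.0,
                           jitter_sd_ms=3.0)
        trains, truth = generate_well(config)
        detected = {ch: detect_reverberations(t, config.params, channel=ch)
                    for ch, t in trains.trains.items()}
        active = truth.active
        net = detect_network_reverberations(
            {c: e for c, e in detected.items() if c in active and e},
            active, CRIT)
        bursts = detect_network_bursts(net, CRIT)
        assert len(bursts) == len(truth.network_bursts)

    def test_merge_rule_shared_with_single_channel_bursts(self):
        a = EventInterval(0.0, 0.1, 10, children=[rev(0.0, 0.1, "a")])
        b = EventInterval(0.25, 0.4, 12, children=[rev(0.25, 0.4, "a")])
        (nb,) = detect_network_bursts([a, b], CRIT)
        assert nb.children == [a, b]
        assert nb.spike_count == 22
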