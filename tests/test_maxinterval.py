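"""MaxInterval detector: hand-traced examples, a naive reference oracle,
and the structural properties of merging."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from meaburst.maxinterval import (CORTICAL_ISI100, EventInterval,
                                  MaxIntervalParams, detect_reverberations,
                                  merge_events)

DEFAULTS = MaxIntervalParams()


def naive_maxinterval(times_s, p: MaxIntervalParams):
    """Deliberately plain reference: greedy candidate scan, then repeated
    pairwise merging to a fixpoint, then filtering. Returns (first, last)
    index pairs."""
    t = list(times_s)
    s, e = p.max_start_ms / 1e3, p.max_end_ms / 1e3
    cands = []
    i = 0
    while i < len(t) - 1:
        if t[i + 1] - t[i] <= s:
            j = i + 1
            while j < len(t) - 1 and t[j + 1] - t[j] <= e:
                j += 1
            cands.append((i, j))
            i = j + 1
        else:
            i += 1
    changed = True
    while changed:
        changed = False
        for k in range(len(cands) - 1):
            if t[cands[k + 1][0]] - t[cands[k][1]] < p.min_between_ms / 1e3:
                cands[k:k + 2] = [(cands[k][0], cands[k + 1][1])]
                changed = True
                break
    return [(a, b) for a, b in cands
            if t[b] - t[a] >= p.min_duration_ms / 1e3
            and b - a + 1 >= p.min_spikes]


def ms(*values):
    return np.asarray(values, dtype=float) / 1e3


class TestHandTraces:
    def test_empty_train(self):
        assert detect_reverberations([], DEFAULTS) == []

    def test_five_regular_spikes_form_one_reverberation(self):
        evs = detect_reverberations(ms(0, 10, 20, 30, 40), DEFAULTS)
        assert len(evs) == 1
        assert evs[0].start_s == 0.0
        assert evs[0].end_s == pytest.approx(0.040)
        assert evs[0].spike_count == 5

    def test_30ms_gap_splits_into_two_reverberations(self):
        evs = detect_reverberations(
            ms(0, 10, 20, 30, 40, 70, 80, 90, 100, 110), DEFAULTS)
        assert [(e.start_s, e.end_s) for e in evs] == [
            (0.0, pytest.approx(0.040)),
            (pytest.approx(0.070), pytest.approx(0.110))]

    def test_three_spikes_fail_min_spikes(self):
        assert detect_reverberations(ms(0, 10, 20), DEFAULTS) == []

    def test_unsorted_input_rejected(self):
        with pytest.raises(ValueError, match="increasing"):
            detect_reverberations([0.1, 0.05], DEFAULTS)


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_reference_on_random_trains(self, seed):
        rng = np.random.default_rng(seed)
        for _ in range(100):
            n = int(rng.integers(0, 61))
            t = np.unique(np.round(rng.uniform(0, 2.0, size=n), 4))
            p = MaxIntervalParams(
                max_start_ms=float(rng.uniform(2, 60)),
                max_end_ms=float(rng.uniform(2, 60)),
                min_between_ms=float(rng.uniform(2, 120)),
                min_duration_ms=float(rng.uniform(1, 60)),
                min_spikes=int(rng.integers(1, 7)))
            got = [(e.start_s, e.end_s, e.spike_count)
                   for e in detect_reverberations(t, p)]
            want = [(t[a], t[b], b - a + 1)
                    for a, b in naive_maxinterval(t, p)]
            assert got == want


class TestMerging:
    def test_100ms_gap_merges_into_one_burst_with_children(self):
        a = EventInterval(0.0, 0.10, 5)
        b = EventInterval(0.20, 0.30, 6)
        merged = merge_events([a, b])
        assert len(merged) == 1
        assert (merged[0].start_s, merged[0].end_s) == (0.0, 0.30)
        assert merged[0].spike_count == 11
        assert len(merged[0].children) == 2

    def test_gap_of_exactly_300ms_does_not_merge(self):
        a = EventInterval(0.0, 0.10, 5)
        b = EventInterval(0.40, 0.50, 5)  # gap exactly 0.300
        assert len(merge_events([a, b])) == 2

    def test_gap_just_under_300ms_merges(self):
        a = EventInterval(0.0, 0.10, 5)
        b = EventInterval(0.399999, 0.50, 5)
        assert len(merge_events([a, b])) == 1

    def test_single_event_becomes_its_own_parent(self):
        a = EventInterval(0.1, 0.2, 5, channel="c")
        (parent,) = merge_events([a])
        assert (parent.start_s, parent.end_s, parent.spike_count) == \
            (0.1, 0.2, 5)
        assert parent.children == [a]

    def test_overlapping_inputs_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            merge_events([EventInterval(0, 0.5, 5),
                          EventInterval(0.4, 0.6, 5)])

    @given(st.lists(st.tuples(st.floats(0, 10), st.floats(0.001, 0.4)),
                    max_size=15))
    @settings(max_examples=50, deadline=None)
    def test_merging_is_idempotent_on_spans(self, raw):
        events, last_end = [], -1.0
        for start, dur in sorted(raw):
            if start <= last_end:
                continue
            events.append(EventInterval(start, start + dur, 5))
            last_end = start + dur
        once = merge_events(events)
        twice = merge_events(once)
        assert [(e.start_s, e.end_s, e.spike_count) for e in once] == \
            [(e.start_s, e.end_s, e.spike_count) for e in twice]


class TestProperties:
    @pytest.mark.parametrize("seed", range(3))
    def test_count_non_increasing_in_min_spikes(self, seed, rng):
        t = np.unique(np.round(np.random.default_rng(seed)
                               .uniform(0, 3.0, 200), 4))
        counts = [len(detect_reverberations(
            t, MaxIntervalParams(min_spikes=k))) for k in range(1, 10)]
        assert counts == sorted(counts, reverse=True)

    def test_spikes_inside_interval_belong_to_exactly_one_event(self, rng):
        t = np.unique(np.round(rng.uniform(0, 5.0, 400), 4))
        evs = detect_reverberations(t, DEFAULTS)
        for a, b in zip(evs, evs[1:]):
            assert a.end_s < b.start_s
        covered = sum(
            int(((t >= e.start_s) & (t <= e.end_s)).sum()) for e in evs)
        assert covered == sum(e.spike_count for e in evs)

    def test_cortical_variant_intervals_contain_default_intervals(self, rng):
        cortical = MaxIntervalParams(*CORTICAL_ISI100)
        for seed in range(5):
            t = np.unique(np.round(np.random.default_rng(seed)
                                   .uniform(0, 4.0, 300), 4))
            default_evs = detect_reverberations(t, DEFAULTS)
            cortical_evs = detect_reverberations(t, cortical)
            for d in default_evs:
                assert any(c.start_s <= d.start_s and d.end_s <= c.end_s
                           for c in cortical_evs)

    def test_filter_first_order_is_available_and_differs_when_it_should(self):
        # a 3-spike fragment 24 ms behind a full reverberation: merge-then-
        # filter keeps the union (8 spikes); filter-then-merge drops the
        # fragment first and keeps only the 5-spike event
        t = ms(0, 10, 20, 30, 40, 64, 74, 84)
        (merged_first,) = detect_reverberations(t, DEFAULTS)
        (filtered_first,) = detect_reverberations(t, DEFAULTS,
                                                  filter_first=True)
        assert merged_first.spike_count == 8
        assert filtered_first.spike_count == 5
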