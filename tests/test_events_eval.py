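"""Thresholding, event extraction, confusion metrics, error taxonomy."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scratchdetect.events_eval import (
    BinaryTrack,
    ConfusionMatrix,
    ErrorBreakdown,
    ProbabilityTrack,
    ScratchEvent,
    classify_errors,
    confusion,
    count_correlation,
    events_to_track,
    extract_events,
    grooming_confusion,
    match_durations,
    metrics,
    threshold_track,
)


def track(values, times=None, role="prediction"):
    values = np.asarray(values)
    if times is None:
        times = np.arange(len(values))
    return BinaryTrack(times, values, role)


# ---------------------------------------------------------------------------
# Brute-force oracles, independent of the implementation under test
# ---------------------------------------------------------------------------


def brute_events(values, times):
    runs = []
    for t, v in zip(times, values):
        if v and runs and runs[-1][1] == t - 1:
            runs[-1][1] = t
        elif v:
            runs.append([t, t])
    return [(s, e) for s, e in runs]


def brute_errors(pred_values, obs_values, times):
    pred_ev = brute_events(pred_values, times)
    obs_ev = brute_events(obs_values, times)
    lookup = dict(zip(times, zip(pred_values, obs_values)))

    def enclosing(events, t):
        return next((s, e) for s, e in events if s <= t <= e)

    def overlaps_any(ev, others):
        return any(ev[0] <= oe and os <= ev[1] for os, oe in others)

    boundary = false_det = oversight = 0
    for t in times:
        p, o = lookup[t]
        if p and not o:  # false positive
            if overlaps_any(enclosing(pred_ev, t), obs_ev):
                boundary += 1
            else:
                false_det += 1
        elif o and not p:  # false negative
            if overlaps_any(enclosing(obs_ev, t), pred_ev):
                boundary += 1
            else:
                oversight += 1
    return boundary, false_det, oversight


# ---------------------------------------------------------------------------


class TestThreshold:
    def test_strictly_more_than_cutoff(self):
        probs = ProbabilityTrack(np.arange(3), [0.6, 0.5, 0.499])
        np.testing.assert_array_equal(threshold_track(probs).values, [1, 0, 0])

    def test_low_probabilities_give_empty_track(self):
        probs = ProbabilityTrack(np.arange(5), np.full(5, 0.01))
        assert threshold_track(probs).values.sum() == 0

    def test_bad_cutoff_rejected(self):
        with pytest.raises(ValueError):
            threshold_track(ProbabilityTrack(np.arange(2), [0.1, 0.9]), cutoff=1.5)


class TestExtractEvents:
    def test_runs_and_their_lengths(self):
        events = extract_events(track([0, 0, 1, 1, 1, 0, 1, 0]))
        assert [(e.start_t, e.end_t, e.n_segments) for e in events] == [
            (2, 4, 3),
            (6, 6, 1),
        ]

    def test_all_zero_gives_no_events(self):
        assert extract_events(track([0] * 10)) == []

    def test_duration_at_60_fps(self):
        (ev,) = extract_events(track([1, 1, 1]), fps=60)
        assert ev.duration_s == pytest.approx(3 / 60)

    def test_time_gap_splits_a_run(self):
        t = track([1, 1, 1, 1], times=np.array([5, 6, 10, 11]))
        events = extract_events(t)
        assert [(e.start_t, e.end_t) for e in events] == [(5, 6), (10, 11)]

    def test_event_track_roundtrip_random(self, rng):
        for _ in range(300):
            values = (rng.random(rng.integers(1, 60)) < 0.4).astype(np.uint8)
            t = track(values)
            rebuilt = events_to_track(extract_events(t), t.times)
            np.testing.assert_array_equal(rebuilt.values, t.values)

    def test_matches_brute_force_runs(self, rng):
        for _ in range(200):
            values = (rng.random(50) < 0.5).astype(np.uint8)
            t = track(values)
            got = [(e.start_t, e.end_t) for e in extract_events(t)]
            assert got == brute_events(values, t.times)
            assert sum(e.n_segments for e in extract_events(t)) == values.sum()


class TestConfusion:
    def test_two_by_two_example(self):
        cm = confusion(track([1, 1, 0, 0]), track([1, 0, 1, 0], role="observation"))
        assert (cm.tp, cm.fp, cm.fn, cm.tn) == (1, 1, 1, 1)

    def test_identical_tracks_no_errors(self, rng):
        v = (rng.random(40) < 0.3).astype(np.uint8)
        cm = confusion(track(v), track(v, role="observation"))
        assert cm.fp == cm.fn == 0 and cm.total == 40

    def test_observed_positives_conserved(self, rng):
        p = (rng.random(60) < 0.4).astype(np.uint8)
        o = (rng.random(60) < 0.4).astype(np.uint8)
        cm = confusion(track(p), track(o, role="observation"))
        assert cm.tp + cm.fn == o.sum()

    def test_index_mismatch_errors(self):
        with pytest.raises(ValueError, match="mismatch"):
            confusion(track([1, 0]), track([1, 0], times=np.array([3, 4])))


class TestMetrics:
    def test_undefined_when_denominator_zero(self):
        ms = metrics(ConfusionMatrix(tp=0, fn=0, fp=3, tn=7))
        assert ms.sensitivity is None
        assert ms.specificity == pytest.approx(70.0)

    def test_perfect_prediction(self):
        ms = metrics(ConfusionMatrix(tp=5, fn=0, fp=0, tn=5))
        assert ms.sensitivity == ms.specificity == ms.ppv == ms.npv == 100.0


class TestClassifyErrors:
    def test_shifted_event_is_pure_boundary(self):
        times = np.arange(30)
        obs = np.zeros(30, np.uint8); obs[10:21] = 1   # observed 10-20
        pred = np.zeros(30, np.uint8); pred[12:24] = 1  # predicted 12-23
        errs = classify_errors(track(pred), track(obs, role="observation"))
        assert (errs.boundary, errs.false_detection, errs.oversight) == (5, 0, 0)

    def test_spurious_event_is_false_detection(self):
        pred = np.zeros(12, np.uint8); pred[5:9] = 1
        errs = classify_errors(track(pred), track(np.zeros(12, np.uint8), role="observation"))
        assert (errs.boundary, errs.false_detection, errs.oversight) == (0, 4, 0)

    def test_missed_event_is_oversight(self):
        obs = np.zeros(12, np.uint8); obs[5:9] = 1
        errs = classify_errors(track(np.zeros(12, np.uint8)), track(obs, role="observation"))
        assert (errs.boundary, errs.false_detection, errs.oversight) == (0, 0, 4)

    def test_conservation_and_oracle_on_random_pairs(self, rng):
        """boundary + false_detection + oversight == fp + fn, and the full
        taxonomy matches the brute-force event-scanning oracle."""
        for _ in range(400):
            n = int(rng.integers(1, 120))
            p = (rng.random(n) < rng.uniform(0.1, 0.6)).astype(np.uint8)
            o = (rng.random(n) < rng.uniform(0.1, 0.6)).astype(np.uint8)
            tp_, to_ = track(p), track(o, role="observation")
            errs = classify_errors(tp_, to_)
            cm = confusion(tp_, to_)
            assert errs.total == cm.fp + cm.fn
            assert (errs.boundary, errs.false_detection, errs.oversight) == \
                brute_errors(p, o, tp_.times)


class TestEventProperties:
    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(st.lists(st.integers(0, 1), min_size=1, max_size=80))
    def test_roundtrip_and_segment_conservation(self, values):
        """events -> track is the identity, and event segment counts sum to
        the number of positive segments, for every binary track."""
        t = track(values)
        events = extract_events(t)
        np.testing.assert_array_equal(
            events_to_track(events, t.times).values, t.values
        )
        assert sum(e.n_segments for e in events) == sum(values)

    @settings(derandomize=True, max_examples=200, deadline=None)
    @given(
        st.lists(st.integers(0, 1), min_size=1, max_size=60),
        st.data(),
    )
    def test_error_taxonomy_conserves_confusion_errors(self, pred_values, data):
        obs_values = data.draw(
            st.lists(st.integers(0, 1), min_size=len(pred_values), max_size=len(pred_values))
        )
        pt = track(pred_values)
        ot = track(obs_values, role="observation")
        errs = classify_errors(pt, ot)
        cm = confusion(pt, ot)
        assert errs.total == cm.fp + cm.fn


class TestCountsAndDurations:
    def test_identical_counts_correlate_perfectly(self):
        assert count_correlation([(3, 3), (7, 7), (1, 1)]) == pytest.approx(1.0)

    def test_linear_counts_correlate_perfectly(self):
        assert count_correlation([(1, 2), (2, 4), (3, 6)]) == pytest.approx(1.0)

    def test_independent_counts_near_zero(self, rng):
        pairs = list(zip(rng.integers(0, 50, 1000), rng.integers(0, 50, 1000)))
        assert abs(count_correlation(pairs)) < 0.1

    def test_zero_variance_undefined(self):
        assert count_correlation([(2, 1), (2, 5), (2, 9)]) is None

    def test_too_few_pairs_errors(self):
        with pytest.raises(ValueError):
            count_correlation([(1, 1), (2, 2)])

    def test_identical_event_lists_pair_equal(self):
        evs = [ScratchEvent(2, 5), ScratchEvent(9, 9)]
        pairs, unmatched = match_durations(evs, evs)
        assert all(a == b for a, b in pairs) and unmatched == []

    def test_fragmented_prediction_sums_durations(self):
        obs = [ScratchEvent(0, 99)]
        pred = [ScratchEvent(0, 9), ScratchEvent(20, 29),
                ScratchEvent(40, 49), ScratchEvent(60, 69)]
        pairs, unmatched = match_durations(pred, obs)
        assert pairs == [(100 / 60, 40 / 60)] and unmatched == []

    def test_unmatched_observed_pairs_with_zero(self):
        pairs, unmatched = match_durations([ScratchEvent(50, 59)], [ScratchEvent(0, 5)])
        assert pairs == [(6 / 60, 0.0)]
        assert [(e.start_t, e.end_t) for e in unmatched] == [(50, 59)]


class TestGrooming:
    @pytest.mark.parametrize(
        "pred,groom,expected",
        [
            ([0, 0, 0], [1, 1, 1], 0),
            ([1, 0, 1], [1, 1, 0], 1),
            ([1, 1, 0, 0], [0, 0, 1, 1], 0),
        ],
    )
    def test_grooming_confused_as_scratch_count(self, pred, groom, expected):
        assert grooming_confusion(track(pred), track(groom, role="grooming")) == expected
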