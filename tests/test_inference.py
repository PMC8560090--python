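"""Chunked inference and annotation generation from confidence tracks."""

import numpy as np
import pytest

from songseg import (
    ConfidenceTrack,
    Recording,
    build_network,
    detect_events,
    label_segments,
    majority_vote,
    predict_confidence,
    predictions_to_table,
    smooth_segments,
)

CLASSES3 = ["pulse", "sine", "no_song"]


def _track(values, rate=1000.0, names=CLASSES3):
    values = np.asarray(values, dtype=float)
    return ConfidenceTrack(values=values, rate=rate, class_names=names)


def _bump_track(centers, heights, n, rate=1000.0, width=5):
    y = np.zeros(n)
    for c, h in zip(centers, heights):
        i = np.arange(n)
        y = np.maximum(y, h * np.exp(-((i - c) ** 2) / (2 * width**2)))
    vals = np.stack([y, np.zeros(n), 1 - y], axis=1)
    return _track(vals, rate)


class TestPredictConfidence:
    def test_chunked_equals_whole(self, tiny_config, rng):
        net = build_network(tiny_config, rng=0)
        n = 8192
        rec = Recording(rng.standard_normal((n, 1)), tiny_config.rate)
        whole = predict_confidence(net, rec, chunk_samples=n)
        chunked = predict_confidence(net, rec, chunk_samples=1024)
        assert np.max(np.abs(whole.values - chunked.values)) < 1e-5

    def test_constant_input_constant_track(self, tiny_config):
        net = build_network(tiny_config, rng=1)
        rec = Recording(np.full((4096, 1), 0.25), tiny_config.rate)
        track = predict_confidence(net, rec)
        interior = track.values[500:-500]
        assert np.max(np.abs(interior - interior[0])) < 1e-9

    def test_rows_sum_to_one_and_full_coverage(self, tiny_frontend_config, rng):
        net = build_network(tiny_frontend_config, rng=0)
        n = 10_000  # not a stride multiple: exercises padding
        rec = Recording(rng.standard_normal((n, 1)), tiny_frontend_config.rate)
        track = predict_confidence(net, rec, chunk_samples=4096)
        assert track.values.shape == (n, 2)
        np.testing.assert_allclose(track.values.sum(axis=1), 1.0, atol=1e-9)

    def test_rate_mismatch_rejected(self, tiny_config):
        net = build_network(tiny_config, rng=0)
        with pytest.raises(ValueError, match="rate"):
            predict_confidence(net, Recording(np.zeros((4096, 1)), 44_100.0))

    def test_too_short_recording_rejected(self, tiny_config):
        net = build_network(tiny_config, rng=0)
        with pytest.raises(ValueError, match="receptive"):
            predict_confidence(net, Recording(np.zeros((16, 1)), tiny_config.rate))


class TestDetectEvents:
    def test_single_bump(self):
        track = _bump_track([500], [0.9], 1000)
        ev = detect_events(track, "pulse", threshold=0.7, min_distance_s=0.010)
        assert len(ev.times) == 1
        assert ev.times[0] == pytest.approx(0.5, abs=1e-3)

    def test_close_peaks_suppressed_keep_higher(self):
        track = _bump_track([500, 505], [0.8, 0.6], 1000, width=1.5)
        ev = detect_events(track, "pulse", threshold=0.5, min_distance_s=0.010)
        assert len(ev.times) == 1
        assert ev.confidences[0] == pytest.approx(0.8, abs=0.01)

    def test_below_threshold_no_events(self):
        track = _bump_track([300], [0.5], 1000)
        ev = detect_events(track, "pulse", threshold=0.7, min_distance_s=0.010)
        assert len(ev.times) == 0

    def test_matches_bruteforce_suppression_oracle(self, rng):
        """Greedy highest-first suppression equals a brute-force oracle."""
        for _ in range(50):
            n = 400
            centers = rng.choice(np.arange(20, 380), size=8, replace=False)
            heights = rng.uniform(0.3, 1.0, size=8)
            track = _bump_track(centers, heights, n, width=2)
            ev = detect_events(track, "pulse", threshold=0.4, min_distance_s=0.015)
            y = track.values[:, 0]
            # oracle: all local maxima above threshold, then greedy by height
            cand = [i for i in range(1, n - 1)
                    if y[i] > 0.4 and y[i] >= y[i - 1] and y[i] > y[i + 1]]
            kept = []
            for i in sorted(cand, key=lambda i: -y[i]):
                if all(abs(i - j) >= 15 for j in kept):
                    kept.append(i)
            assert sorted(kept) == [int(round(t * track.rate)) for t in ev.times]

    def test_appending_silence_leaves_events_unchanged(self):
        track = _bump_track([300, 600], [0.9, 0.85], 1000)
        vals = np.concatenate([track.values,
                               np.tile([0.0, 0.0, 1.0], (500, 1))])
        longer = _track(vals)
        a = detect_events(track, "pulse", 0.7, 0.010)
        b = detect_events(longer, "pulse", 0.7, 0.010)
        np.testing.assert_array_equal(a.times, b.times)

    def test_bad_threshold_rejected(self):
        track = _bump_track([300], [0.9], 1000)
        with pytest.raises(ValueError):
            detect_events(track, "pulse", threshold=1.5)


class TestLabelSegments:
    def test_one_hot_and_tie_rules(self):
        vals = np.array([[1.0, 0.0, 0.0],
                         [0.0, 0.0, 1.0],
                         [1 / 3, 1 / 3, 1 / 3]])
        labels = label_segments(_track(vals))
        assert labels.tolist() == [0, 2, 0]  # ties break to lowest index

    def test_matches_naive_rowwise_argmax(self, rng):
        vals = rng.dirichlet(np.ones(3), size=200)
        labels = label_segments(_track(vals))
        naive = [int(max(range(3), key=lambda c: row[c])) for row in vals]
        assert labels.tolist() == naive


class TestSmoothing:
    NO = 2

    def test_fill_short_gap_between_same_label(self):
        rate = 1000.0
        lab = np.full(100, self.NO)
        lab[10:40] = 1
        lab[48:80] = 1  # 8 ms gap
        seg = smooth_segments(lab, rate, CLASSES3, fill_gap_s=0.020, min_duration_s=0.0)
        assert len(seg.segments) == 1
        name, on, off = seg.segments[0]
        assert (name, on, off) == ("sine", 0.010, 0.080)

    def test_gap_between_different_labels_not_filled(self):
        rate = 1000.0
        lab = np.full(100, self.NO)
        lab[10:40] = 0
        lab[48:80] = 1
        seg = smooth_segments(lab, rate, CLASSES3, fill_gap_s=0.020, min_duration_s=0.0)
        assert len(seg.segments) == 2

    def test_short_run_removed(self):
        rate = 1000.0
        lab = np.full(100, self.NO)
        lab[50:53] = 1  # 3 ms
        seg = smooth_segments(lab, rate, CLASSES3, fill_gap_s=0.0, min_duration_s=0.020)
        assert seg.segments == []
        assert np.all(seg.labels == self.NO)

    def test_fill_happens_before_removal(self):
        """Two sub-minimum runs bridged by a short gap must survive as one
        segment (fill first), not be deleted (removal first)."""
        rate = 1000.0
        lab = np.full(100, self.NO)
        lab[10:25] = 1
        lab[30:45] = 1  # each 15 ms < min_duration 20 ms; gap 5 ms
        seg = smooth_segments(lab, rate, CLASSES3, fill_gap_s=0.010, min_duration_s=0.020)
        assert len(seg.segments) == 1

    def test_idempotent_on_random_tracks(self, rng):
        rate = 1000.0
        for _ in range(20):
            lab = rng.integers(0, 3, size=300)
            once = smooth_segments(lab, rate, CLASSES3, 0.008, 0.005)
            twice = smooth_segments(once.labels, rate, CLASSES3, 0.008, 0.005)
            np.testing.assert_array_equal(once.labels, twice.labels)
            assert once.segments == twice.segments


class TestMajorityVote:
    def test_mode_wins(self):
        rate = 1000.0
        raw = np.full(100, 2)
        raw[10:40] = 0
        raw[10 + 18 :40] = 1  # 18 of 30 samples class 0
        seg = smooth_segments(np.where(raw != 2, 1, 2), rate, CLASSES3, 0.0, 0.0)
        voted = majority_vote(raw, seg)
        assert voted.segments[0][0] == "pulse"

    def test_tie_breaks_to_earliest(self):
        rate = 1000.0
        raw = np.full(60, 2)
        raw[10:20] = 1
        raw[20:30] = 0  # 10 vs 10; class 1 occurs first
        seg = smooth_segments(np.where(raw != 2, 0, 2), rate, CLASSES3, 0.0, 0.0)
        voted = majority_vote(raw, seg)
        assert voted.segments[0][0] == "sine"

    def test_matches_counting_oracle(self, rng):
        rate = 1000.0
        for _ in range(20):
            raw = rng.integers(0, 3, size=200)
            base = smooth_segments(raw, rate, CLASSES3, 0.0, 0.0)
            voted = majority_vote(raw, base)
            for name, on, off in voted.segments:
                a, b = int(on * rate), int(off * rate)
                song = raw[a:b][raw[a:b] != 2]
                counts = {c: int(np.sum(song == c)) for c in set(song)}
                best = max(counts.values())
                assert counts[CLASSES3.index(name)] == best


def test_predictions_to_table_merges_events_and_segments():
    from songseg import EventPredictions, SegmentPredictions

    ev = EventPredictions("pulse", np.array([0.1, 0.2]), np.array([0.9, 0.8]))
    seg = SegmentPredictions([("sine", 0.3, 0.5)], np.array([]), 1000.0, CLASSES3)
    table = predictions_to_table([ev], seg)
    assert len(table) == 3
    assert set(table.names) == {"pulse", "sine"}
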