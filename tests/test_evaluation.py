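"""Event matching, derived metrics, confusion matrices, sequence error rate."""

import numpy as np
import pytest

from songseg import (
    event_metrics,
    match_events,
    pseudo_true_negatives,
    segment_confusion,
    sequence_error_rate,
    temporal_error,
)


class TestMatchEvents:
    def test_one_hit_one_miss_one_spurious(self):
        c = match_events([0.100, 0.200], [0.103, 0.400], tolerance=0.010)
        assert (c.tp, c.fp, c.fn) == (1, 1, 1)

    def test_nearest_prediction_wins_shared_true(self):
        c = match_events([0.100], [0.095, 0.104], tolerance=0.010)
        assert (c.tp, c.fp, c.fn) == (1, 1, 0)
        assert c.matched_pairs == [(0.100, 0.104)]  # distance 4 ms < 5 ms

    def test_displaced_prediction_rematched_to_free_true(self):
        # both predictions near the first true event; the farther one should
        # be re-matched to the second true event rather than counted FP
        c = match_events([0.100, 0.108], [0.099, 0.104], tolerance=0.010)
        assert (c.tp, c.fp, c.fn) == (2, 0, 0)

    def test_empty_predictions(self):
        c = match_events([0.1, 0.2, 0.3], [], tolerance=0.010)
        assert (c.tp, c.fp, c.fn) == (0, 0, 3)

    def test_count_identities_on_random_instances(self, rng):
        for _ in range(200):
            true = np.sort(rng.uniform(0, 1, size=rng.integers(0, 10)))
            pred = np.sort(rng.uniform(0, 1, size=rng.integers(0, 10)))
            c = match_events(true, pred, tolerance=0.02)
            assert c.tp + c.fn == len(true)
            assert c.tp + c.fp == len(pred)
            assert all(abs(t - p) <= 0.02 for t, p in c.matched_pairs)

    def test_zero_tolerance_rejected(self):
        with pytest.raises(ValueError):
            match_events([0.1], [0.1], tolerance=0.0)


class TestPseudoTrueNegatives:
    def test_formula(self):
        assert pseudo_true_negatives(1.0, 0.010, 10) == 40

    def test_clipped_at_zero(self):
        assert pseudo_true_negatives(1.0, 0.010, 100) == 0

    def test_single_window(self):
        assert pseudo_true_negatives(1.0, 0.5, 0) == 1


class TestEventMetrics:
    def test_precision_recall_f1(self):
        from songseg import EvalCounts

        rep = event_metrics(EvalCounts(tp=8, fp=2, fn=2))
        assert rep.precision == pytest.approx(0.8)
        assert rep.recall == pytest.approx(0.8)
        assert rep.f1 == pytest.approx(0.8)

    def test_perfect_counts(self):
        from songseg import EvalCounts

        rep = event_metrics(EvalCounts(tp=5, fp=0, fn=0, tn=3))
        assert (rep.precision, rep.recall, rep.f1, rep.accuracy) == (1, 1, 1, 1)

    def test_zero_over_zero_returns_zero_with_warning(self):
        from songseg import EvalCounts

        with pytest.warns(UserWarning):
            rep = event_metrics(EvalCounts())
        assert rep.precision == 0.0 and rep.f1 == 0.0

    def test_matches_independent_formulas_on_random_counts(self, rng):
        from songseg import EvalCounts

        for _ in range(100):
            tp, fp, fn, tn = (int(x) for x in rng.integers(1, 50, size=4))
            rep = event_metrics(EvalCounts(tp=tp, fp=fp, fn=fn, tn=tn))
            p, r = tp / (tp + fp), tp / (tp + fn)
            assert rep.precision == pytest.approx(p)
            assert rep.recall == pytest.approx(r)
            assert rep.f1 == pytest.approx(2 * p * r / (p + r))
            assert rep.accuracy == pytest.approx((tp + tn) / (tp + tn + fp + fn))


class TestTemporalError:
    def test_median_of_absolute_offsets(self):
        pairs = [(0.100, 0.099), (0.200, 0.200), (0.300, 0.303)]
        assert temporal_error(pairs) == pytest.approx(0.001)

    def test_perfect_matches(self):
        assert temporal_error([(0.1, 0.1), (0.2, 0.2)]) == 0.0

    def test_empty_is_nan(self):
        assert np.isnan(temporal_error([]))

    def test_matches_sorted_midpoint_oracle(self, rng):
        for _ in range(50):
            n = int(rng.integers(1, 20))
            true = rng.uniform(0, 10, n)
            pred = true + rng.normal(0, 0.005, n)
            med = temporal_error(list(zip(true, pred)))
            offs = sorted(abs(t - p) for t, p in zip(true, pred))
            mid = (offs[(n - 1) // 2] + offs[n // 2]) / 2
            assert med == pytest.approx(mid)


class TestSegmentConfusion:
    NAMES = ["a", "b", "no_song"]

    def test_identical_tracks_diagonal(self, rng):
        lab = rng.integers(0, 3, size=500)
        conf, rep = segment_confusion(lab, lab, self.NAMES)
        assert conf.sum() == 500
        assert np.all(conf == np.diag(np.diag(conf)))
        assert rep.accuracy == 1.0 and rep.f1 == 1.0

    def test_all_no_song_prediction_zero_recall(self):
        true = np.array([0, 0, 1, 1, 2, 2])
        pred = np.full(6, 2)
        with pytest.warns(UserWarning):
            conf, rep = segment_confusion(true, pred, self.NAMES)
        assert conf[:, 2].sum() == 6
        assert rep.recall == 0.0

    def test_sample_mode_matches_pairwise_counting_oracle(self, rng):
        true = rng.integers(0, 3, size=300)
        pred = rng.integers(0, 3, size=300)
        conf, _ = segment_confusion(true, pred, self.NAMES)
        for i in range(3):
            for j in range(3):
                assert conf[i, j] == int(np.sum((true == i) & (pred == j)))

    def test_syllable_mode_uses_label_modes(self):
        true = np.array([0] * 10 + [1] * 10 + [2] * 5)
        pred = np.array([0] * 6 + [1] * 4 + [1] * 10 + [2] * 5)
        conf, rep = segment_confusion(
            true, pred, self.NAMES, mode="syllable", segments=[(0, 10), (10, 20)]
        )
        assert conf[0, 0] == 1 and conf[1, 1] == 1
        assert rep.accuracy == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            segment_confusion(np.zeros(3, int), np.zeros(4, int), self.NAMES)


def _lev_recursive(a, b, memo=None):
    """Plain recursive definition of the edit distance (oracle)."""
    if memo is None:
        memo = {}
    key = (a, b)
    if key in memo:
        return memo[key]
    if not a:
        d = len(b)
    elif not b:
        d = len(a)
    else:
        d = min(
            _lev_recursive(a[1:], b, memo) + 1,
            _lev_recursive(a, b[1:], memo) + 1,
            _lev_recursive(a[1:], b[1:], memo) + (a[0] != b[0]),
        )
    memo[key] = d
    return d


class TestSequenceErrorRate:
    def test_identical_sequences(self):
        assert sequence_error_rate("ABC", "ABC") == 0.0

    def test_single_substitution(self):
        assert sequence_error_rate("ABC", "ABD") == pytest.approx(1 / 3)

    def test_all_deleted(self):
        assert sequence_error_rate("ABC", "") == 1.0

    def test_empty_true_rejected(self):
        with pytest.raises(ValueError):
            sequence_error_rate("", "A")

    def test_matches_recursive_oracle_short_strings(self):
        import itertools

        alphabet = "AB"
        strings = [
            "".join(s)
            for k in range(0, 4)
            for s in itertools.product(alphabet, repeat=k)
        ]
        for a in strings:
            if not a:
                continue
            for b in strings:
                assert sequence_error_rate(a, b) == _lev_recursive(a, b) / len(a)

    def test_matches_edlib_on_random_strings(self, rng):
        edlib = pytest.importorskip("edlib")
        for _ in range(100):
            a = "".join(rng.choice(list("ABC"), size=rng.integers(1, 15)))
            b = "".join(rng.choice(list("ABC"), size=rng.integers(0, 15)))
            d = edlib.align(b, a)["editDistance"]
            assert sequence_error_rate(a, b) == pytest.approx(d / len(a))

    def test_triangle_inequality(self, rng):
        for _ in range(50):
            a, b, c = (
                "".join(rng.choice(list("ABC"), size=rng.integers(1, 8)))
                for _ in range(3)
            )
            dab = sequence_error_rate(a, b) * len(a)
            dac = sequence_error_rate(a, c) * len(a)
            dcb = sequence_error_rate(c, b) * len(c)
            assert dab <= dac + dcb + 1e-12
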