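"""Score a jittered/corrupted annotation against its ground truth.

Simulates an annotator that misses some pulses, adds spurious ones and
jitters the rest, then reports tolerance-matched precision/recall/F1,
median temporal error and the syllable sequence error rate.
"""

import numpy as np

import songseg as ss

rng = np.random.default_rng(0)
true_times = np.cumsum(rng.uniform(0.035, 0.045, size=200))  # a long pulse train

# corrupt: drop 10%, jitter by 2 ms, add 5% spurious detections
keep = rng.uniform(size=len(true_times)) > 0.10
pred = true_times[keep] + rng.normal(0.0, 0.002, size=keep.sum())
spurious = rng.uniform(0, true_times[-1], size=10)
pred = np.sort(np.concatenate([pred, spurious]))

counts = ss.match_events(true_times, pred, tolerance=0.010)
report = ss.event_metrics(counts)
print(f"TP {counts.tp}  FP {counts.fp}  FN {counts.fn}")
print(f"precision {report.precision:.3f}  recall {report.recall:.3f}  "
      f"F1 {report.f1:.3f}")
print(f"median temporal error: {report.temporal_error_median * 1000:.2f} ms")

ser = ss.sequence_error_rate("ABCABCABD", "ABCABDABD")
print(f"sequence error rate ABCABCABD -> ABCABDABD: {ser:.3f} "
      "(edit distance over true length)")
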