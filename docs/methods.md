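# Methods

`songseg` annotates animal acoustic signals — fly pulse and sine song,
rodent ultrasonic vocalizations, marmoset calls, bird syllables — by
sequence labeling with a dilated temporal convolutional network (TCN).
This note documents the model, its training and inference procedures, the
numerical choices made where the design was open, what the synthetic-data
generator does and does not emulate, and known limitations.

## Model

The network maps raw audio `x(t, γ)` (time × channels, any rate from
~2 kHz to 300 kHz) to per-sample class probabilities `y_i(t)` over the song
types plus an implicit `no_song` class (always ordered last).

**Trainable STFT frontend (optional).** Two strided one-dimensional
convolution banks of shape `[T × pairs]` are initialized with the real and
imaginary parts of DFT kernels, `cos(2πfτ/T)` and `−sin(2πfτ/T)` for the
first `pairs` non-negative bins. Per frame `i` and filter `f` the output is
`log10(max(√(Re² + Im²), 1e−10))`; the floor is a numerical stabilizer the
plain formula lacks. The stride `s` downsamples time by `s`; the input is
right-padded by `T − s` zeros so the frame count is exactly `len/s`.
Defaults follow the mammal/bird configurations: 33 pairs, `T = 64`,
`s = 16`. The banks are trained together with the rest of the network.
A `power` flag switches to `log10(Re² + Im²)` for users who prefer the
power-spectrum convention; the magnitude form is the default.
The frontend is used in the mouse/marmoset/finch presets and omitted in the
fly presets, where downsampling costs temporal resolution on pulsatile
signals.

**TCN body.** A full network stacks 2–4 TCN blocks; each TCN block is a
stack of five residual blocks whose dilation doubles 1, 2, 4, 8, 16. A
residual block applies one dilated convolution
`y_i(t) = Σ_{τ,γ} k_i(τ, γ) x(t − aτ, γ)` (implemented as centered
cross-correlation with "same" zero padding — the standard deep-learning
orientation; kernels are learned so the flip is immaterial), a rectifier,
and a max-abs normalization `y / (max|y| + 1e−5)` taken per kernel channel.
The block output `z` is added to the block input (through a 1×1 projection
when the widths differ, i.e. in the first block) and also routed to a skip
path. The skip outputs of *all* residual blocks are summed and fed to a
single dense layer with softmax; when the frontend downsampled, the
confidences are restored to the audio rate by repeating each frame `s`
times. For multi-channel audio, designated TCN blocks use time–channel
separable convolutions: one shared temporal kernel per block applied to
every channel followed by `N` channel mixes (`τ + N·γ` parameters instead
of `τ·γ` per kernel).

**Normalization at inference.** The max-abs statistic is a global
(chunk-wide) quantity, so using it at inference would make the output
depend on how the audio is chunked. We therefore treat it like batch-norm
statistics: during training the per-chunk max is used and an exponential
moving average (momentum 0.1, initialized at 1) of the per-channel max is
tracked; at inference the frozen running statistic divides the activations.
This keeps inference purely convolutional, hence translation-covariant and
exactly chunk-size independent.

**Implementation.** The network, backpropagation and the Adam optimizer are
implemented directly in NumPy (float64). Convolutions are computed as `k`
shifted matrix products; gradients were validated against central finite
differences (max relative error ~1e−6 away from ReLU/argmax kinks).

## Structural presets

Shipped per-species presets (YAML, editable):

| preset | rate kHz | chunk | ch | STFT | separable | stacks | kernel size × count |
|---|---|---|---|---|---|---|---|
| fly_single | 10 | 4096 | 1 | – | – | 3 | 32 × 32 |
| fly_multi_pulse / _sine | 10 | 2048 | 9 | – | stacks 1–2 | 4 | 32 × 32 |
| mouse | 300 | 8192 | 1 | 16× | – | 2 | 16 × 32 |
| marmoset | 44.1 | 8192 | 1 | 16× | – | 2 | 16 × 32 |
| bengalese_finch | 32 | 1024 | 1 | 16× | – | 4 | 32 × 64 |
| zebra_finch | 32 | 2048 | 1 | 16× | – | 4 | 32 × 64 |

Each preset also carries post-processing defaults: event threshold 0.7
(single-channel fly) or 0.5, minimum peak distance 10 ms, gap-fill /
minimum-duration pairs of 20/20 ms (flies), 10/5 ms (mice), 5/30 ms
(marmosets and birds), and evaluation tolerances (10 ms for events and most
boundaries, 40 ms for sine-song and marmoset boundaries, which fade in and
out). Bird presets ship placeholder syllable vocabularies; real repertoires
are dataset-specific.

## Targets and training

Segments are encoded as binary vectors on `[start, stop)`. Events become
unit-peak Gaussian bumps (σ = 1.6 ms, truncated at ±4σ) to encode timing
uncertainty. For syllable-kind classes, a `no_song` gap of 6.25 ms (200
samples at 32 kHz) is carved between adjacent syllables so on/offsets are
unambiguous changes from `no_song` to song. The `no_song` row completes
each sample to 1; where song rows would exceed 1 (a bump overlapping a
segment of another type) the song rows are proportionally renormalized
first, so every row sums to exactly 1.

Training minimizes categorical cross-entropy with Adam (batch 32, learning
rate 1e−4 by default; the rate is exposed because no canonical value
exists). Chunks are drawn with seeded random offsets from the training
intervals so chunk boundaries do not align with annotation boundaries;
validation chunks tile their intervals deterministically and are evaluated
in inference mode. With a frontend, full-rate targets are mean-pooled to
the frame rate (mathematically identical to scoring the repeat-upsampled
output). Training stops after 400 epochs or when the validation loss has
not improved for 20 consecutive epochs, restoring the best-validation
weights. Optional inverse-frequency class weights exist behind a flag; no
reweighting is the default. Determinism contract: target encoding is fully
deterministic; training is reproducible under a fixed seed to the extent
the BLAS backend allows (in practice bit-stable on one thread).

Recordings are split 80:10:10 (60:20:20 selectable) into train/validation/
test; the validation and test blocks are contiguous and drawn, seeded, from
the first, middle or last portion of each recording (per-recording draws by
default; a shared draw is available since the choice mechanism is not
canonical).

## Inference

Audio is processed in overlapping chunks; each chunk's contaminated margins
— half a receptive field per side, rounded up to a frontend-stride multiple
— are discarded and the retained interiors concatenated, so chunked output
is *identical* (to float64 rounding) to processing the whole recording at
once. Preset chunk lengths can be shorter than a receptive field; the
inference chunk is then enlarged automatically (chunk length changes no
parameters). The receptive field is `1 + Σ (kernel − 1)·dilation` frames,
carried through the frontend stride and window when present.

Event times are local maxima of the event class's confidence above a
threshold, with greedy minimum-distance suppression (higher peaks kept
first). Plateaus — which repeat-upsampling can create — resolve to their
first sample; an optional quadratic interpolation flag refines peak times
below the stride resolution (off by default). Segment labels are the
per-sample argmax (ties break to the lowest class index; `no_song` is last,
so ties never silently favor it). The label track is then smoothed: gaps of
`no_song` shorter than the gap-fill are filled when flanked by the same
label, then runs shorter than the minimum duration are removed. These two
steps, in that order, are iterated to a fixpoint: a removal can expose a
new fillable gap, and the iteration (which terminates because re-opened
gaps only grow) makes smoothing idempotent without altering the first
fill-then-remove pass. Only `no_song` gaps are filled — a gap carrying a
different song label is left alone. Finally, segments are emitted at
`no_song`↔song transitions and multi-class syllables are labeled by the
mode of the per-sample song labels (ties break to the earliest-occurring
label).

## Evaluation

Predictions are matched to true events within a tolerance by a greedy pass
over candidate pairs in ascending distance: each true event accepts at most
one prediction, the closest of several candidates wins, displaced
predictions are re-matched to remaining true events, and leftovers are
false positives. (Matching runs prediction→true: that is the only
direction under which the de-duplication rule is well defined, and it is
oracle-tested against an optimal bipartite matcher.) Pseudo true
negatives —
`floor(duration / 2·tolerance) − n_true`, clipped at 0 — only complete
confusion matrices. Precision `TP/(TP+FP)`, recall `TP/(TP+FN)`,
`F1 = 2PR/(P+R)` (the harmonic-mean formula; 0/0 conventions return 0 with
a warning), accuracy `(TP+TN)/(TP+TN+FP+FN)`. Temporal precision is the
median absolute distance between matched events. Segment annotations are
compared per sample or per detected syllable (mode of true vs predicted
labels; the reference direction is selectable). The sequence error rate is
the Levenshtein distance between label sequences normalized by the true
length.

SNR estimators (all gain-invariant; RMS is `√mean(x²)`):

* **pulse** — 20 ms windows centered on the pulse-energy peak;
  SNR = RMS(center 7.5–12.5 ms) / RMS(first+last 5 ms); multi-channel uses
  the channel with the highest center RMS;
* **sine** — RMS inside the segment over RMS of the 200 ms flanks (10 ms
  buffer), excluding annotated song samples (pulse events by a ±5 ms
  window, so inter-pulse intervals stay in the noise estimate);
* **mouse** — additive-noise model on 1 ms windows:
  `SNR(t) = max(σ²_total(t) − floor, 0)/floor` with the noise floor a low
  percentile (default 10th, exposed) of the windowed power, since no
  explicit floor estimator is canonical.

## Unsupervised repertoire classification

Pulse/sine waveforms (15 ms windows — distinct from the 20 ms SNR window;
both are kept as separate, documented constants) are peak-energy aligned,
unit-normalized and sign-adjusted. Syllables become preprocessed mel
spectrograms: per-band division by the frequency-specific noise floor (the
band's median over time), log, subtract-threshold-and-clip at 0 (threshold
0 for mouse-like, 2 for marmoset/bird-like material), log time-resizing
(new width `max(1, round(ln(W)·8))`, linear interpolation, which
compresses duration differences between syllables),
zero-padding to the longest item, and optionally retaining only the 40
bands around each item's peak frequency (clamped and zero-padded at band
edges). Mel parameters (64 bands, window 1024, hop 128) are exposed;
short syllables at low rates need a proportionally finer grid (the examples use window 256, hop 32 at 8 kHz). Features are
embedded in 2-D with UMAP (min_dist 0.5; 0.1 improves separation for
marmoset-like material; n_neighbors defaults to 15, with ~30 appropriate
for a few hundred items) and clustered either with HDBSCAN
(min_samples 10, min_cluster_size 20; −1 marks noise points) or, for
repertoires without density structure, k-means with 40 groups. Agreement
with manual labels is scored by homogeneity `1 − H(manual|cluster)/H(manual)`,
completeness `1 − H(cluster|manual)/H(cluster)` and their harmonic mean
(v-measure), implemented from the contingency-table entropies (degenerate
single-class partitions score 1).

## Synthetic data

The generator emulates the *statistics* of the signals, not their acoustics:

* pulse trains of Gaussian-windowed cosines (an analytic stand-in for the
  biphasic pulses; the envelope peak is the annotated event time), carrier
  180–500 Hz, duration 5–10 ms, inter-pulse interval 35–45 ms;
* sine song at 150 Hz with cosine ramps;
* harmonic syllables with piecewise-linear frequency contours; each
  rendered instance jitters duration (±10%) and pitch (±5%), since natural
  syllables vary continuously — without this, instances are near-identical
  and density clustering fragments on discretization artifacts;
* Gaussian background noise of controllable RMS, pulsatile noise (isolated
  single-cycle clicks at Poisson times, exercising the false-positive
  pathway), and per-channel gain projection for multi-channel fixtures.

Identical seeds give bit-identical output, annotations never extend beyond
the audio, and labeled segments of different types may not overlap.

What passing tests on this material show — and what they do not: the
pipeline recovers signals whose generative statistics match the training
material at controlled SNR. Real recordings add reverberation, nonstation-
ary noise, animal-to-animal variability and annotation error, none of
which the generator models; performance numbers on synthetic corpora are
therefore upper bounds, not predictions for real data.

## Problem sizes for the recovery studies

The supervised recovery study trains the reduced fly network (2 TCN stacks,
16 filters of 16 samples, no frontend, ~37k parameters) on a 5.5-minute
fly-like corpus at a 2 kHz sample rate — all carriers (≤350 Hz pulse,
150 Hz sine) sit well below Nyquist, and the rate keeps the NumPy training
loop at desk scale — with learning rate 1e−3 for 8 epochs, an 80:10:10
split, and scoring on the held-out test block (events: threshold 0.7,
10 ms minimum distance, 10 ms tolerance; sine: sample-wise). A noise sweep
re-noises the held-out audio at increasing RMS (0.02, 0.3, 0.6 against
unit pulse amplitude) and tracks event recall. The unsupervised study uses
450 syllables (three templates × 150) at 8 kHz.

## Known limitations

* No GPU path; training cost grows linearly with sample rate and network
  width, so full-size presets on hours of high-rate audio are outside this
  implementation's comfortable range.
* Overlapping song from multiple animals is not modeled (annotations are
  mutually exclusive by design).
* No streaming/real-time inference; the chunked API is offline-first.
* Bird-audio denoising is a pluggable pre-step and intentionally not
  bundled.
* Checkpoints store weights as NumPy archives next to a YAML config; no
  cross-framework exchange format.
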