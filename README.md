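# songseg

Sample-accurate annotation of animal acoustic signals — fly pulse and sine
song, rodent ultrasonic vocalizations, marmoset calls, bird syllables —
with dilated temporal convolutional networks, plus the surrounding
toolchain a bioacoustics lab needs: sample-wise target encoding, training
with early stopping, chunked inference with exact edge handling,
tolerance-matched event metrics, signal-to-noise estimation, and
unsupervised repertoire classification. A seeded synthetic-song generator
makes every stage testable without recordings.

## Who this is for

Researchers who have audio plus sparse manual annotations (event times for
pulse-like signals, on/offsets for syllable-like signals) and want
sample-accurate automatic annotation of the rest, or want to discover a
vocal repertoire's types without labels.

## The model

A network maps raw audio `x(t, γ)` to per-sample class confidences
`y_i(t)` (softmax over song types plus `no_song`):

* an optional **trainable STFT frontend** — strided convolution banks
  initialized with DFT kernels, output
  `log10 √(Re x(i,f)² + Im x(i,f)²)`, downsampling time by the stride
  `s` (33 filter pairs, `T = 64`, `s = 16` by default);
* **TCN blocks** — stacks of five residual blocks of dilated convolutions
  `y_i(t) = Σ_{τ,γ} k_i(τ,γ) x(t − aτ, γ)` with dilation `a` doubling
  1→16, each block: conv → ReLU → max-abs normalization
  `y/(max|y| + 10⁻⁵)` → residual add; time–channel *separable*
  convolutions (`τ + N·γ` parameters) for multi-channel audio;
* a **skip-sum head** — all residual-block outputs summed, one dense layer
  + softmax, repeat-upsampling back to the audio rate.

Event times are then confidence peaks (threshold + minimum distance);
segments come from the argmax label track after gap-filling and
minimum-duration smoothing with majority-vote labels. Evaluation matches
events within a tolerance (10 ms default) and reports precision, recall,
`F1 = 2PR/(P+R)`, median temporal error, confusion matrices and the
normalized Levenshtein sequence error rate.

The network, backpropagation and Adam are implemented in NumPy — no deep
learning framework required. Structural presets for the tested species
(`fly_single`, `fly_multi_pulse`, `fly_multi_sine`, `mouse`, `marmoset`,
`bengalese_finch`, `zebra_finch`) ship as editable YAML. See
`docs/methods.md` for the full model description and design choices.

## Worked example

Train a reduced network on 5.5 minutes of synthetic fly song and annotate
the held-out split (a few minutes on one CPU):

```sh
$ python examples/train_and_annotate.py
pulse events:  precision 1.000, recall 1.000, F1 1.000
temporal error (median): 0.44 ms
sine segments: sample-wise F1 0.999
recall vs added noise RMS [0.02, 0.3, 0.6]: [1.0, 0.07, 0.0]
F1 near 1 means the network recovered the song statistics it was trained
on; recall should fall as noise drowns the pulses.
```

The network recovers every held-out pulse to sub-millisecond precision and
the sine-song boundaries almost exactly; event recall collapses once the
added noise approaches the pulse amplitude, as expected for a network
trained at high SNR.

Other runnable walkthroughs in `examples/`: SNR estimation
(`simulate_and_estimate_snr.py`), annotation scoring
(`evaluate_annotations.py`) and unsupervised repertoire discovery
(`cluster_repertoire.py`, which re-finds three syllable types with
v-measure 1.0). A thin CLI covers the same pipeline from the shell:

```sh
songseg simulate --kind fly --duration 60 --out data/
songseg train --audio data/audio.wav --annotations data/annotations.csv \
    --preset fly_single --out run/
songseg predict --model run/model --audio data/audio.wav --out pred.csv
songseg evaluate --true data/annotations.csv --pred pred.csv
songseg cluster --audio data/audio.wav --annotations pred.csv --out clusters.csv
```

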