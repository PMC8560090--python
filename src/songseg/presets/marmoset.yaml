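# Marmoset calls; the class vocabulary is dataset-specific, these four are
# common call types. 40 ms boundary tolerance (calls fade in and out).
name: marmoset
rate: 44100.0
chunk_samples: 8192
channels: 1
use_stft: true
stft_pairs: 33
stft_duration_T: 64
stft_stride_s: 16
kernel_count: 32
kernel_size: 16
tcn_blocks: 2
residual_blocks_per_tcn: 5
dilation_base: 2
separable_blocks: []
classes:
  - {name: tsik, kind: syllable}
  - {name: ekk, kind: syllable}
  - {name: phee, kind: syllable}
  - {name: trill, kind: syllable}
postprocessing:
  event_threshold: 0.5
  event_min_distance_s: 0.010
  fill_gap_s: 0.005
  min_duration_s: 0.030
  event_tolerance_s: 0.040
  segment_boundary_tolerance_s: 0.040
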