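# Bengalese finch song; real repertoires have ~50 syllable types, the class
# list is a placeholder to be replaced per dataset.
name: bengalese_finch
rate: 32000.0
chunk_samples: 1024
channels: 1
use_stft: true
stft_pairs: 33
stft_duration_T: 64
stft_stride_s: 16
kernel_count: 64
kernel_size: 32
tcn_blocks: 4
residual_blocks_per_tcn: 5
dilation_base: 2
separable_blocks: []
classes:
  - {name: syll_a, kind: syllable}
  - {name: syll_b, kind: syllable}
  - {name: syll_c, kind: syllable}
  - {name: syll_d, kind: syllable}
  - {name: syll_e, kind: syllable}
  - {name: syll_f, kind: syllable}
postprocessing:
  event_threshold: 0.5
  event_min_distance_s: 0.010
  fill_gap_s: 0.005
  min_duration_s: 0.030
  event_tolerance_s: 0.010
  segment_boundary_tolerance_s: 0.010
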