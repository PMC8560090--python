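name: fly_multi_sine
rate: 10000.0
chunk_samples: 2048
channels: 9
use_stft: false
stft_pairs: 33
stft_duration_T: 64
stft_stride_s: 16
kernel_count: 32
kernel_size: 32
tcn_blocks: 4
residual_blocks_per_tcn: 5
dilation_base: 2
separable_blocks: [0, 1]
classes:
  - {name: sine, kind: segment}
postprocessing:
  event_threshold: 0.5
  event_min_distance_s: 0.010
  fill_gap_s: 0.020
  min_duration_s: 0.020
  event_tolerance_s: 0.010
  segment_boundary_tolerance_s: 0.040
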