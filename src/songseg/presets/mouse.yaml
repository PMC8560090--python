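# Mouse ultrasonic vocalizations: 300 kHz audio through a 16x-downsampling
# trainable STFT frontend (33 pairs, T=64, s=16).
name: mouse
rate: 300000.0
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
  - {name: usv, kind: segment}
postprocessing:
  event_threshold: 0.5
  event_min_distance_s: 0.010
  fill_gap_s: 0.010
  min_duration_s: 0.005
  event_tolerance_s: 0.010
  segment_boundary_tolerance_s: 0.010
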