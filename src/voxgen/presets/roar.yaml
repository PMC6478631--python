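# aggressive roar: low pitch, rich harmonics, pervasive subharmonics+chaos
f0_anchors:
- [0.0, 120.0]
- [0.4, 180.0]
- [1.0, 110.0]
bout:
  n_syllables: 1
  syllable_ms: 1200.0
mouth:
- [0.0, 0.5]
- [0.4, 0.95]
- [1.0, 0.4]
source:
  rolloff: 6.0
  jitter_depth: 0.3
  jitter_period: 0.012
  shimmer_depth: 0.1
  attack_len: 0.08
  sub_ratio: 2
  sub_depth: 8.0
  chaos_jitter: 1.8
  chaos_shimmer: 0.3
nonlinear_balance: 0.75
noise:
  envelope_db: -20.0
  rolloff_noise: -3.0
formants:
- freq: 550.0
- freq: 1100.0
- freq: 1900.0
- freq: 3100.0
tract:
  vtl: 19.0
temperature: 0.05
seed: 41
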