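# high-arousal scream: very high pitch, harsh nonlinear regimes
f0_anchors:
- [0.0, 900.0]
- [0.3, 1400.0]
- [0.8, 1200.0]
- [1.0, 800.0]
bout:
  n_syllables: 1
  syllable_ms: 900.0
mouth: 0.85
source:
  rolloff: 7.0
  jitter_depth: 0.4
  jitter_period: 0.008
  shimmer_depth: 0.12
  attack_len: 0.02
  sub_ratio: 2
  sub_depth: 10.0
  chaos_jitter: 1.5
  chaos_shimmer: 0.25
nonlinear_balance: 0.6
noise:
  envelope_db: -24.0
  rolloff_noise: -4.0
formants:
- freq: 900.0
- freq: 1700.0
- freq: 3200.0
tract:
  vtl: 14.0
temperature: 0.05
seed: 23
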