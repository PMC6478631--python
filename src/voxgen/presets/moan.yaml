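# breathy low moan: falling pitch, relaxed open vowel, audible aspiration
f0_anchors:
- [0.0, 180.0]
- [0.3, 220.0]
- [1.0, 120.0]
bout:
  n_syllables: 1
  syllable_ms: 600.0
mouth:
- [0.0, 0.4]
- [0.5, 0.6]
- [1.0, 0.35]
source:
  rolloff: 14.0
  vibrato_depth: 0.2
  vibrato_freq: 5.0
  jitter_depth: 0.08
  shimmer_depth: 0.05
  attack_len: 0.05
noise:
  envelope_db:
  - [0.0, -22.0]
  - [1.0, -16.0]
  rolloff_noise: -8.0
formants:
- freq: 630.0
- freq: 1100.0
- freq: 2500.0
tract:
  vtl: 15.5
temperature: 0.05
seed: 11
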