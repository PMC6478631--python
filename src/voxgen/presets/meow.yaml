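# cat-like meow: short vocal tract, gliding pitch, mouth opens then closes
f0_anchors:
- [0.0, 480.0]
- [0.25, 700.0]
- [0.8, 550.0]
- [1.0, 380.0]
bout:
  n_syllables: 1
  syllable_ms: 700.0
mouth:
- [0.0, 0.15]
- [0.3, 0.9]
- [1.0, 0.12]
source:
  rolloff: 9.0
  vibrato_depth: 0.3
  vibrato_freq: 6.0
  jitter_depth: 0.1
  shimmer_depth: 0.06
  attack_len: 0.04
noise:
  envelope_db: -30.0
  rolloff_noise: -10.0
formants:
- freq: 1100.0
- freq: 3300.0
tract:
  vtl: 8.0
  lip_radiation: 6.0
temperature: 0.05
seed: 53
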