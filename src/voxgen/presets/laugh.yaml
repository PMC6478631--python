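# voiced laugh bout: short repeated ha-syllables with strong aspiration
f0_anchors:
- [0.0, 320.0]
- [0.5, 280.0]
- [1.0, 230.0]
bout:
  n_syllables: 5
  syllable_ms:
  - [0.0, 140.0]
  - [1.0, 100.0]
  pause_ms: 130.0
mouth: 0.7
source:
  rolloff: 12.0
  jitter_depth: 0.15
  shimmer_depth: 0.08
  attack_len: 0.02
noise:
  envelope_db:
  - [0.0, -12.0]
  - [1.0, -20.0]
  rolloff_noise: -6.0
formants:
- freq: 800.0
- freq: 1250.0
- freq: 2700.0
tract:
  vtl: 14.5
temperature: 0.08
seed: 37
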