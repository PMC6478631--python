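# voxgen

Parametric synthesis of **nonverbal vocalizations** — moans, screams,
laughs, roars, and animal calls — from a handful of acoustically
meaningful control parameters. `voxgen` is a source–filter vocoder
aimed at bioacousticians and voice researchers who need precisely
controlled, natural-sounding stimuli for perceptual experiments (e.g.
manipulating one acoustic feature at a time, or morphing between two
calls) rather than text-to-speech output.

## The model

A vocalization is a bout of syllables. For each syllable:

1. **Voiced source.** Instead of modeling glottal pulses in the time
   domain, each harmonic *h* is synthesized directly as a sine with
   time-varying frequency *h·f0(t)* and zero initial phase:

   *w_h(t) = a_h(t) · sin(2π · h/s · Σ₁ᵗ f0(τ))*,

   summed over all harmonics below the Nyquist frequency *s/2*.
   Harmonic strength falls by `rolloff` dB per octave. The f0 contour
   is interpolated through sparse anchors and modulated by vibrato
   (sinusoidal) and jitter (seeded smooth noise in semitones); shimmer
   perturbs amplitude per glottal cycle. Nonlinear vocal phenomena are
   first-class: **subharmonics** add a second fundamental *g0 = f0/k*
   (sidebands between harmonics), and **deterministic chaos** is
   simulated as strong jitter plus shimmer; a bounded random walk
   switches the sound between regimes (none / subharmonics /
   subharmonics + chaos).

2. **Unvoiced source.** Turbulent noise is built in the frequency
   domain: uniform random magnitudes per STFT bin, flat up to 1200 Hz
   and sloped by `rolloff_noise` dB/kHz above, with its own amplitude
   envelope (a sound can also be fully voiceless).

3. **Filter.** The vocal tract is a transfer-function matrix (gain per
   STFT bin × frame) built from a zero-pole formant model. Missing
   formants are extended from the uniform-tube (schwa) series
   *F_n = (2n−1)·c/(4·VTL)* with *c* = 35,400 cm/s; apparent vocal
   tract length is estimated from user formants by regression on the
   odd-quarter-wavelength predictor. Mouth opening *m* shifts every
   formant by *ΔF = (m − 0.5)·c/(4·VTL)*; a closed mouth nasalizes the
   sound (B1 → 175 Hz plus a zero–pole pair near F1). Filtering is
   spectrogram multiplication followed by inverse STFT.

The output is peak-normalized 22050-Hz mono audio. All randomness is
seeded: the same configuration and seed give a bit-identical WAV, while
`temperature > 0` with different seeds yields a family of similar but
non-identical calls.

## Worked example

```python
import numpy as np
import voxgen as vg
from voxgen.cli import load_preset

cfg = load_preset("moan")          # bundled presets: moan, scream, laugh, roar, meow
wav = vg.synthesize(cfg)
print(f"duration = {wav.duration:.3f} s, peak = {wav.peak:.4f}")

times, f0 = vg.estimate_f0(wav, floor=60, ceiling=500)
m = vg.measure_peaks_and_rolloff(wav, f0_hint=float(np.nanmedian(f0)))
print(f"median f0 = {np.nanmedian(f0):.1f} Hz, "
      f"fitted source rolloff = {m.rolloff_db_per_octave:.1f} dB/octave")
vg.write_wav(wav, "moan.wav")
```

prints

```
duration = 0.596 s, peak = 0.9943
median f0 = 203.7 Hz, fitted source rolloff = -12.7 dB/octave
```

— a 0.6-s breathy moan whose pitch glides from ~220 down to ~140 Hz
(the preset's anchor contour) and whose measured spectral slope matches
the preset's 14 dB/octave rolloff softened by the formant envelope.
The same thing from a shell:

```sh
voxgen --preset moan --seed 1 --out moan.wav --spectrogram moan.png
voxgen --config a.yaml --morph-to b.yaml --steps 5 --out morph.wav
```

Configs are YAML; any time-varying parameter takes either a number or
`[time, value]` anchor pairs with times in [0, 1]:

```yaml
f0_anchors: [[0, 180], [0.3, 220], [1, 120]]
mouth: 0.6
source: {rolloff: 14}
noise: {envelope_db: -20, rolloff_noise: -8}
formants: [{freq: 630}, {freq: 1100}, {freq: 2500}]
tract: {vtl: 15.5}
```

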