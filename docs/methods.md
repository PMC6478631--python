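# Methods

This note documents the synthesis model implemented in `voxgen`, the
choices made where the underlying acoustics admits several reasonable
realizations, and what the test suite does and does not demonstrate.

## Source–filter decomposition

`voxgen` assumes vocal production separates into an excitation source
(vocal folds or syrinx) and a linear, time-varying resonant filter (the
vocal tract). The source is specified in the *frequency* domain — the
strengths of individual harmonics — rather than as a parametric glottal
pulse shape. This makes the perceptually relevant spectral properties
directly controllable and keeps the model applicable to nonmodal
phonation (screams, roars) and to nonhuman vocal anatomy, at the cost
of not reproducing glottal-pulse time-domain detail. All components are
mixed *before* the single final peak normalization, so relative levels
set in dB are preserved.

## Contours and temperature

Every time-varying parameter is a sparse list of `[time, value]`
anchors with times normalized to [0, 1] per segment. Dense realization
uses monotone piecewise-cubic (PCHIP) interpolation: it passes exactly
through the anchors and cannot overshoot between monotone anchors,
which matters for pitch (an overshooting spline between two pitch
anchors is audible). Frequency-like parameters (f0, formants)
interpolate on the log scale, matching pitch perception; amplitudes in
dB interpolate linearly. Constant contours bypass the log/exp round
trip so flat specifications are reproduced bit-exactly.

`temperature` (dimensionless, default 0.05) scales seeded Gaussian
perturbation of anchor values. The per-parameter scales at temperature
1 are declared in one table (`contours.WIGGLE_SCALES`): 5% of value for
f0 and formants, 2 dB for amplitudes, 10% for syllable and pause
lengths, 0.05 absolute for mouth opening. Perturbed values are clamped
to each parameter's legal range. Temperature 0 is exact and also
disables tube-model formant extension, which is why a small positive
value is the recommended "precise" mode.

## Voiced source

Each harmonic is an integer multiple of the per-sample f0 track, with
phase accumulated as `2π·h·cumsum(f0)/s` (zero initial phase). Any
component whose instantaneous frequency would cross the Nyquist
frequency contributes zero at those samples, so no aliasing energy is
generated. Harmonic amplitude follows `10^(−rolloff·log2 h / 20)`,
with an optional user hook for non-exponential source spectra (only the
plain exponential is covered by the acceptance tests).

* **Vibrato**: multiplies f0 by `2^(depth·sin(2π·f_vib·t)/12)`
  (depth in semitones).
* **Jitter**: seeded Gaussian noise low-passed to a correlation length
  of `jitter_period` seconds (2nd-order Butterworth, zero-phase),
  renormalized to unit SD and scaled to `jitter_depth` semitones on
  log-f0. Renormalizing after filtering makes the realized SD equal
  the configured depth regardless of the smoothing bandwidth. Very
  short `jitter_period` approaches rapid pitch perturbation; long
  periods approach slow vibrato-like wander.
* **Shimmer**: one multiplicative Gaussian draw per glottal cycle
  (cycle boundaries from the cumulative fundamental phase), SD =
  `shimmer_depth`, clipped below at 0.05 to keep amplitudes positive.
* **Attack**: raised-cosine fade of `attack_len` seconds at both
  segment edges.
* **Slow AM**: sinusoidal modulator of depth `am_depth` in [0, 1];
  `am_shape` ≠ 0 clips the sine toward a pulse-like waveform for
  trill-like sounds.

### Subharmonics and chaos

`sub_ratio = k` introduces a second fundamental g0 = f0/k: sinusoidal
components at every multiple of g0 that is not already an f0 harmonic,
each `sub_depth` dB below the harmonic envelope interpolated at that
frequency (the envelope is capped at unity below f0; no extra taper
across sidebands). Chaos raises jitter to 1.5 semitones and shimmer
to 0.25 by default (config-exposed — these magnitudes are this
package's defaults, not published constants).

Which regime is active is decided by a seeded bounded random walk:
Gaussian increments reflected into [0, 1], smoothed by a moving
average (`walk_smoothness` frames, default 21 at 100 frames/s), min-max
normalized, then mapped linearly into a target interval controlled by
`nonlinear_balance`: balance 0 confines the walk below the first
threshold (all frames "none"), balance 1 puts it above the second
threshold (all frames "subharmonics + chaos"), and intermediate values
span the thresholds so the call wanders unpredictably between regimes.
Default thresholds are (0.4, 0.7) of the walk range.

## Unvoiced source

Noise frames are built directly in the STFT domain: magnitude per bin
drawn from a seeded uniform distribution on [0, 1] (linear magnitude —
the simplest reading; drawing uniform dB would be an alternative),
phase uniform on [0, 2π), shaped by the piecewise source spectrum
(flat below `flat_ceiling` = 1200 Hz, `rolloff_noise` dB/kHz above)
and by the vocal-tract transfer function, then inverted by
overlap-add. Glottal noises (breathing) share the voiced filter; a
separate `own_filter` supports noises produced further from the
glottis (hissing). The noise amplitude envelope (dB) is applied per
sample after inversion and is independent of the voiced envelope.

## Filter

One STFT geometry is used everywhere: Hann window of 1024 samples, hop
256 (75% overlap), one-sided spectrum, inverted with the canonical
dual window (`scipy.signal.ShortTimeFFT`), giving reconstruction error
at machine precision for a unity envelope.

The transfer function is a zero-pole model evaluated at bin centers
`k·s/1024`: per formant the second-order resonance magnitude
`F² / sqrt((F² − f²)² + (B·f)²)` (unity at DC, peak ≈ F, half-power
width ≈ B), multiplied over poles and divided over zeros
(antiformants), so a pole and zero with identical parameters cancel
exactly. A formant's relative amplitude in dB maps to an exponent on
its pole term (`1 + amp_db / peak_gain_db`), which moves that
formant's peak by the requested dB without disturbing the rest of the
spectrum — this realizes flexible per-formant strength control.
Lip/nose radiation is a spectral tilt in dB/octave (default +6 lip,
0 nose) referenced to 500 Hz; the reference only shifts overall gain,
which the final normalization removes.

Formant bandwidths, where not given, come from a piecewise empirical
curve: `B(f) = 50·(1 + 0.1·(f/1000)²)` Hz above 500 Hz, continued
below 500 Hz by `B(500)·(1 + 2·((500 − f)/500)²)`, which widens
bandwidths toward low frequencies. This curve is this package's
documented default in the spirit of classic phonetic bandwidth fits;
its guaranteed properties (positive, continuous, decreasing toward
500 Hz from below) are tested, and any user-supplied bandwidth
overrides it.

Vocal-tract length ties the pieces together: user formants →
apparent VTL by through-origin regression of F_i on (2i − 1) (the
closed-form least-squares inverse of the uniform-tube formula);
VTL → schwa series for formant extension up to Nyquist; VTL → the
slope of the mouth-opening shift. The mouth contour is evaluated per
STFT frame; shifted formant frequencies are floored at 50 Hz. The
nasal configuration at m = 0 (B1 = 175 Hz, zero at F1 − 100 Hz and
pole at F1 + 100 Hz, both 100-Hz bandwidth) is calibrated on human
voice; for animal sounds, specify the transition manually instead.

## Assembly

Syllables are synthesized independently and concatenated with silent
pauses — no cross-syllable smoothing, mirroring how polysyllabic calls
are naturally built from discrete syllables. The bout is normalized to
a peak of −0.05 dBFS: effectively full scale while guaranteeing that
16-bit quantization cannot clip. `male_female` in [−1, 1] moves f0 and
the vocal tract together (+1 → f0 × 1/2, VTL × 1.25; smooth geometric
interpolation in between); formant shifts go through VTL scaling so
tube-extended formants stay consistent with user ones.

`morph(a, b, n)` produces a graded series of configs with exact
endpoint identity: frequencies interpolate geometrically (equal musical
steps), dB values and fractions linearly, integers by rounding, and
anchor lists after resampling both contours onto a common grid of
max(len(a), len(b)) uniformly spaced times. Endpoints must share
formant count and syllable structure; no automatic reconciliation is
attempted.

## Verification estimators

The package measures its own output (`voxgen.verify`); these are test
oracles for self-synthesized signals, not competitive analysis tools.

* **f0**: frame-wise autocorrelation via the power spectrum, evaluated
  on a 16× oversampled lag grid (band-limited interpolation), with the
  triangular window taper divided out (unbiased estimator) — without
  this, broad ACF peaks bias sharp and the zero-lag shoulder can beat
  the true period for low-pitched near-sinusoids. Candidate periods
  are local maxima; among candidates within 90% of the best, the
  shortest lag wins (avoids period-multiple errors). Frames whose best
  normalized ACF is below 0.45 are unvoiced.
* **Peaks / rolloff**: Welch-averaged spectrum (4096-point segments);
  peaks are local maxima with ≥ 10 dB prominence; source rolloff is
  the least-squares slope of harmonic peak level (dB) on log2(h).

The calibration targets met by these estimators (≤ 1% median f0 error
over random tonal syntheses at 80–800 Hz; rolloff slope within
1 dB/octave for 3–24 dB/octave) are verified in the test suite at the
problem sizes stated there (0.3–1 s of audio per measurement, 100
random configurations for the f0 sweep).

## What the tests show — and do not

All tests run on synthetic signals generated by this package, so they
demonstrate internal consistency: the output's measured acoustics
match the requested control parameters, published formulas are
implemented exactly (tube model, mouth shift, nasal bandwidth, noise
knee), and synthesis is bit-deterministic given a seed. They do not
demonstrate perceptual naturalness of the presets, fidelity to any
particular species' voice, or robustness of the estimators on recorded
(noisy, reverberant) audio.

## Known limitations

* No glottal-pulse (time-domain) synthesis mode; voice qualities
  defined by pulse shape (e.g. creak with double pulsing) can only be
  approximated spectrally.
* Formant contours inside one syllable are sampled at the STFT frame
  rate (~86 Hz at 22050 Hz); faster formant transitions are smoothed.
* `morph` requires structurally compatible endpoints.
* Synthesis is offline; no real-time or streaming operation.
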