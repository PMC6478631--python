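"""Voiced excitation: additive harmonic synthesis with nonlinear phenomena.

The glottal (or syringeal) source is built in the frequency domain as a
stack of sine-wave harmonics rather than as a train of glottal pulses.
Each harmonic h is a sine with instantaneous frequency h * f0(t) and zero
initial phase; the waveform of one component is

    w_h(t) = a_h(t) * sin(2 * pi * h / s * cumsum(f0)(t)),

where s is the sampling rate, and the voiced source is the sum over all
components whose instantaneous frequency stays below the Nyquist
frequency.  Harmonic strength decays by ``rolloff`` dB per octave above
the fundamental.

Voice quality is shaped by deterministic modulation (vibrato, slow
amplitude modulation), stochastic modulation (jitter on f0, shimmer on
per-cycle amplitude), and nonlinear vocal phenomena: subharmonics
(an additional fundamental g0 = f0 / k inserting sidebands between
harmonics) and deterministic chaos, simulated as strong jitter plus
shimmer.  Which phenomena are active when is governed by a seeded,
bounded random walk thresholded into three regimes (none / subharmonics /
subharmonics + chaos).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable

import numpy as np
from scipy.signal import butter, sosfiltfilt

from .contours import ContourSpec, sample_contour
from .waveform import Waveform

__all__ = [
    "GlottalSourceParams",
    "RegimeTrack",
    "REGIME_NONE",
    "REGIME_SUBH",
    "REGIME_CHAOS",
    "compute_f0_track",
    "harmonic_amplitudes",
    "synthesize_voiced",
    "add_subharmonics",
    "generate_regime_track",
    "apply_chaos",
]

REGIME_NONE = 0
REGIME_SUBH = 1
REGIME_CHAOS = 2


@dataclass
class GlottalSourceParams:
    """Control parameters of the voiced excitation source.

    rolloff is in dB/octave (>= 0 means decay); vibrato and jitter depths
    are in semitones; shimmer and AM depths are fractions of amplitude;
    sub_ratio is the integer f0/g0 ratio (1 disables subharmonics) and
    sub_depth the sideband attenuation in dB below the local harmonic
    envelope.  chaos_jitter / chaos_shimmer are the depths substituted in
    chaos regimes.
    """

    f0_contour: ContourSpec
    rolloff: float = 12.0
    rolloff_shape: Callable[[np.ndarray], np.ndarray] | None = None
    vibrato_freq: float = 5.0
    vibrato_depth: float = 0.0
    jitter_depth: float | np.ndarray = 0.0
    jitter_period: float = 0.02
    shimmer_depth: float | np.ndarray = 0.0
    attack_len: float = 0.01
    am_depth: float = 0.0
    am_freq: float = 30.0
    am_shape: float = 0.0
    sub_ratio: int = 1
    sub_depth: float = 12.0
    chaos_jitter: float = 1.5
    chaos_shimmer: float = 0.25

    def __post_init__(self) -> None:
        if self.rolloff < 0:
            raise ValueError("rolloff must be >= 0 (dB/octave of decay)")
        if self.sub_ratio < 1 or int(self.sub_ratio) != self.sub_ratio:
            raise ValueError("sub_ratio must be an integer >= 1")
        self.sub_ratio = int(self.sub_ratio)
        for name in ("vibrato_depth", "attack_len", "am_freq", "jitter_period"):
            if np.any(np.asarray(getattr(self, name)) < 0):
                raise ValueError(f"{name} must be >= 0")


@dataclass
class RegimeTrack:
    """Per-frame nonlinear-regime labels covering one voiced segment."""

    labels: np.ndarray  # ints in {REGIME_NONE, REGIME_SUBH, REGIME_CHAOS}
    frame_rate: float

    def per_sample(self, n_samples: int, sampling_rate: float) -> np.ndarray:
        """Expand frame labels to one label per audio sample."""
        t = np.arange(n_samples) / sampling_rate
        idx = np.clip((t * self.frame_rate).astype(int), 0, len(self.labels) - 1)
        return self.labels[idx]


def _per_sample_depth(
    depth: float | np.ndarray,
    chaos_level: float,
    regimes: RegimeTrack | None,
    n: int,
    sampling_rate: float,
) -> np.ndarray:
    """Per-sample modulation depth: baseline, raised to chaos level in chaos frames."""
    if np.ndim(depth) == 0:
        out = np.full(n, float(depth))
    else:
        d = np.asarray(depth, dtype=float)
        pos = np.linspace(0, len(d) - 1, n)
        out = d[np.clip(np.round(pos).astype(int), 0, len(d) - 1)]
    if regimes is not None:
        chaos = regimes.per_sample(n, sampling_rate) == REGIME_CHAOS
        out = np.where(chaos, np.maximum(out, chaos_level), out)
    return out


def _smooth_noise(n: int, cutoff_hz: float, sampling_rate: float, rng) -> np.ndarray:
    """Unit-SD Gaussian noise low-passed to the requested correlation scale."""
    x = rng.standard_normal(n)
    nyq = sampling_rate / 2
    if 0 < cutoff_hz < nyq * 0.95 and n > 30:
        sos = butter(2, cutoff_hz / nyq, output="sos")
        x = sosfiltfilt(sos, x)
    sd = x.std()
    return x / sd if sd > 0 else x


def compute_f0_track(
    params: GlottalSourceParams,
    duration: float,
    sampling_rate: float,
    regimes: RegimeTrack | None = None,
    seed: int = 0,
) -> np.ndarray:
    """Per-sample fundamental frequency: anchor contour x vibrato x jitter.

    Vibrato multiplies the base contour by
    ``2 ** (depth * sin(2 pi f_vib t) / 12)``.  Jitter is a seeded smooth
    random fluctuation of log-f0 with SD = jitter_depth semitones and
    correlation length jitter_period; in chaos regimes its depth is raised
    to the configured chaos level.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    base = sample_contour(params.f0_contour, duration, sampling_rate).values
    n = len(base)
    t = np.arange(n) / sampling_rate
    semitones = np.zeros(n)
    if params.vibrato_depth > 0:
        semitones += params.vibrato_depth * np.sin(2 * np.pi * params.vibrato_freq * t)
    depth = _per_sample_depth(
        params.jitter_depth, params.chaos_jitter, regimes, n, sampling_rate
    )
    if np.any(depth > 0):
        rng = np.random.default_rng(seed)
        cutoff = 1.0 / max(params.jitter_period, 1e-4)
        semitones += depth * _smooth_noise(n, cutoff, sampling_rate, rng)
    return base * 2.0 ** (semitones / 12.0)


def harmonic_amplitudes(
    h: int | np.ndarray, f0: float, params: GlottalSourceParams
) -> np.ndarray | float:
    """Source-spectrum amplitude of harmonic h relative to the fundamental.

    Plain exponential decay ``10 ** (-rolloff * log2(h) / 20)``, optionally
    modified by a user-supplied ``rolloff_shape(h) -> dB`` adjustment for
    non-exponential source spectra.  h = 1 maps to 1.0; output clipped to
    [0, 1].
    """
    h_arr = np.asarray(h, dtype=float)
    if np.any(h_arr < 1):
        raise ValueError("harmonic index must be >= 1")
    db = -params.rolloff * np.log2(h_arr)
    if params.rolloff_shape is not None:
        db = db + np.asarray(params.rolloff_shape(h_arr), dtype=float)
    amp = np.clip(10.0 ** (db / 20.0), 0.0, 1.0)
    return float(amp) if np.ndim(h) == 0 else amp


def add_subharmonics(
    params: GlottalSourceParams,
    f0_track: np.ndarray,
    regimes: RegimeTrack | None,
    sampling_rate: float,
) -> list[tuple[float, float]]:
    """Extra source components realizing g0 = f0 / sub_ratio.

    Returns (frequency multiplier, linear amplitude) pairs for every
    multiple of g0 that is not already an f0 harmonic, attenuated
    ``sub_depth`` dB below the harmonic envelope interpolated at that
    frequency (the envelope is capped at the fundamental's level below
    f0).  Gating by regime happens at synthesis time.
    """
    k = params.sub_ratio
    if k < 2:
        return []
    atten = 10.0 ** (-params.sub_depth / 20.0)
    f0_max = float(np.max(f0_track))
    n_max = int(np.floor(k * (sampling_rate / 2) / f0_max))
    components = []
    for j in range(1, n_max + 1):
        if j % k == 0:
            continue  # already a harmonic of f0
        m = j / k
        env = 10.0 ** (-params.rolloff * np.log2(max(m, 1.0)) / 20.0)
        components.append((m, env * atten))
    return components


def synthesize_voiced(
    f0_track: np.ndarray,
    params: GlottalSourceParams,
    sampling_rate: float,
    seed: int = 0,
    regimes: RegimeTrack | None = None,
    amplitude_envelope: np.ndarray | None = None,
) -> Waveform:
    """Sum the harmonic (and subharmonic) stack into the voiced waveform.

    Components whose instantaneous frequency would exceed the Nyquist
    frequency contribute zero at those samples.  Shimmer perturbs
    amplitude once per f0 cycle (cycle boundaries from the cumulative
    phase); an attack fade and slow amplitude modulation are applied to
    the summed signal.
    """
    f0_track = np.asarray(f0_track, dtype=float)
    if np.any(f0_track <= 0):
        raise ValueError("f0 track must be strictly positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    n = len(f0_track)
    nyquist = sampling_rate / 2
    phase = 2.0 * np.pi * np.cumsum(f0_track) / sampling_rate

    components: list[tuple[float, float]] = []
    h_max = int(np.floor(nyquist / float(np.min(f0_track))))
    for h in range(1, max(h_max, 1) + 1):
        components.append((float(h), float(harmonic_amplitudes(h, f0_track[0], params))))
    sub_components = add_subharmonics(params, f0_track, regimes, sampling_rate)

    sub_gate = None
    if regimes is not None and sub_components:
        lab = regimes.per_sample(n, sampling_rate)
        sub_gate = (lab == REGIME_SUBH) | (lab == REGIME_CHAOS)

    out = np.zeros(n)
    for m, amp in components:
        if amp <= 0:
            continue
        audible = m * f0_track <= nyquist
        if not np.any(audible):
            continue
        out += amp * audible * np.sin(m * phase)
    for m, amp in sub_components:
        audible = m * f0_track <= nyquist
        if sub_gate is not None:
            audible = audible & sub_gate
        if amp > 0 and np.any(audible):
            out += amp * audible * np.sin(m * phase)

    # shimmer: one multiplicative draw per glottal cycle
    shim_depth = _per_sample_depth(
        params.shimmer_depth, params.chaos_shimmer, regimes, n, sampling_rate
    )
    if np.any(shim_depth > 0):
        rng = np.random.default_rng(np.random.SeedSequence([int(seed) & 0x7FFFFFFF, 17]))
        cycle = np.floor(phase / (2 * np.pi)).astype(int)
        z = rng.standard_normal(cycle[-1] + 1)
        out *= np.clip(1.0 + shim_depth * z[cycle], 0.05, None)

    if params.am_depth > 0:
        t = np.arange(n) / sampling_rate
        mod = np.sin(2 * np.pi * params.am_freq * t)
        if params.am_shape != 0:
            # shape > 0 squares the modulator toward a pulse train
            mod = np.clip(mod * (1.0 + 2.0 * abs(params.am_shape)), -1.0, 1.0)
        out *= 1.0 - params.am_depth * (1.0 - mod) / 2.0

    if amplitude_envelope is not None:
        out *= amplitude_envelope

    fade = int(round(params.attack_len * sampling_rate))
    if 0 < fade < n // 2:
        ramp = 0.5 - 0.5 * np.cos(np.pi * np.arange(fade) / fade)
        out[:fade] *= ramp
        out[-fade:] *= ramp[::-1]

    return Waveform(out, sampling_rate)


def generate_regime_track(
    duration: float,
    nonlinear_balance: float,
    thresholds: tuple[float, float] = (0.4, 0.7),
    walk_smoothness: int = 21,
    seed: int = 0,
    frame_rate: float = 100.0,
) -> RegimeTrack:
    """Seeded random walk thresholded into nonlinear-phenomena regimes.

    A Gaussian-increment walk reflected into [0, 1] and smoothed by a
    moving average is min-max normalized and then squeezed into a target
    interval controlled by ``nonlinear_balance``: balance 0 confines it
    below the first threshold (every frame "none"), balance 1 above the
    second (every frame "subharmonics + chaos"), intermediate values span
    both thresholds so the walk wanders between regimes.
    """
    t1, t2 = thresholds
    if not 0 < t1 < t2 < 1:
        raise ValueError("thresholds must satisfy 0 < t1 < t2 < 1")
    if not 0 <= nonlinear_balance <= 1:
        raise ValueError("nonlinear_balance must be in [0, 1]")
    n = max(2, round(duration * frame_rate))
    rng = np.random.default_rng(seed)
    walk = np.cumsum(rng.normal(0.0, 0.1, n))
    # reflect into [0, 1]
    walk = np.abs(np.mod(walk + 1.0, 4.0) - 2.0) - 1.0
    walk = np.abs(walk)
    if walk_smoothness > 1:
        kernel = np.ones(int(walk_smoothness)) / int(walk_smoothness)
        walk = np.convolve(walk, kernel, mode="same")
    span = walk.max() - walk.min()
    walk = (walk - walk.min()) / span if span > 0 else np.full(n, 0.5)
    b = nonlinear_balance
    lo = b * t2
    hi = t1 * (1.0 - 1e-9) * (1.0 - b) + b * 1.0
    walk = lo + walk * (hi - lo)
    labels = np.full(n, REGIME_NONE, dtype=int)
    labels[walk >= t1] = REGIME_SUBH
    labels[walk >= t2] = REGIME_CHAOS
    return RegimeTrack(labels=labels, frame_rate=frame_rate)


def apply_chaos(
    params: GlottalSourceParams, regimes: RegimeTrack
) -> GlottalSourceParams:
    """Raise jitter/shimmer to chaos levels in chaos-labeled frames.

    Returns a copy whose jitter_depth and shimmer_depth are per-frame
    arrays (at the regime frame rate): baseline values outside chaos
    frames, the configured chaos levels inside them.
    """
    lab = regimes.labels
    chaos = lab == REGIME_CHAOS
    base_j = np.broadcast_to(np.asarray(params.jitter_depth, dtype=float), lab.shape)
    base_s = np.broadcast_to(np.asarray(params.shimmer_depth, dtype=float), lab.shape)
    jit = np.where(chaos, np.maximum(base_j, params.chaos_jitter), base_j)
    shim = np.where(chaos, np.maximum(base_s, params.chaos_shimmer), base_s)
    return replace(params, jitter_depth=jit, shimmer_depth=shim)
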