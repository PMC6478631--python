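"""Unvoiced (turbulent) excitation, built directly in the frequency domain.

Aspiration noise has a source spectrum that is flat up to a threshold
(1200 Hz by default) and falls off linearly above it at ``rolloff_noise``
dB per kHz.  Each STFT frame's magnitudes are drawn from a seeded uniform
distribution, shaped by that piecewise rolloff, multiplied by a
vocal-tract transfer function (the shared one for glottal noise such as
breathing, or a separate filter for noises produced further from the
glottis, e.g. hissing), given random phase, and converted to a waveform
by inverse STFT with overlap-add.  The result is then scaled by the noise
component's own amplitude envelope, which is independent of the voiced
envelope; a voiceless sound is simply noise with no harmonic component
mixed in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import ContourSpec, sample_contour
from .stft import N_BINS, bin_frequencies, make_stft
from .waveform import Waveform

__all__ = ["NoiseParams", "generate_noise", "mix_voiced_unvoiced", "noise_rolloff_gain"]

DEFAULT_FLAT_CEILING = 1200.0


@dataclass
class NoiseParams:
    """Turbulent-noise source controls.

    envelope is the noise amplitude contour in dB (0 dB = full scale of
    the raw noise); rolloff_noise the spectral slope in dB/kHz above the
    flat region ending at flat_ceiling Hz; own_filter, when given, is a
    SpectralEnvelope substituting for the shared vocal-tract filter.
    """

    envelope: ContourSpec = field(
        default_factory=lambda: ContourSpec.from_pairs(0.0, parameter_id="noise_db")
    )
    rolloff_noise: float = 0.0
    flat_ceiling: float = DEFAULT_FLAT_CEILING
    own_filter: object | None = None  # SpectralEnvelope

    def __post_init__(self) -> None:
        if self.flat_ceiling <= 0:
            raise ValueError("flat_ceiling must be positive")


def noise_rolloff_gain(
    freqs: np.ndarray, rolloff_noise: float, flat_ceiling: float
) -> np.ndarray:
    """Linear gain of the piecewise noise source spectrum.

    0 dB below ``flat_ceiling``; ``rolloff_noise`` dB per kHz beyond it
    (negative values attenuate high frequencies).
    """
    db = rolloff_noise * np.maximum(freqs - flat_ceiling, 0.0) / 1000.0
    return 10.0 ** (db / 20.0)


def generate_noise(
    params: NoiseParams,
    duration: float,
    sampling_rate: float,
    transfer: object | None = None,
    seed: int = 0,
) -> Waveform:
    """Synthesize turbulent noise of the requested duration.

    Per-frame magnitudes ~ U(0, 1) per bin, shaped by the piecewise
    rolloff and the transfer function (``params.own_filter`` wins over
    the shared ``transfer``; unity if neither is given), with seeded
    uniform random phase, inverted by overlap-add.  Output length is
    ``round(duration * sampling_rate)``.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    if sampling_rate <= 0:
        raise ValueError("sampling_rate must be positive")
    n_samples = round(duration * sampling_rate)
    S = make_stft(sampling_rate)
    n_frames = S.p_num(n_samples)
    rng = np.random.default_rng(seed)
    mags = rng.uniform(0.0, 1.0, (N_BINS, n_frames))
    freqs = bin_frequencies(sampling_rate)
    mags *= noise_rolloff_gain(freqs, params.rolloff_noise, params.flat_ceiling)[:, None]

    env = params.own_filter if params.own_filter is not None else transfer
    if env is not None:
        gains = env.gains
        if gains.shape[1] != n_frames:
            # resample envelope frames onto the noise STFT grid
            pos = np.linspace(0, gains.shape[1] - 1, n_frames)
            gains = gains[:, np.clip(np.round(pos).astype(int), 0, gains.shape[1] - 1)]
        mags *= gains

    phase = rng.uniform(0.0, 2.0 * np.pi, (N_BINS, n_frames))
    spec = mags * np.exp(1j * phase)
    x = S.istft(spec, k1=n_samples)
    x = np.asarray(x[:n_samples], dtype=float)
    if len(x) < n_samples:
        x = np.pad(x, (0, n_samples - len(x)))

    env_db = sample_contour(params.envelope, duration, sampling_rate).values
    x *= 10.0 ** (env_db / 20.0)
    return Waveform(x, sampling_rate)


def mix_voiced_unvoiced(
    voiced: Waveform | None,
    unvoiced: Waveform | None,
    alignment: tuple[float, float] = (0.0, 0.0),
) -> Waveform:
    """Sample-wise sum of the two components at the given onset offsets (s).

    Either component may be None or empty (voiceless or purely tonal
    output).  No normalization happens here -- peak scaling is applied
    once, after all mixing.
    """
    parts = []
    rates = []
    for wav, offset in zip((voiced, unvoiced), alignment):
        if wav is None or len(wav.samples) == 0:
            continue
        parts.append((wav, offset))
        rates.append(wav.sampling_rate)
    if not parts:
        raise ValueError("at least one non-empty component required")
    if len(set(rates)) > 1:
        raise ValueError("components must share a sampling rate")
    rate = rates[0]
    total = max(
        int(round(off * rate)) + len(w.samples) for w, off in parts
    )
    out = np.zeros(total)
    for w, off in parts:
        i = int(round(off * rate))
        out[i : i + len(w.samples)] += w.samples
    return Waveform(out, rate)
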