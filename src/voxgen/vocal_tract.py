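"""Vocal-tract filter: formants, tube model, and spectrogram filtering.

The vocal tract is modeled as the concatenation of second-order
resonances (formants) and optional anti-resonances (antiformants/zeros),
evaluated in the frequency domain as a transfer-function matrix: one gain
per STFT bin and frame.  Filtering multiplies the spectrogram of the
unfiltered excitation by this matrix and inverts the STFT.

The uniform-tube model links vocal-tract length (VTL) to the neutral
(schwa) formant series

    F_n = (2 n - 1) / 2 * d,     d = c / (2 * VTL),

with c = 35,400 cm/s the speed of sound in warm air.  Given user
formants, apparent VTL is recovered by regressing observed frequencies on
the odd-quarter-wavelength predictor; additional tube formants are then
appended above the user-specified ones up to the Nyquist frequency.

Mouth opening m in [0, 1] shifts every formant by

    dF = (m - 0.5) * c / (4 * VTL)

(0.5 = neutral, no adjustment).  A fully closed mouth (m = 0) nasalizes
the sound: the first formant's bandwidth is raised to 175 Hz and a
zero-pole pair is inserted in the vicinity of F1.  These nasalization
constants are calibrated on human voice and are not recommended for
animal calls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .contours import ContourSpec, SampledContour, evaluate_contour
from .stft import N_BINS, bin_frequencies, make_stft
from .waveform import Waveform

__all__ = [
    "SPEED_OF_SOUND",
    "NASAL_F1_BANDWIDTH",
    "Formant",
    "FormantTable",
    "VocalTractParams",
    "SpectralEnvelope",
    "estimate_vtl",
    "formant_frequencies_from_vtl",
    "extend_formants",
    "adjust_for_mouth",
    "estimate_bandwidth",
    "compute_spectral_envelope",
    "apply_filter",
]

#: speed of sound in warm air, cm/s
SPEED_OF_SOUND = 35_400.0
#: first-formant bandwidth imposed when the mouth is fully closed, Hz
NASAL_F1_BANDWIDTH = 175.0
#: offsets and bandwidth of the nasal zero-pole pair around F1, Hz
NASAL_ZERO_OFFSET = -100.0
NASAL_POLE_OFFSET = 100.0
NASAL_PAIR_BANDWIDTH = 100.0
#: formant frequencies are floored here after mouth adjustment, Hz
MIN_FORMANT_HZ = 50.0


@dataclass
class Formant:
    """One resonance (or anti-resonance): frequency/amplitude/bandwidth.

    ``frequency`` is a contour so formant transitions can be specified
    over time; ``bandwidth_hz`` of None means "estimate from frequency";
    ``amp_db`` boosts or cuts this formant's peak relative to the plain
    all-pole response; ``is_zero`` marks an antiformant.
    """

    frequency: ContourSpec
    amp_db: float = 0.0
    bandwidth_hz: float | None = None
    is_zero: bool = False

    @classmethod
    def at(cls, hz: float, **kw) -> "Formant":
        return cls(ContourSpec.from_pairs(hz, value_scale="log", parameter_id="formant"), **kw)


@dataclass
class FormantTable:
    formants: list[Formant] = field(default_factory=list)

    def frequencies_at(self, t_norm: float = 0.0) -> np.ndarray:
        """Pole frequencies at one normalized time, sorted ascending."""
        f = [
            float(evaluate_contour(fm.frequency, np.array([t_norm]))[0])
            for fm in self.formants
            if not fm.is_zero
        ]
        return np.sort(np.array(f))


@dataclass
class VocalTractParams:
    """Tract geometry and radiation controls.

    vtl in cm (None = estimate from the formant table); mouth contour in
    [0, 1]; lip/nose radiation as spectral tilt in dB/octave applied on
    top of the formant envelope.
    """

    vtl: float | None = None
    mouth_contour: ContourSpec = field(
        default_factory=lambda: ContourSpec.from_pairs(0.5, parameter_id="mouth")
    )
    lip_radiation: float = 6.0
    nose_radiation: float = 0.0
    speed_of_sound: float = SPEED_OF_SOUND

    def __post_init__(self) -> None:
        if self.vtl is not None and self.vtl <= 0:
            raise ValueError("vtl must be positive")


@dataclass
class SpectralEnvelope:
    """Vocal-tract transfer function sampled on the STFT grid."""

    gains: np.ndarray  # (n_bins, n_frames), linear, >= 0
    bin_hz: float
    hop_s: float

    def __post_init__(self) -> None:
        if np.any(~np.isfinite(self.gains)) or np.any(self.gains < 0):
            raise ValueError("envelope gains must be finite and >= 0")


def estimate_vtl(observed_formants, speed_of_sound: float = SPEED_OF_SOUND) -> float:
    """Apparent vocal-tract length (cm) from observed formant frequencies.

    Regression through the origin of F_i on the odd-quarter-wavelength
    predictor (2 i - 1): the closed-form L minimizing
    sum_i (F_i - (2 i - 1) c / (4 L))^2.  Exact inverse of
    :func:`formant_frequencies_from_vtl` on ideal tube inputs.
    """
    f = np.asarray(list(observed_formants), dtype=float)
    if f.size == 0:
        raise ValueError("need at least one formant frequency")
    if np.any(f <= 0):
        raise ValueError("formant frequencies must be positive")
    x = 2.0 * np.arange(1, f.size + 1) - 1.0
    slope = float(np.dot(x, f) / np.dot(x, x))  # = c / (4 L)
    return speed_of_sound / (4.0 * slope)


def formant_frequencies_from_vtl(
    vtl: float, n: int, speed_of_sound: float = SPEED_OF_SOUND
) -> np.ndarray:
    """First n schwa formants of a uniform tube closed at the glottis."""
    if vtl <= 0:
        raise ValueError("vtl must be positive")
    if n < 1:
        raise ValueError("n must be >= 1")
    d = speed_of_sound / (2.0 * vtl)
    return (2.0 * np.arange(1, n + 1) - 1.0) / 2.0 * d


def extend_formants(
    user: FormantTable,
    vtl: float | None,
    nyquist: float,
    temperature: float = 0.1,
    speed_of_sound: float = SPEED_OF_SOUND,
) -> FormantTable:
    """Append tube-model formants above the user-specified ones.

    Extra poles continue the schwa series (2 i - 1) * c / (4 * VTL) from
    the first index past the user's formant count, up to the Nyquist
    frequency.  User formants are never altered.  Setting temperature to
    exactly zero disables the extension (precise-synthesis mode).
    """
    if temperature == 0:
        return user
    user_freqs = user.frequencies_at(0.0)
    if vtl is None:
        if user_freqs.size == 0:
            raise ValueError("need vtl or at least one user formant")
        vtl = estimate_vtl(user_freqs, speed_of_sound)
    n_user = user_freqs.size
    highest = user_freqs[-1] if n_user else 0.0
    extra = []
    i = n_user + 1
    while True:
        f = (2.0 * i - 1.0) * speed_of_sound / (4.0 * vtl)
        if f > nyquist:
            break
        if f > highest:
            extra.append(Formant.at(f))
        i += 1
    return FormantTable(formants=list(user.formants) + extra)


def adjust_for_mouth(
    formants: FormantTable,
    mouth: SampledContour,
    vtl: float,
    speed_of_sound: float = SPEED_OF_SOUND,
) -> list[FormantTable]:
    """Apply the mouth-opening shift dF = (m - 0.5) c / (4 VTL) per frame.

    Returns one FormantTable per mouth frame (formant contours are
    collapsed to that frame's value).  Where the mouth is fully closed
    the sound is nasalized: B1 becomes 175 Hz and a zero-pole pair is
    inserted near F1.
    """
    m = np.asarray(mouth.values, dtype=float)
    if np.any((m < 0) | (m > 1)):
        raise ValueError("mouth opening must lie in [0, 1]")
    n_frames = len(m)
    grid = np.linspace(0.0, 1.0, n_frames) if n_frames > 1 else np.zeros(1)
    out = []
    for j, t_norm in enumerate(grid):
        delta = (m[j] - 0.5) * speed_of_sound / (4.0 * vtl)
        frame_formants = []
        for fm in formants.formants:
            f = float(evaluate_contour(fm.frequency, np.array([t_norm]))[0])
            if not fm.is_zero:
                f = max(f + delta, MIN_FORMANT_HZ)
            frame_formants.append(
                Formant.at(f, amp_db=fm.amp_db, bandwidth_hz=fm.bandwidth_hz, is_zero=fm.is_zero)
            )
        if m[j] == 0.0:
            poles = [fm for fm in frame_formants if not fm.is_zero]
            if poles:
                f1 = min(poles, key=lambda fm: fm.frequency.anchors[0].value)
                f1.bandwidth_hz = NASAL_F1_BANDWIDTH
                f1_hz = f1.frequency.anchors[0].value
                frame_formants.append(
                    Formant.at(
                        max(f1_hz + NASAL_ZERO_OFFSET, MIN_FORMANT_HZ),
                        bandwidth_hz=NASAL_PAIR_BANDWIDTH,
                        is_zero=True,
                    )
                )
                frame_formants.append(
                    Formant.at(f1_hz + NASAL_POLE_OFFSET, bandwidth_hz=NASAL_PAIR_BANDWIDTH)
                )
        out.append(FormantTable(formants=frame_formants))
    return out


def estimate_bandwidth(frequency) -> np.ndarray | float:
    """Formant bandwidth (Hz) estimated from center frequency.

    Piecewise empirical curve in the spirit of classic phonetic
    bandwidth-vs-frequency fits: above 500 Hz the bandwidth grows slowly
    and quadratically with frequency,

        B(f) = 50 * (1 + 0.1 * (f / 1000)^2),

    while below 500 Hz a correction widens bandwidths as frequency
    falls,

        B(f) = B(500) * (1 + 2 * ((500 - f) / 500)^2),

    continuous at 500 Hz and monotonically decreasing toward it from
    below.  Used only where the user supplied no bandwidth.
    """
    f = np.asarray(frequency, dtype=float)
    if np.any(f <= 0):
        raise ValueError("frequency must be positive")
    upper = 50.0 * (1.0 + 0.1 * (f / 1000.0) ** 2)
    b500 = 50.0 * (1.0 + 0.1 * 0.25)
    lower = b500 * (1.0 + 2.0 * ((500.0 - f) / 500.0) ** 2)
    out = np.where(f >= 500.0, upper, lower)
    return float(out) if np.ndim(frequency) == 0 else out


def _resonance_gain(freqs: np.ndarray, fc: float, bw: float) -> np.ndarray:
    """Magnitude response of one second-order resonance, unity at DC.

    Peak sits at the pole frequency (for bw << fc) with half-power width
    ~= bw.
    """
    num = fc * fc
    den = np.sqrt((fc * fc - freqs * freqs) ** 2 + (bw * freqs) ** 2)
    return num / np.maximum(den, 1e-12)


def compute_spectral_envelope(
    frame_tables: list[FormantTable] | FormantTable,
    sampling_rate: float,
    radiation: VocalTractParams | None = None,
) -> SpectralEnvelope:
    """Zero-pole transfer-function matrix on the STFT grid.

    Per frame, the gain at each bin is the product over formants of the
    second-order resonance response (divided, for antiformants, by the
    corresponding zero response).  A formant's relative amplitude in dB
    maps to an exponent on its pole term such that the formant peak moves
    by exactly that many dB.  Lip/nose radiation adds a spectral tilt in
    dB/octave (referenced to 500 Hz).
    """
    if isinstance(frame_tables, FormantTable):
        frame_tables = [frame_tables]
    S = make_stft(sampling_rate)
    freqs = bin_frequencies(sampling_rate)
    n_frames = len(frame_tables)
    gains = np.ones((N_BINS, n_frames))
    for j, table in enumerate(frame_tables):
        g = np.ones(N_BINS)
        for fm in table.formants:
            fc = float(evaluate_contour(fm.frequency, np.array([0.0]))[0])
            bw = fm.bandwidth_hz if fm.bandwidth_hz is not None else estimate_bandwidth(fc)
            if bw <= 0:
                raise ValueError("formant bandwidth must be positive")
            term = _resonance_gain(freqs, fc, bw)
            if fm.is_zero:
                g /= np.maximum(term, 1e-12)
            else:
                exponent = 1.0
                if fm.amp_db:
                    peak_db = 20.0 * np.log10(max(term.max(), 1.0 + 1e-9))
                    exponent = 1.0 + fm.amp_db / max(peak_db, 1e-6)
                g *= term**exponent
        gains[:, j] = g
    if radiation is not None:
        tilt = radiation.lip_radiation + radiation.nose_radiation
        if tilt:
            ref = 500.0
            f_safe = np.maximum(freqs, freqs[1] if len(freqs) > 1 else 1.0)
            rad = 10.0 ** (tilt * np.log2(f_safe / ref) / 20.0)
            gains *= rad[:, None]
    return SpectralEnvelope(
        gains=gains, bin_hz=sampling_rate / (2 * (N_BINS - 1)), hop_s=S.hop / sampling_rate
    )


def apply_filter(sound: Waveform, envelope: SpectralEnvelope) -> Waveform:
    """Filter by spectrogram multiplication: STFT -> x gains -> inverse STFT."""
    x = sound.samples
    S = make_stft(sound.sampling_rate)
    X = S.stft(x)
    g = envelope.gains
    if g.shape[0] != X.shape[0]:
        raise ValueError(
            f"envelope has {g.shape[0]} bins but the STFT uses {X.shape[0]}"
        )
    if g.shape[1] != X.shape[1]:
        pos = np.linspace(0, g.shape[1] - 1, X.shape[1])
        g = g[:, np.clip(np.round(pos).astype(int), 0, g.shape[1] - 1)]
    y = S.istft(X * g, k1=len(x))
    return Waveform(np.asarray(y[: len(x)], dtype=float), sound.sampling_rate)
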