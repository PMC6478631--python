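"""Acoustic verification: the package measures its own output.

Synthesis quality is checked not by listening but by independent acoustic
measurement: an autocorrelation pitch tracker recovers the f0 contour, a
Welch-averaged spectrum yields harmonic/formant peaks, and a regression
of harmonic level on log2(harmonic index) recovers the source rolloff.
These estimators are deliberately simple -- they are oracles for signals
this package synthesized, not general-purpose analysis tools -- and all
their thresholds live in one constants table so measurements are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import find_peaks, welch

from .waveform import Waveform

__all__ = [
    "SpectralMeasurement",
    "PERIODICITY_THRESHOLD",
    "PEAK_PROMINENCE_DB",
    "estimate_f0",
    "measure_peaks_and_rolloff",
    "render_spectrogram",
]

#: minimum normalized autocorrelation at the pitch lag to call a frame voiced
PERIODICITY_THRESHOLD = 0.45
#: minimum prominence (dB) for a spectral maximum to count as a peak
PEAK_PROMINENCE_DB = 10.0


@dataclass
class SpectralMeasurement:
    frame_times: np.ndarray
    f0: np.ndarray  # Hz per frame; NaN where unvoiced
    peaks_hz: np.ndarray
    peaks_db: np.ndarray
    rolloff_db_per_octave: float | None


def estimate_f0(
    sound: Waveform,
    frame: float = 0.05,
    floor: float = 50.0,
    ceiling: float = 1000.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Frame-wise autocorrelation pitch track.

    Returns (frame center times, f0 estimates); unvoiced frames (peak
    normalized autocorrelation below the periodicity threshold) are NaN.
    The autocorrelation is computed via the power spectrum and evaluated
    on a 16x-oversampled lag grid (band-limited interpolation), so the
    pitch-period estimate has sub-sample resolution even for
    harmonic-rich signals whose autocorrelation peaks are sharp.
    """
    x = sound.samples
    if len(x) == 0:
        raise ValueError("empty sound")
    rate = sound.sampling_rate
    if not floor < ceiling < rate / 2:
        raise ValueError("need floor < ceiling < Nyquist")
    n = int(round(frame * rate))
    n = max(n, int(3 * rate / floor))  # >= 3 periods of the lowest pitch
    hop = n // 2
    lag_max = rate / floor
    upsample = 16
    nfft = 1 << int(np.ceil(np.log2(2 * n)))
    times, f0s = [], []
    for start in range(0, max(len(x) - n, 0) + 1, hop):
        seg = x[start : start + n]
        if len(seg) < int(lag_max) + 2:
            break
        seg = seg - seg.mean()
        power = np.abs(np.fft.rfft(seg, nfft)) ** 2
        ac = np.fft.irfft(power, n=nfft * upsample)  # lag grid of 1/16 sample
        if ac[0] <= 0:
            times.append((start + n / 2) / rate)
            f0s.append(np.nan)
            continue
        ac = ac / ac[0]
        i_min = int(np.ceil(rate / ceiling * upsample))
        i_max = int(np.floor(lag_max * upsample))
        # undo the triangular taper of the windowed estimator, which biases
        # broad peaks toward shorter lags
        lags = np.arange(i_min, i_max + 1) / upsample
        window = ac[i_min : i_max + 1] / (1.0 - lags / len(seg))
        times.append((start + n / 2) / rate)
        # candidate pitch periods are local maxima; of those near the global
        # maximum, take the shortest lag (avoids period-multiple errors)
        peaks, _ = find_peaks(window)
        if len(peaks) == 0 or window[peaks].max() < PERIODICITY_THRESHOLD:
            f0s.append(np.nan)
            continue
        best = window[peaks].max()
        k = int(peaks[window[peaks] >= 0.9 * best][0]) + i_min
        f0s.append(rate * upsample / k)
    return np.asarray(times), np.asarray(f0s)


def _welch_db(sound: Waveform, nperseg: int = 4096) -> tuple[np.ndarray, np.ndarray]:
    nperseg = min(nperseg, len(sound.samples))
    freqs, psd = welch(sound.samples, fs=sound.sampling_rate, nperseg=nperseg)
    db = 10.0 * np.log10(np.maximum(psd, 1e-30))
    return freqs, db


def measure_peaks_and_rolloff(
    sound: Waveform, f0_hint: float | None = None, n_harmonics: int = 10
) -> SpectralMeasurement:
    """Spectral peaks and, given an f0 hint, the fitted source rolloff.

    Peaks are local maxima of the Welch-averaged power spectrum with at
    least the configured prominence.  With an f0 hint, the level of each
    harmonic (spectrum maximum within half an f0 of h * f0) is regressed
    on log2(h); the slope estimates the source rolloff in dB/octave.
    """
    freqs, db = _welch_db(sound)
    if np.all(db <= db.min() + 1e-9):  # silence
        return SpectralMeasurement(
            frame_times=np.zeros(0), f0=np.zeros(0),
            peaks_hz=np.zeros(0), peaks_db=np.zeros(0),
            rolloff_db_per_octave=None,
        )
    idx, _ = find_peaks(db, prominence=PEAK_PROMINENCE_DB)
    slope = None
    if f0_hint is not None and f0_hint > 0:
        levels, hs = [], []
        for h in range(1, n_harmonics + 1):
            target = h * f0_hint
            if target >= sound.sampling_rate / 2:
                break
            band = (freqs > target - f0_hint / 2) & (freqs < target + f0_hint / 2)
            if not np.any(band):
                break
            levels.append(db[band].max())
            hs.append(h)
        if len(hs) >= 3:
            slope = float(np.polyfit(np.log2(hs), levels, 1)[0])
    return SpectralMeasurement(
        frame_times=np.zeros(0),
        f0=np.zeros(0),
        peaks_hz=freqs[idx],
        peaks_db=db[idx],
        rolloff_db_per_octave=slope,
    )


def render_spectrogram(sound: Waveform, path: str, fmax: float | None = None) -> None:
    """Save a dB-scaled spectrogram of the sound as a raster image."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from scipy.signal import spectrogram as _spectrogram

    f, t, sxx = _spectrogram(
        sound.samples, fs=sound.sampling_rate, nperseg=1024, noverlap=768
    )
    fig, ax = plt.subplots(figsize=(8, 4))
    ax.pcolormesh(t, f, 10 * np.log10(np.maximum(sxx, 1e-12)), shading="auto", cmap="magma")
    if fmax:
        ax.set_ylim(0, fmax)
    ax.set_xlabel("time (s)")
    ax.set_ylabel("frequency (Hz)")
    fig.tight_layout()
    fig.savefig(path, dpi=100)
    plt.close(fig)
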