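"""Shared short-time Fourier transform geometry.

One STFT configuration (hann window of 1024 samples, hop 256, one-sided
spectrum) is used everywhere a spectrogram is taken, multiplied or
inverted -- noise synthesis and vocal-tract filtering alike -- so there is
a single reconstruction-error budget and envelope matrices are always
geometrically compatible.
"""

from __future__ import annotations

import numpy as np
from scipy.signal import ShortTimeFFT, get_window

N_FFT = 1024
HOP = 256
N_BINS = N_FFT // 2 + 1


def make_stft(sampling_rate: float) -> ShortTimeFFT:
    win = get_window("hann", N_FFT, fftbins=True)
    return ShortTimeFFT(win, hop=HOP, fs=sampling_rate, fft_mode="onesided")


def bin_frequencies(sampling_rate: float) -> np.ndarray:
    """Center frequency of each one-sided FFT bin (k * s / N)."""
    return np.arange(N_BINS) * sampling_rate / N_FFT
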