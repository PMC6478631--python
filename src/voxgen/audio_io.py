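"""WAV output (PCM 16-bit mono) with atomic writes."""

from __future__ import annotations

import os
import tempfile
from pathlib import Path

import numpy as np
from scipy.io import wavfile

from .waveform import Waveform

__all__ = ["write_wav", "read_wav"]


def write_wav(sound: Waveform, path: str | Path) -> None:
    """Write a normalized waveform as 16-bit mono PCM.

    The file is written to a temporary sibling and renamed into place, so
    a failure never leaves a partial audio file at the destination.
    """
    path = Path(path)
    samples = np.clip(sound.samples, -1.0, 1.0)
    pcm = np.round(samples * 32767.0).astype(np.int16)
    fd, tmp = tempfile.mkstemp(suffix=".wav", dir=path.parent or None)
    os.close(fd)
    try:
        wavfile.write(tmp, int(sound.sampling_rate), pcm)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def read_wav(path: str | Path) -> Waveform:
    """Read a PCM WAV file back into a float waveform in [-1, 1]."""
    rate, data = wavfile.read(str(path))
    if data.dtype == np.int16:
        samples = data.astype(float) / 32767.0
    elif data.dtype == np.int32:
        samples = data.astype(float) / 2147483647.0
    else:
        samples = data.astype(float)
    if samples.ndim > 1:
        samples = samples.mean(axis=1)
    return Waveform(samples, float(rate))
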