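"""Sampled audio container shared by all synthesis stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class Waveform:
    """Mono audio: a float sample array plus its sampling rate in Hz."""

    samples: np.ndarray
    sampling_rate: float

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")

    @property
    def duration(self) -> float:
        return len(self.samples) / self.sampling_rate

    @property
    def peak(self) -> float:
        return float(np.max(np.abs(self.samples))) if len(self.samples) else 0.0

    def normalized(self, peak: float = 1.0) -> "Waveform":
        """Scale to the requested peak amplitude (no-op on silence)."""
        p = self.peak
        scaled = self.samples if p == 0 else self.samples * (peak / p)
        return Waveform(scaled, self.sampling_rate)
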