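"""Sparse anchor contours and their dense realization.

Every time-varying control parameter of the synthesizer (intonation,
amplitude envelope, mouth opening, formant frequencies ...) is specified
by a handful of time-value anchors rather than a frame-by-frame matrix.
Anchor times are normalized to [0, 1] within the segment they control, so
the same anchor set can be stretched over any segment duration.  Dense
contours are realized with shape-preserving (monotone) piecewise-cubic
interpolation, on a logarithmic value scale for frequency-like parameters
and a linear scale otherwise: the interpolant passes exactly through the
anchors and never overshoots between monotone anchor values.

The ``temperature`` hyperparameter drives seeded stochastic "wiggling" of
anchor values, so repeated synthesis with temperature > 0 and different
seeds produces similar but non-identical vocalizations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.interpolate import PchipInterpolator

__all__ = [
    "Anchor",
    "ContourSpec",
    "SampledContour",
    "PARAM_RANGES",
    "WIGGLE_SCALES",
    "sample_contour",
    "wiggle_contour",
]


class InvalidSpecError(ValueError):
    """A contour specification violates its invariants."""


#: Legal value range per parameter id; wiggled values are clamped to these.
PARAM_RANGES: dict[str, tuple[float, float]] = {
    "f0": (1.0, 10_000.0),
    "formant": (10.0, 20_000.0),
    "ampl_db": (-120.0, 40.0),
    "noise_db": (-120.0, 40.0),
    "mouth": (0.0, 1.0),
    "syllable_ms": (10.0, 60_000.0),
    "pause_ms": (0.0, 60_000.0),
}

#: Standard deviation of the anchor perturbation at temperature = 1.
#: ("rel", x): SD is x * |value|;  ("abs", x): SD is x in native units.
WIGGLE_SCALES: dict[str, tuple[str, float]] = {
    "f0": ("rel", 0.05),
    "formant": ("rel", 0.05),
    "ampl_db": ("abs", 2.0),
    "noise_db": ("abs", 2.0),
    "mouth": ("abs", 0.05),
    "syllable_ms": ("rel", 0.10),
    "pause_ms": ("rel", 0.10),
}

_DEFAULT_WIGGLE = ("rel", 0.05)


@dataclass(frozen=True)
class Anchor:
    """One time-value anchor; time is a normalized position in [0, 1]."""

    time: float
    value: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.time <= 1.0:
            raise InvalidSpecError(f"anchor time {self.time} outside [0, 1]")


@dataclass(frozen=True)
class ContourSpec:
    """Sparse specification of one time-varying parameter.

    Parameters
    ----------
    anchors
        Ordered (by time) anchors; at least one.
    value_scale
        ``"linear"`` or ``"log"`` -- the domain in which interpolation
        happens.  Log scale requires strictly positive values and is the
        default for pitch and formant frequencies.
    parameter_id
        Name of the controlled parameter; selects the legal range and the
        temperature scale used by :func:`wiggle_contour`.
    """

    anchors: tuple[Anchor, ...]
    value_scale: str = "linear"
    parameter_id: str = ""

    def __post_init__(self) -> None:
        if len(self.anchors) == 0:
            raise InvalidSpecError("contour needs at least one anchor")
        times = [a.time for a in self.anchors]
        if any(t2 < t1 for t1, t2 in zip(times, times[1:])):
            raise InvalidSpecError("anchors must be sorted by time")
        if self.value_scale not in ("linear", "log"):
            raise InvalidSpecError(f"unknown value_scale {self.value_scale!r}")
        if self.value_scale == "log" and any(a.value <= 0 for a in self.anchors):
            raise InvalidSpecError("log-scale contour requires positive values")
        lo, hi = PARAM_RANGES.get(self.parameter_id, (-np.inf, np.inf))
        for a in self.anchors:
            if not lo <= a.value <= hi:
                raise InvalidSpecError(
                    f"{self.parameter_id or 'contour'} anchor value {a.value} "
                    f"outside legal range [{lo}, {hi}]"
                )

    @property
    def times(self) -> np.ndarray:
        return np.array([a.time for a in self.anchors])

    @property
    def values(self) -> np.ndarray:
        return np.array([a.value for a in self.anchors])

    @classmethod
    def from_pairs(
        cls,
        pairs: list | tuple | float | int,
        value_scale: str = "linear",
        parameter_id: str = "",
    ) -> "ContourSpec":
        """Build a spec from ``[[time, value], ...]``, ``[v0, v1, ...]`` or a scalar.

        A bare scalar means a flat contour; a flat list of values is spread
        evenly over [0, 1].
        """
        if np.isscalar(pairs):
            anchors = (Anchor(0.0, float(pairs)),)
        else:
            seq = list(pairs)
            if seq and np.isscalar(seq[0]):
                times = np.linspace(0.0, 1.0, len(seq)) if len(seq) > 1 else [0.0]
                anchors = tuple(Anchor(float(t), float(v)) for t, v in zip(times, seq))
            else:
                anchors = tuple(Anchor(float(t), float(v)) for t, v in seq)
        return cls(anchors=anchors, value_scale=value_scale, parameter_id=parameter_id)


@dataclass
class SampledContour:
    """Dense realization of a contour: one value per sample (or frame)."""

    values: np.ndarray
    rate: float

    def __len__(self) -> int:
        return len(self.values)

    @property
    def times(self) -> np.ndarray:
        """Normalized time of each point on the [0, 1] segment axis."""
        n = len(self.values)
        return np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)


def _interpolator(spec: ContourSpec):
    t, v_raw = spec.times, spec.values
    if len(t) == 1 or np.all(v_raw == v_raw[0]):
        const = v_raw[0]  # constant contour: no scale round trip
        return lambda x: np.full_like(np.asarray(x, dtype=float), const)
    v = np.log(v_raw) if spec.value_scale == "log" else v_raw
    # collapse duplicate anchor times (instantaneous steps): keep the later value
    keep = np.concatenate([np.diff(t) > 0, [True]])
    t2, v2 = t[keep], v[keep]
    if len(t2) == 1:
        const = v_raw[keep][0]
        return lambda x: np.full_like(np.asarray(x, dtype=float), const)
    pchip = PchipInterpolator(t2, v2, extrapolate=False)

    def f(x, _p=pchip, _t=t2):
        return _p(np.clip(x, _t[0], _t[-1]))

    if spec.value_scale == "log":
        return lambda x: np.exp(f(x))
    return f


def sample_contour(spec: ContourSpec, duration: float, rate: float) -> SampledContour:
    """Realize a sparse contour as ``round(duration * rate)`` dense values.

    The grid spans the normalized segment [0, 1] inclusively; the
    interpolant passes through every anchor and, between anchors with
    monotone values, is itself monotone (no overshoot).
    """
    if duration <= 0:
        raise InvalidSpecError("duration must be positive")
    if rate <= 0:
        raise InvalidSpecError("rate must be positive")
    n = max(1, round(duration * rate))
    grid = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    values = np.asarray(_interpolator(spec)(grid), dtype=float)
    return SampledContour(values=values, rate=rate)


def evaluate_contour(spec: ContourSpec, at: np.ndarray) -> np.ndarray:
    """Evaluate the contour interpolant at arbitrary normalized times."""
    return np.asarray(_interpolator(spec)(np.asarray(at, dtype=float)), dtype=float)


def wiggle_contour(spec: ContourSpec, temperature: float, seed: int) -> ContourSpec:
    """Stochastically perturb anchor values, scaled by ``temperature``.

    Each anchor value receives an independent Gaussian perturbation with
    SD = temperature x the per-parameter scale declared in
    :data:`WIGGLE_SCALES` (relative scales multiply by |value|).  Results
    are clamped to the parameter's legal range.  Temperature 0 returns the
    spec unchanged; a fixed seed gives identical output on every call.
    """
    if temperature < 0:
        raise ValueError("temperature must be >= 0")
    if temperature == 0:
        return spec
    kind, scale = WIGGLE_SCALES.get(spec.parameter_id, _DEFAULT_WIGGLE)
    lo, hi = PARAM_RANGES.get(spec.parameter_id, (-np.inf, np.inf))
    if spec.value_scale == "log":
        lo = max(lo, 1e-6)
    rng = np.random.default_rng(seed)
    new_anchors = []
    for a in spec.anchors:
        sd = temperature * (scale * abs(a.value) if kind == "rel" else scale)
        v = float(np.clip(a.value + rng.normal(0.0, sd), lo, hi))
        new_anchors.append(Anchor(a.time, v))
    return replace(spec, anchors=tuple(new_anchors))
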