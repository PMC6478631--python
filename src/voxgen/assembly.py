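"""Top-level synthesis: bouts, syllables, mixing, normalization, morphing.

A vocalization is a bout of one or more syllables separated by pauses.
Each syllable is synthesized independently -- voiced source (with
subharmonics and chaos per the regime random walk), turbulent noise,
vocal-tract filtering -- then the syllables are concatenated with silent
pauses and the whole bout is normalized for peak amplitude.  All
randomness flows from the config seed, so the same (config, seed) pair
always yields a bit-identical waveform, while temperature > 0 with
different seeds gives a family of similar but non-identical calls.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, replace

import numpy as np

from .contours import Anchor, ContourSpec, sample_contour, wiggle_contour
from .noise import NoiseParams, generate_noise, mix_voiced_unvoiced
from .source import (
    GlottalSourceParams,
    apply_chaos,
    compute_f0_track,
    generate_regime_track,
    synthesize_voiced,
)
from .stft import HOP, make_stft
from .vocal_tract import (
    FormantTable,
    VocalTractParams,
    adjust_for_mouth,
    apply_filter,
    compute_spectral_envelope,
    estimate_vtl,
    extend_formants,
)
from .waveform import Waveform

__all__ = [
    "BoutSpec",
    "SynthConfig",
    "Waveform",
    "synthesize",
    "apply_male_female",
    "morph",
]

#: final peak level: -0.05 dBFS, leaving headroom for 16-bit quantization
PEAK_LEVEL = 10.0 ** (-0.05 / 20.0)
#: maleFemale mapping constants: at +1, f0 halves and the tract lengthens
MALE_FEMALE_F0_OCTAVES = 1.0
MALE_FEMALE_VTL_FACTOR = 1.25


@dataclass
class BoutSpec:
    """Bout structure: syllable count and length/pause contours (ms).

    The length contours are indexed by normalized syllable position, so a
    bout can, e.g., accelerate (shorter syllables toward the end) with
    two anchors.
    """

    n_syllables: int = 1
    syllable_len: ContourSpec = field(
        default_factory=lambda: ContourSpec.from_pairs(300.0, parameter_id="syllable_ms")
    )
    pause_len: ContourSpec = field(
        default_factory=lambda: ContourSpec.from_pairs(100.0, parameter_id="pause_ms")
    )
    repeat_bout: int = 1

    def __post_init__(self) -> None:
        if self.n_syllables < 1:
            raise ValueError("n_syllables must be >= 1")
        if self.repeat_bout < 1:
            raise ValueError("repeat_bout must be >= 1")


@dataclass
class SynthConfig:
    """Complete control-parameter set for one vocalization."""

    bout: BoutSpec = field(default_factory=BoutSpec)
    source: GlottalSourceParams = field(
        default_factory=lambda: GlottalSourceParams(
            f0_contour=ContourSpec.from_pairs(120.0, value_scale="log", parameter_id="f0")
        )
    )
    noise: NoiseParams | None = None
    formants: FormantTable = field(default_factory=FormantTable)
    tract: VocalTractParams = field(default_factory=VocalTractParams)
    temperature: float = 0.05
    male_female: float = 0.0
    nonlinear_balance: float = 0.0
    voiced: bool = True
    sampling_rate: float = 22050.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.temperature < 0:
            raise ValueError("temperature must be >= 0")
        if not -1.0 <= self.male_female <= 1.0:
            raise ValueError("male_female must lie in [-1, 1]")
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")


def apply_male_female(config: SynthConfig) -> SynthConfig:
    """Shift f0 and tract length together along a male-female axis.

    male_female = 0 leaves the config unchanged; +1 halves every f0
    anchor and lengthens the vocal tract by 25% (lowering all formants
    coherently, including tube-added ones); -1 does the opposite.  Both
    mappings are smooth and monotone in between.
    """
    mf = config.male_female
    if not -1.0 <= mf <= 1.0:
        raise ValueError("male_female must lie in [-1, 1]")
    if mf == 0.0:
        return config
    cfg = copy.deepcopy(config)
    f0_factor = 2.0 ** (-MALE_FEMALE_F0_OCTAVES * mf)
    vtl_factor = MALE_FEMALE_VTL_FACTOR**mf
    spec = cfg.source.f0_contour
    cfg.source.f0_contour = replace(
        spec,
        anchors=tuple(Anchor(a.time, a.value * f0_factor) for a in spec.anchors),
    )
    if cfg.tract.vtl is not None:
        cfg.tract.vtl *= vtl_factor
    for fm in cfg.formants.formants:
        fm.frequency = replace(
            fm.frequency,
            anchors=tuple(
                Anchor(a.time, a.value / vtl_factor) for a in fm.frequency.anchors
            ),
        )
    cfg.male_female = 0.0
    return cfg


def _resolve_vtl(config: SynthConfig) -> float:
    if config.tract.vtl is not None:
        return config.tract.vtl
    user = config.formants.frequencies_at(0.0)
    if user.size:
        return estimate_vtl(user, config.tract.speed_of_sound)
    return 17.7  # neutral adult schwa tract


def _syllable_durations(config: SynthConfig, rng: np.random.Generator) -> tuple[list, list]:
    """Per-syllable and per-pause durations in seconds, wiggled by temperature."""
    n = config.bout.n_syllables
    grid = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    syl_spec, pause_spec = config.bout.syllable_len, config.bout.pause_len
    if config.temperature > 0:
        syl_spec = wiggle_contour(syl_spec, config.temperature, int(rng.integers(2**31)))
        pause_spec = wiggle_contour(pause_spec, config.temperature, int(rng.integers(2**31)))
    from .contours import evaluate_contour

    syl_ms = evaluate_contour(syl_spec, grid)
    pause_ms = evaluate_contour(pause_spec, grid[:-1]) if n > 1 else np.array([])
    return [max(s, 10.0) / 1000.0 for s in syl_ms], [max(p, 0.0) / 1000.0 for p in pause_ms]


def _synthesize_syllable(
    config: SynthConfig, duration: float, vtl: float, rng: np.random.Generator
) -> Waveform:
    s = config.sampling_rate
    temp = config.temperature
    seeds = rng.integers(2**31, size=6)

    regimes = None
    source_params = config.source
    if config.nonlinear_balance > 0:
        regimes = generate_regime_track(
            duration, config.nonlinear_balance, seed=int(seeds[0])
        )
        source_params = apply_chaos(source_params, regimes)

    # vocal-tract transfer function shared by voiced and glottal noise
    mouth_spec = config.tract.mouth_contour
    f0_spec = source_params.f0_contour
    if temp > 0:
        mouth_spec = wiggle_contour(mouth_spec, temp, int(seeds[1]))
        f0_spec = wiggle_contour(f0_spec, temp, int(seeds[2]))
        source_params = replace(source_params, f0_contour=f0_spec)
    nyquist = s / 2
    table = extend_formants(
        config.formants, vtl, nyquist, temperature=temp,
        speed_of_sound=config.tract.speed_of_sound,
    )
    frame_rate = s / HOP
    n_samples = round(duration * s)
    n_frames = make_stft(s).p_num(n_samples)
    mouth = sample_contour(mouth_spec, duration, n_frames / duration)
    mouth.values = mouth.values[:n_frames]
    frame_tables = adjust_for_mouth(table, mouth, vtl, config.tract.speed_of_sound)
    envelope = compute_spectral_envelope(frame_tables, s, radiation=config.tract)

    voiced = None
    if config.voiced:
        f0_track = compute_f0_track(source_params, duration, s, regimes, seed=int(seeds[3]))
        raw = synthesize_voiced(f0_track, source_params, s, seed=int(seeds[4]), regimes=regimes)
        voiced = apply_filter(raw, envelope)

    unvoiced = None
    if config.noise is not None:
        unvoiced = generate_noise(config.noise, duration, s, transfer=envelope, seed=int(seeds[5]))

    if voiced is None and unvoiced is None:
        raise ValueError("config produces neither voiced nor noise component")
    return mix_voiced_unvoiced(voiced, unvoiced)


def synthesize(config: SynthConfig) -> Waveform:
    """Render a complete vocalization bout from its control parameters."""
    cfg = apply_male_female(config)
    s = cfg.sampling_rate
    rng = np.random.default_rng(cfg.seed)
    pieces = []
    for _ in range(cfg.bout.repeat_bout):
        syl_durs, pause_durs = _syllable_durations(cfg, rng)
        for i, dur in enumerate(syl_durs):
            pieces.append(_synthesize_syllable(cfg, dur, _resolve_vtl(cfg), rng).samples)
            if i < len(syl_durs) - 1:
                pieces.append(np.zeros(round(pause_durs[i] * s)))
        if cfg.bout.repeat_bout > 1:
            pieces.append(np.zeros(round((pause_durs[-1] if pause_durs else 0.1) * s)))
    out = np.concatenate(pieces) if pieces else np.zeros(0)
    return Waveform(out, s).normalized(PEAK_LEVEL)


def _interp_scalar(a: float, b: float, w: float, geometric: bool) -> float:
    if a == b:
        return float(a)
    if geometric:
        if a <= 0 or b <= 0:
            raise ValueError("geometric interpolation requires positive values")
        return float(a ** (1 - w) * b**w)
    return float(a * (1 - w) + b * w)


def _interp_contour(ca: ContourSpec, cb: ContourSpec, w: float) -> ContourSpec:
    """Interpolate two anchor lists after resampling to a common grid."""
    from .contours import evaluate_contour

    if ca == cb:
        return ca
    geometric = ca.value_scale == "log" and cb.value_scale == "log"
    n = max(len(ca.anchors), len(cb.anchors))
    grid = np.linspace(0.0, 1.0, n) if n > 1 else np.zeros(1)
    va = evaluate_contour(ca, grid)
    vb = evaluate_contour(cb, grid)
    vals = [
        _interp_scalar(x, y, w, geometric) for x, y in zip(va, vb)
    ]
    return replace(
        ca, anchors=tuple(Anchor(float(t), v) for t, v in zip(grid, vals))
    )


def morph(config_a: SynthConfig, config_b: SynthConfig, n_steps: int) -> list[SynthConfig]:
    """Graded series of configs from a to b (endpoints included exactly).

    Frequencies interpolate geometrically, dB values and fractions
    linearly; integer counts are rounded from the interpolant; anchor
    lists are resampled to a common grid first.  Both configs must have
    the same formant structure and syllable count.
    """
    if n_steps < 2:
        raise ValueError("n_steps must be >= 2")
    na = len(config_a.formants.formants)
    nb = len(config_b.formants.formants)
    if na != nb:
        raise ValueError(
            f"morph endpoints must share the formant count (got {na} vs {nb})"
        )
    out = []
    for step in range(n_steps):
        if step == 0:
            out.append(copy.deepcopy(config_a))
            continue
        if step == n_steps - 1:
            out.append(copy.deepcopy(config_b))
            continue
        w = step / (n_steps - 1)
        cfg = copy.deepcopy(config_a)
        cfg.source.f0_contour = _interp_contour(
            config_a.source.f0_contour, config_b.source.f0_contour, w
        )
        for name, geo in [
            ("rolloff", False), ("vibrato_freq", True), ("vibrato_depth", False),
            ("jitter_depth", False), ("shimmer_depth", False), ("attack_len", False),
            ("am_depth", False), ("am_freq", True), ("sub_depth", False),
        ]:
            a_v = getattr(config_a.source, name)
            b_v = getattr(config_b.source, name)
            if np.ndim(a_v) == 0 and np.ndim(b_v) == 0:
                geo_ok = geo and a_v > 0 and b_v > 0
                setattr(cfg.source, name, _interp_scalar(float(a_v), float(b_v), w, geo_ok))
        cfg.source.sub_ratio = max(1, round(
            _interp_scalar(config_a.source.sub_ratio, config_b.source.sub_ratio, w, False)
        ))
        for i, fm in enumerate(cfg.formants.formants):
            fm.frequency = _interp_contour(
                config_a.formants.formants[i].frequency,
                config_b.formants.formants[i].frequency,
                w,
            )
            fm.amp_db = _interp_scalar(
                config_a.formants.formants[i].amp_db,
                config_b.formants.formants[i].amp_db, w, False,
            )
        va, vb = config_a.tract.vtl, config_b.tract.vtl
        if va is not None and vb is not None:
            cfg.tract.vtl = _interp_scalar(va, vb, w, True)
        cfg.tract.mouth_contour = _interp_contour(
            config_a.tract.mouth_contour, config_b.tract.mouth_contour, w
        )
        cfg.temperature = _interp_scalar(config_a.temperature, config_b.temperature, w, False)
        cfg.nonlinear_balance = _interp_scalar(
            config_a.nonlinear_balance, config_b.nonlinear_balance, w, False
        )
        cfg.bout.n_syllables = max(1, round(_interp_scalar(
            config_a.bout.n_syllables, config_b.bout.n_syllables, w, False
        )))
        cfg.bout.syllable_len = _interp_contour(
            config_a.bout.syllable_len, config_b.bout.syllable_len, w
        )
        cfg.bout.pause_len = _interp_contour(
            config_a.bout.pause_len, config_b.bout.pause_len, w
        )
        if config_a.noise is not None and config_b.noise is not None:
            cfg.noise.envelope = _interp_contour(
                config_a.noise.envelope, config_b.noise.envelope, w
            )
            cfg.noise.rolloff_noise = _interp_scalar(
                config_a.noise.rolloff_noise, config_b.noise.rolloff_noise, w, False
            )
        out.append(cfg)
    return out
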