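"""Reading and writing synthesis configurations (YAML).

A config document is a nested mapping mirroring :class:`SynthConfig`;
every key is optional and defaults to the neutral schwa-like voice at
22050 Hz.  Any time-varying parameter accepts either a bare number (flat
contour) or a list of ``[time, value]`` anchor pairs with normalized
times in [0, 1].  Unknown keys and out-of-range values are rejected with
the offending dotted key path, and parse -> serialize -> parse is the
identity.
"""

from __future__ import annotations

from pathlib import Path

import yaml

from .assembly import BoutSpec, SynthConfig
from .contours import ContourSpec, InvalidSpecError
from .noise import DEFAULT_FLAT_CEILING, NoiseParams
from .source import GlottalSourceParams
from .vocal_tract import Formant, FormantTable, VocalTractParams

__all__ = ["ConfigError", "load_config", "parse_document", "config_to_document", "save_config"]


class ConfigError(ValueError):
    """Configuration file problem; the message names the offending key path."""


_SOURCE_KEYS = {
    "rolloff": (0.0, 120.0),
    "vibrato_freq": (0.0, 1000.0),
    "vibrato_depth": (0.0, 12.0),
    "jitter_depth": (0.0, 12.0),
    "jitter_period": (1e-4, 1.0),
    "shimmer_depth": (0.0, 1.0),
    "attack_len": (0.0, 1.0),
    "am_depth": (0.0, 1.0),
    "am_freq": (0.0, 1000.0),
    "am_shape": (-1.0, 1.0),
    "sub_ratio": (1, 20),
    "sub_depth": (0.0, 120.0),
    "chaos_jitter": (0.0, 12.0),
    "chaos_shimmer": (0.0, 1.0),
}

_TRACT_KEYS = {
    "vtl": (0.5, 500.0),
    "lip_radiation": (-24.0, 24.0),
    "nose_radiation": (-24.0, 24.0),
}

_BOUT_KEYS = {"n_syllables": (1, 1000), "repeat_bout": (1, 100)}

_TOP_KEYS = {
    "bout", "f0_anchors", "ampl_anchors", "mouth", "source", "noise",
    "formants", "tract", "temperature", "male_female", "nonlinear_balance",
    "voiced", "sampling_rate", "seed",
}


def _require_mapping(node, path: str) -> dict:
    if node is None:
        return {}
    if not isinstance(node, dict):
        raise ConfigError(f"{path}: expected a mapping, got {type(node).__name__}")
    return node


def _check_unknown(node: dict, allowed, path: str) -> None:
    for key in node:
        if key not in allowed:
            where = f"{path}.{key}" if path else str(key)
            raise ConfigError(f"unknown key: {where}")


def _number(node: dict, key: str, default, bounds, path: str):
    if key not in node or node[key] is None:
        return default
    v = node[key]
    if isinstance(v, bool) or not isinstance(v, (int, float)):
        raise ConfigError(f"{path}.{key}: expected a number")
    lo, hi = bounds
    if not lo <= v <= hi:
        raise ConfigError(f"{path}.{key}: value {v} outside [{lo}, {hi}]")
    return type(default)(v) if default is not None else float(v)


def _contour(node, path: str, value_scale: str, parameter_id: str) -> ContourSpec:
    try:
        return ContourSpec.from_pairs(node, value_scale=value_scale, parameter_id=parameter_id)
    except (InvalidSpecError, TypeError, ValueError, IndexError) as exc:
        raise ConfigError(f"{path}: {exc}") from exc


def parse_document(doc: dict | None, path: str = "") -> SynthConfig:
    """Validate a config document and build the corresponding SynthConfig."""
    doc = _require_mapping(doc, path or "<root>")
    _check_unknown(doc, _TOP_KEYS, path)

    bout_node = _require_mapping(doc.get("bout"), "bout")
    _check_unknown(bout_node, set(_BOUT_KEYS) | {"syllable_ms", "pause_ms"}, "bout")
    bout = BoutSpec(
        n_syllables=_number(bout_node, "n_syllables", 1, _BOUT_KEYS["n_syllables"], "bout"),
        syllable_len=_contour(
            bout_node.get("syllable_ms", 300.0), "bout.syllable_ms", "linear", "syllable_ms"
        ),
        pause_len=_contour(
            bout_node.get("pause_ms", 100.0), "bout.pause_ms", "linear", "pause_ms"
        ),
        repeat_bout=_number(bout_node, "repeat_bout", 1, _BOUT_KEYS["repeat_bout"], "bout"),
    )

    src_node = _require_mapping(doc.get("source"), "source")
    _check_unknown(src_node, set(_SOURCE_KEYS), "source")
    f0 = _contour(doc.get("f0_anchors", 120.0), "f0_anchors", "log", "f0")
    src_kwargs = {
        key: _number(src_node, key, GlottalSourceParams.__dataclass_fields__[key].default,
                     bounds, "source")
        for key, bounds in _SOURCE_KEYS.items()
    }
    source = GlottalSourceParams(f0_contour=f0, **src_kwargs)

    noise = None
    if "noise" in doc and doc["noise"] is not None:
        noise_node = _require_mapping(doc["noise"], "noise")
        _check_unknown(noise_node, {"envelope_db", "rolloff_noise", "flat_ceiling"}, "noise")
        noise = NoiseParams(
            envelope=_contour(
                noise_node.get("envelope_db", 0.0), "noise.envelope_db", "linear", "noise_db"
            ),
            rolloff_noise=_number(noise_node, "rolloff_noise", 0.0, (-100.0, 10.0), "noise"),
            flat_ceiling=_number(
                noise_node, "flat_ceiling", DEFAULT_FLAT_CEILING, (1.0, 20000.0), "noise"
            ),
        )

    formants = FormantTable()
    for i, item in enumerate(doc.get("formants") or []):
        fpath = f"formants[{i}]"
        item = _require_mapping(item, fpath)
        _check_unknown(item, {"freq", "amp", "width", "zero"}, fpath)
        if "freq" not in item:
            raise ConfigError(f"{fpath}.freq: required")
        width = item.get("width")
        if width is not None and (not isinstance(width, (int, float)) or width <= 0):
            raise ConfigError(f"{fpath}.width: must be a positive number")
        formants.formants.append(
            Formant(
                frequency=_contour(item["freq"], f"{fpath}.freq", "log", "formant"),
                amp_db=_number(item, "amp", 0.0, (-60.0, 60.0), fpath),
                bandwidth_hz=float(width) if width is not None else None,
                is_zero=bool(item.get("zero", False)),
            )
        )

    tract_node = _require_mapping(doc.get("tract"), "tract")
    _check_unknown(tract_node, set(_TRACT_KEYS), "tract")
    vtl = tract_node.get("vtl")
    if vtl is not None:
        lo, hi = _TRACT_KEYS["vtl"]
        if not isinstance(vtl, (int, float)) or not lo <= vtl <= hi:
            raise ConfigError(f"tract.vtl: value {vtl} outside [{lo}, {hi}]")
        vtl = float(vtl)
    tract = VocalTractParams(
        vtl=vtl,
        mouth_contour=_contour(doc.get("mouth", 0.5), "mouth", "linear", "mouth"),
        lip_radiation=_number(tract_node, "lip_radiation", 6.0, _TRACT_KEYS["lip_radiation"], "tract"),
        nose_radiation=_number(tract_node, "nose_radiation", 0.0, _TRACT_KEYS["nose_radiation"], "tract"),
    )

    try:
        return SynthConfig(
            bout=bout,
            source=source,
            noise=noise,
            formants=formants,
            tract=tract,
            temperature=_number(doc, "temperature", 0.05, (0.0, 2.0), ""),
            male_female=_number(doc, "male_female", 0.0, (-1.0, 1.0), ""),
            nonlinear_balance=_number(doc, "nonlinear_balance", 0.0, (0.0, 1.0), ""),
            voiced=bool(doc.get("voiced", True)),
            sampling_rate=_number(doc, "sampling_rate", 22050.0, (4000.0, 192000.0), ""),
            seed=int(_number(doc, "seed", 0, (0, 2**31 - 1), "")),
        )
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc


def load_config(path: str | Path) -> SynthConfig:
    """Load and validate a YAML config file; defaults fill omitted keys."""
    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        doc = yaml.safe_load(p.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse {p}: {exc}") from exc
    return parse_document(doc)


def _contour_out(spec: ContourSpec):
    if len(spec.anchors) == 1:
        return float(spec.anchors[0].value)
    return [[float(a.time), float(a.value)] for a in spec.anchors]


def config_to_document(config: SynthConfig) -> dict:
    """Serialize a SynthConfig to a plain document (inverse of parsing)."""
    doc: dict = {
        "bout": {
            "n_syllables": config.bout.n_syllables,
            "syllable_ms": _contour_out(config.bout.syllable_len),
            "pause_ms": _contour_out(config.bout.pause_len),
            "repeat_bout": config.bout.repeat_bout,
        },
        "f0_anchors": _contour_out(config.source.f0_contour),
        "mouth": _contour_out(config.tract.mouth_contour),
        "source": {k: getattr(config.source, k) for k in _SOURCE_KEYS},
        "tract": {
            "lip_radiation": config.tract.lip_radiation,
            "nose_radiation": config.tract.nose_radiation,
        },
        "temperature": config.temperature,
        "male_female": config.male_female,
        "nonlinear_balance": config.nonlinear_balance,
        "voiced": config.voiced,
        "sampling_rate": config.sampling_rate,
        "seed": config.seed,
    }
    if config.tract.vtl is not None:
        doc["tract"]["vtl"] = config.tract.vtl
    if config.noise is not None:
        doc["noise"] = {
            "envelope_db": _contour_out(config.noise.envelope),
            "rolloff_noise": config.noise.rolloff_noise,
            "flat_ceiling": config.noise.flat_ceiling,
        }
    if config.formants.formants:
        doc["formants"] = []
        for fm in config.formants.formants:
            item = {"freq": _contour_out(fm.frequency)}
            if fm.amp_db:
                item["amp"] = fm.amp_db
            if fm.bandwidth_hz is not None:
                item["width"] = fm.bandwidth_hz
            if fm.is_zero:
                item["zero"] = True
            doc["formants"].append(item)
    return doc


def save_config(config: SynthConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_document(config), sort_keys=False))
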