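"""Configuration parsing, unit handling and the preset registry.

Configs are YAML mappings with a ``motif`` name, a ``params`` block and one
or more allosteric ``tf`` blocks; concentration-valued fields accept unit
suffixes (M, mM, uM/µM, nM, pM) and are normalised to molar on load.
Unknown keys are rejected with an error naming the offending key.
"""

from __future__ import annotations

import importlib.resources
import math
import re
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .allostery import AllostericTF
from .circuits import (
    AutoActivationParams,
    CoherentFFLParams,
    IncoherentFFLParams,
    HillAutoParams,
    MutualRepressionParams,
)

__all__ = [
    "ConfigError",
    "RunConfig",
    "parse_concentration",
    "load_config",
    "get_preset",
    "preset_params",
    "preset_tf",
    "list_presets",
]


class ConfigError(ValueError):
    pass


_UNITS = {"M": 1.0, "mM": 1e-3, "uM": 1e-6, "µM": 1e-6, "nM": 1e-9, "pM": 1e-12}
_CONC_RE = re.compile(r"^\s*([-+0-9.eE]+)\s*(M|mM|uM|µM|nM|pM)?\s*$")


def parse_concentration(value) -> float:
    """Parse a concentration into molar: numbers pass through, strings may
    carry a unit suffix ('5uM' -> 5e-6)."""
    if isinstance(value, (int, float)):
        out = float(value)
    else:
        m = _CONC_RE.match(str(value))
        if not m:
            raise ConfigError(f"cannot parse concentration {value!r}")
        out = float(m.group(1)) * _UNITS.get(m.group(2) or "M", 1.0)
    if not (out >= 0 and math.isfinite(out)):
        raise ConfigError(f"concentration must be finite and >= 0, got {value!r}")
    return out


def _build_tf(block) -> AllostericTF:
    if not isinstance(block, dict):
        raise ConfigError(f"tf block must be a mapping, got {block!r}")
    allowed = {"kind", "K_A", "K_I", "eps", "n_sites"}
    unknown = set(block) - allowed
    if unknown:
        raise ConfigError(f"unknown tf keys: {sorted(unknown)}")
    try:
        return AllostericTF(
            K_A=parse_concentration(block["K_A"]),
            K_I=parse_concentration(block["K_I"]),
            eps=float(block["eps"]),
            n_sites=int(block.get("n_sites", 2)),
        )
    except KeyError as e:
        raise ConfigError(f"tf block missing key {e.args[0]!r}") from e


_MOTIF_FIELDS = {
    "auto_activation": {"r0", "r1", "r2", "omega"},
    "auto_activation_dimensional": {"r0", "r1", "r2", "omega", "gamma", "Kd"},
    "hill_auto": {"n", "r0", "r2", "Kd_eff", "gamma"},
    "mutual_repression": {"rbar", "omega1", "omega2", "Kratio"},
    "coherent_ffl": {"r0Y", "r1Y", "r0Z", "r1Z", "r2Z", "omega", "KXZ", "KYZ", "Xbar"},
    "incoherent_ffl": {"r0Y", "r1Y", "r0Z", "r1Z", "omega", "KXZ", "KYZ", "Xbar"},
}


@dataclass
class RunConfig:
    """A validated analysis configuration.

    ``params`` is the motif parameter object (already carrying its tf
    blocks); ``raw_params`` keeps the dimensional extras (gamma, Kd) of the
    dimensional auto-activation motif; ``protocol`` and ``analysis`` are
    normalised mappings (concentrations in molar).
    """

    motif: str
    params: object
    raw_params: dict = field(default_factory=dict)
    protocol: dict = field(default_factory=dict)
    analysis: dict = field(default_factory=dict)
    output: dict = field(default_factory=dict)


def _normalise_protocol(proto: dict) -> dict:
    out = dict(proto)
    for key, val in proto.items():
        if key.startswith("c") or key in ("cX_high", "cX_low", "cY"):
            out[key] = parse_concentration(val)
    return out


def load_config(source) -> RunConfig:
    """Load and validate a config from a path, YAML string, or mapping."""
    if isinstance(source, (str, Path)) and not isinstance(source, dict):
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text)
    else:
        data = source
    if not isinstance(data, dict):
        raise ConfigError("config must be a mapping")

    allowed_top = {"motif", "params", "tf", "tf1", "tf2", "tfX", "tfY",
                   "protocol", "analysis", "output", "kind"}
    unknown = set(data) - allowed_top
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")

    motif = data.get("motif")
    if motif not in _MOTIF_FIELDS:
        raise ConfigError(
            f"unknown or missing motif {motif!r}; choose from {sorted(_MOTIF_FIELDS)}"
        )
    pblock = dict(data.get("params") or {})
    unknown = set(pblock) - _MOTIF_FIELDS[motif]
    if unknown:
        raise ConfigError(f"unknown {motif} parameter keys: {sorted(unknown)}")

    def tf_of(key, fallback="tf"):
        block = data.get(key) or data.get(fallback)
        if block is None:
            return AllostericTF(140e-6, 530e-9, 4.5, 2)
        if isinstance(block, str):
            block = get_preset(block)
        return _build_tf(block)

    raw: dict = {}
    try:
        if motif == "auto_activation":
            params = AutoActivationParams(
                r0=float(pblock["r0"]), r1=float(pblock["r1"]),
                r2=float(pblock["r2"]), omega=float(pblock["omega"]),
                tf=tf_of("tf"),
            )
        elif motif == "auto_activation_dimensional":
            gamma = float(pblock.pop("gamma"))
            Kd = parse_concentration(pblock.pop("Kd"))
            raw = {"gamma": gamma, "Kd": Kd}
            params = AutoActivationParams(
                r0=float(pblock["r0"]) / (gamma * Kd * 1e6),
                r1=float(pblock["r1"]) / (gamma * Kd * 1e6),
                r2=float(pblock["r2"]) / (gamma * Kd * 1e6),
                omega=float(pblock["omega"]),
                tf=tf_of("tf"),
            )
        elif motif == "hill_auto":
            params = HillAutoParams(
                n=float(pblock["n"]), r0=float(pblock["r0"]), r2=float(pblock["r2"]),
                Kd_eff=parse_concentration(pblock["Kd_eff"]),
                gamma=float(pblock["gamma"]), tf=tf_of("tf"),
            )
        elif motif == "mutual_repression":
            params = MutualRepressionParams(
                rbar=float(pblock["rbar"]), omega1=float(pblock["omega1"]),
                omega2=float(pblock["omega2"]),
                Kratio=float(pblock.get("Kratio", 1.0)),
                tf1=tf_of("tf1"), tf2=tf_of("tf2"),
            )
        elif motif == "coherent_ffl":
            params = CoherentFFLParams(
                r0Y=float(pblock["r0Y"]), r1Y=float(pblock["r1Y"]),
                r0Z=float(pblock["r0Z"]), r1Z=float(pblock["r1Z"]),
                r2Z=float(pblock["r2Z"]), omega=float(pblock["omega"]),
                KXZ=float(pblock.get("KXZ", 1.0)), KYZ=float(pblock.get("KYZ", 1.0)),
                Xbar=float(pblock.get("Xbar", 1.0)),
                tfX=tf_of("tfX"), tfY=tf_of("tfY"),
            )
        else:  # incoherent_ffl
            params = IncoherentFFLParams(
                r0Y=float(pblock["r0Y"]), r1Y=float(pblock["r1Y"]),
                r0Z=float(pblock["r0Z"]), r1Z=float(pblock["r1Z"]),
                omega=float(pblock["omega"]),
                KXZ=float(pblock.get("KXZ", 1.0)), KYZ=float(pblock.get("KYZ", 1.0)),
                Xbar=float(pblock.get("Xbar", 1.0)),
                tfX=tf_of("tfX"), tfY=tf_of("tfY"),
            )
    except KeyError as e:
        raise ConfigError(f"{motif} config missing parameter {e.args[0]!r}") from e

    return RunConfig(
        motif=motif,
        params=params,
        raw_params=raw,
        protocol=_normalise_protocol(dict(data.get("protocol") or {})),
        analysis=dict(data.get("analysis") or {}),
        output=dict(data.get("output") or {}),
    )


# ---------------------------------------------------------------------------
# preset registry
# ---------------------------------------------------------------------------

_PRESETS: dict | None = None


def _registry() -> dict:
    global _PRESETS
    if _PRESETS is None:
        text = (importlib.resources.files("inducekit") / "presets.yaml").read_text()
        _PRESETS = yaml.safe_load(text)
    return _PRESETS


def list_presets() -> list[str]:
    return sorted(_registry())


def get_preset(name: str) -> dict:
    """Return the raw preset mapping for ``name``."""
    reg = _registry()
    if name not in reg:
        raise ConfigError(f"unknown preset {name!r}; available: {list_presets()}")
    block = dict(reg[name])
    # resolve tf-by-name references
    for key in ("tf", "tf1", "tf2", "tfX", "tfY"):
        if isinstance(block.get(key), str):
            block[key] = dict(reg[block[key]])
    return block


def preset_tf(name: str = "tf_default") -> AllostericTF:
    return _build_tf(get_preset(name))


def preset_config(name: str) -> RunConfig:
    """Fully resolved RunConfig for a motif preset."""
    block = get_preset(name)
    if block.get("kind") == "tf":
        raise ConfigError(f"preset {name!r} is a tf block, not a motif config")
    return load_config(block)


def preset_params(name: str):
    """Motif parameter object for a preset (convenience wrapper)."""
    return preset_config(name).params
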