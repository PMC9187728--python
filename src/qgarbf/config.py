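"""Run configuration: TOML/JSON loading and deterministic seed fan-out."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

from .optimizers import GAConfig, QGAConfig
from .rbf import RBFConfig
from .synthetic import ExperimentDesign, GroundTruthParams

__all__ = [
    "derive_seed",
    "load_config",
    "design_from_dict",
    "params_from_dict",
    "rbf_config_from_dict",
    "qga_config_from_dict",
    "ga_config_from_dict",
]


def derive_seed(global_seed: int, step: str) -> int:
    """Deterministic per-step seed: blake2s of "<seed>:<step>", 31 bits."""
    digest = hashlib.blake2s(f"{global_seed}:{step}".encode()).digest()
    return int.from_bytes(digest[:4], "little") & 0x7FFFFFFF


def load_config(path) -> dict:
    """Read a TOML (preferred) or JSON configuration file."""
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    if path.suffix.lower() == ".json":
        return json.loads(text)
    import tomllib

    return tomllib.loads(text)


def design_from_dict(d: dict | None) -> ExperimentDesign:
    d = dict(d or {})
    base = ExperimentDesign()
    kwargs = {}
    if "temperatures" in d:
        kwargs["temperatures"] = tuple(float(x) for x in d["temperatures"])
    if d.pop("sixteen_levels", False):
        base = base.with_16_levels()
    if "ppfd_levels" in d:
        kwargs["ppfd_levels"] = tuple(float(x) for x in d["ppfd_levels"])
    else:
        kwargs["ppfd_levels"] = base.ppfd_levels
    if "blue_ratios" in d:
        kwargs["blue_ratios"] = tuple(float(x) for x in d["blue_ratios"])
    if "replicates" in d:
        kwargs["replicates"] = int(d["replicates"])
    from dataclasses import replace

    return replace(base, **kwargs)


def params_from_dict(d: dict | None, seed: int | None = None) -> GroundTruthParams:
    d = dict(d or {})
    if seed is not None:
        d["seed"] = seed
    return GroundTruthParams(**d)


def rbf_config_from_dict(d: dict | None, seed: int | None = None) -> RBFConfig:
    d = dict(d or {})
    if seed is not None:
        d["seed"] = seed
    return RBFConfig(**d)


def qga_config_from_dict(d: dict | None, seed: int | None = None) -> QGAConfig:
    d = dict(d or {})
    if seed is not None:
        d["seed"] = seed
    return QGAConfig(**d)


def ga_config_from_dict(d: dict | None, seed: int | None = None) -> GAConfig:
    d = dict(d or {})
    if seed is not None:
        d["seed"] = seed
    return GAConfig(**d)
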