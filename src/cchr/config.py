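"""Run configuration files and manifests.

A run config is a YAML or JSON document with up to five blocks —
``synthetic``, ``network``, ``loss``, ``train``, ``eval`` — each mapping
onto the corresponding dataclass; omitted keys take the package
defaults. Every CLI command writes a ``manifest.json`` next to its
outputs holding the fully resolved configuration, the seed, the artifact
paths and a deterministic fingerprint, which together are sufficient to
reproduce the outputs bit-for-bit.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import yaml

from . import __version__
from .evaluation import EvalConfig
from .network import HashingNetworkSpec
from .objectives import LossConfig
from .synthetic import SyntheticConfig
from .training import TrainConfig, config_fingerprint

__all__ = ["load_config", "resolve_configs", "write_manifest"]

_BLOCKS = ("synthetic", "network", "loss", "train", "eval")


class ConfigError(ValueError):
    """A run config file is invalid; the message names the offending key."""


def load_config(path: str | Path | None) -> dict:
    """Load a YAML/JSON run config; ``None`` yields an empty config."""
    if path is None:
        return {}
    path = Path(path)
    with open(path) as fh:
        text = fh.read()
    data = yaml.safe_load(text) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"{path}: top level must be a mapping")
    unknown = set(data) - set(_BLOCKS)
    if unknown:
        raise ConfigError(f"{path}: unknown config block(s) {sorted(unknown)}")
    return data


def _build(cls, block: dict, name: str, **overrides):
    merged = dict(block or {})
    merged.update({k: v for k, v in overrides.items() if v is not None})
    if "class_proportions" in merged and merged["class_proportions"] is not None:
        merged["class_proportions"] = tuple(merged["class_proportions"])
    try:
        return cls(**merged)
    except TypeError as exc:
        raise ConfigError(f"config block '{name}': {exc}") from None
    except ValueError as exc:
        raise ConfigError(f"config block '{name}': {exc}") from None


def resolve_configs(
    raw: dict,
    seed: int | None = None,
    code_length: int | None = None,
) -> tuple[SyntheticConfig, HashingNetworkSpec, LossConfig, TrainConfig, EvalConfig]:
    """Materialise the five config dataclasses from a raw config dict.

    ``seed`` (one top-level knob) overrides the synthetic, network-init
    and training seeds; ``code_length`` overrides the network's L.
    """
    syn_block = dict(raw.get("synthetic") or {})
    syn_block.setdefault("n_clips", 3000)
    syn = _build(SyntheticConfig, syn_block, "synthetic", seed=seed)
    spec = _build(
        HashingNetworkSpec, raw.get("network") or {}, "network",
        init_seed=seed, code_length=code_length,
    )
    loss = _build(LossConfig, raw.get("loss") or {}, "loss")
    train_block = dict(raw.get("train") or {})
    train_block.pop("loss", None)
    train = _build(TrainConfig, train_block, "train", seed=seed)
    train = TrainConfig(**{**{k: getattr(train, k) for k in (
        "learning_rate", "batch_size", "epochs", "seed", "code_length")},
        "loss": loss})
    ev = _build(EvalConfig, raw.get("eval") or {}, "eval")
    return syn, spec, loss, train, ev


def write_manifest(
    out_dir: str | Path,
    command: str,
    resolved: dict,
    seed: int,
    artifact_paths: dict[str, str],
    config_path: str | None = None,
) -> dict:
    """Write ``manifest.json`` describing one command's reproducible run."""
    def canon(x):
        if hasattr(x, "__dataclass_fields__"):
            return asdict(x)
        return x

    resolved_plain = {k: canon(v) for k, v in resolved.items()}
    manifest = {
        "command": command,
        "config_path": config_path,
        "resolved_config": resolved_plain,
        "seed": seed,
        "artifact_paths": artifact_paths,
        "tool_version": __version__,
        "config_fingerprint": config_fingerprint(resolved_plain),
    }
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    # "run_manifest.json": a dataset directory keeps its own manifest.json
    with open(out_dir / "run_manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
        fh.write("\n")
    return manifest
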