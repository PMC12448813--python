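"""YAML configuration and run-manifest handling.

A single YAML file carries the sections ``data``, ``model``,
``contrastive``, ``transe``, ``eval`` and ``synthetic``; command-line flags
override YAML values.  Every command writes a ``manifest.json`` into its
output directory recording the configuration snapshot, sha256 digests of
the inputs, the seed, the package version, per-stage wall times and the
produced files — enough to re-run or audit the invocation.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from pathlib import Path

import yaml

from .contrastive import ContrastiveConfig
from .model import ModelConfig
from .synthetic import SyntheticSpec
from .transe import TransEConfig

__all__ = ["load_config", "model_config_from_dict", "synthetic_spec_from_dict",
           "StageTimer", "write_manifest", "file_digest"]


def load_config(path: str | Path | None) -> dict:
    if path is None:
        return {}
    with open(path, "r", encoding="utf-8") as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: top-level YAML must be a mapping")
    return cfg


def _filtered(cls, mapping: dict) -> dict:
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - names
    if unknown:
        raise ValueError(f"unknown {cls.__name__} keys: {sorted(unknown)}")
    return dict(mapping)


def model_config_from_dict(cfg: dict, **overrides) -> ModelConfig:
    """Build a :class:`ModelConfig` from YAML sections plus CLI overrides."""
    model = _filtered(ModelConfig, dict(cfg.get("model", {})))
    model.pop("contrastive", None)
    model.pop("transe", None)
    contrastive = ContrastiveConfig(**_filtered(ContrastiveConfig, cfg.get("contrastive", {})))
    transe = TransEConfig(**_filtered(TransEConfig, cfg.get("transe", {})))
    model["contrastive"] = contrastive
    model["transe"] = transe
    for key, value in overrides.items():
        if value is not None:
            model[key] = value
    return ModelConfig(**model)


def synthetic_spec_from_dict(cfg: dict, **overrides) -> SyntheticSpec:
    spec = _filtered(SyntheticSpec, dict(cfg.get("synthetic", {})))
    for key, value in overrides.items():
        if value is not None:
            spec[key] = value
    return SyntheticSpec(**spec)


def file_digest(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for block in iter(lambda: fh.read(1 << 20), b""):
            h.update(block)
    return h.hexdigest()


class StageTimer:
    """Records wall time per named stage for the manifest."""

    def __init__(self) -> None:
        self.times: dict[str, float] = {}

    def __call__(self, name: str):
        timer = self

        class _Ctx:
            def __enter__(self_inner):
                self_inner.t0 = time.perf_counter()

            def __exit__(self_inner, *exc):
                timer.times[name] = round(time.perf_counter() - self_inner.t0, 4)

        return _Ctx()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, Path):
        return str(obj)
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_manifest(
    out_dir: str | Path,
    command: str,
    config,
    seed: int,
    inputs: dict[str, str | Path] | None = None,
    outputs: list[str] | None = None,
    stage_times: dict[str, float] | None = None,
    extra: dict | None = None,
) -> Path:
    from . import __version__

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "config": _jsonable(config),
        "input_digests": {
            name: file_digest(p) for name, p in (inputs or {}).items()
        },
        "stage_wall_times_s": stage_times or {},
        "outputs": sorted(outputs or []),
    }
    if extra:
        manifest.update(_jsonable(extra))
    path = out_dir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path
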