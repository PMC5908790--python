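"""File formats, YAML configuration, and run manifests.

All tables are UTF-8 comma-separated CSV with a header row; concentrations
are serialized in nM and in-vivo series use day 0 = randomization. Every
CLI run writes a ``manifest.json`` recording input checksums, the config
snapshot, the seed, and the package version, sufficient to reproduce the
outputs byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
import yaml

from .simulate import ComboConfig, ConfigError, PanelConfig, XenoConfig

__all__ = [
    "RunConfig",
    "load_yaml",
    "panel_config_from_mapping",
    "combo_config_from_mapping",
    "xeno_config_from_mapping",
    "sha256_file",
    "write_manifest",
    "save_table",
]


@dataclass(frozen=True)
class RunConfig:
    """Top-level run options shared by the CLI subcommands."""

    seed: int = 0
    outdir: str = "."
    duration_days: int = 6
    summary_level: str | None = None
    same_level_for_both: bool = True
    min_mutants: int = 1
    control_group: str = "vehicle"

    def validate(self):
        if self.duration_days not in (3, 6):
            raise ConfigError("duration_days: must be 3 or 6")


def load_yaml(path: str | Path) -> dict:
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return data or {}


def _from_mapping(cls, mapping: dict, section: str):
    """Build a config dataclass from a YAML mapping, naming bad fields."""
    allowed = {f.name for f in dataclasses.fields(cls)}
    unknown = set(mapping) - allowed
    if unknown:
        raise ConfigError(f"{section}.{sorted(unknown)[0]}: unknown field")
    kwargs = dict(mapping)
    for key in ("agents", "ratio", "v0_mm3"):
        if key in kwargs and isinstance(kwargs[key], list):
            kwargs[key] = tuple(kwargs[key])
    try:
        cfg = cls(**kwargs)
    except TypeError as exc:  # pragma: no cover - defensive
        raise ConfigError(f"{section}: {exc}") from exc
    cfg.validate()
    return cfg


def panel_config_from_mapping(mapping: dict) -> PanelConfig:
    return _from_mapping(PanelConfig, mapping, "panel")


def combo_config_from_mapping(mapping: dict) -> ComboConfig:
    return _from_mapping(ComboConfig, mapping, "combo")


def xeno_config_from_mapping(mapping: dict) -> XenoConfig:
    return _from_mapping(XenoConfig, mapping, "xeno")


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(dataclasses.asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_manifest(
    outdir: str | Path,
    command: str,
    inputs: dict[str, str | Path],
    config,
    seed: int | None,
    warnings_list: list[str] | None = None,
) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "command": command,
        "package_version": __version__,
        "seed": seed,
        "inputs": {
            name: {"path": str(p), "sha256": sha256_file(p)}
            for name, p in inputs.items()
        },
        "config": _jsonable(config),
        "warnings": warnings_list or [],
    }
    path = outdir / "manifest.json"
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return path


def save_table(df: pd.DataFrame, path: str | Path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)
    return path
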