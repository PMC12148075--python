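"""Configuration loading, result writing, and run manifests."""

from __future__ import annotations

import datetime as _dt
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml
from pydantic import ValidationError

from .model_core import DonorPhenotype, SimulationConfig

__all__ = [
    "ConfigError",
    "load_config",
    "save_config",
    "load_donors_csv",
    "RunManifest",
    "write_results",
]

DONOR_CSV_COLUMNS = [
    "donor_id", "pct_pd1_cd4", "pct_pd1_cd8", "geo_mean_pd1",
    "pct_pdl1_mono", "geo_mean_pdl1", "mlr_days",
]


class ConfigError(ValueError):
    """Invalid or malformed configuration file."""


def load_config(path) -> SimulationConfig:
    """Load and schema-validate a YAML/JSON simulation config.

    Defaults are applied for omitted fields; unknown keys are rejected with
    a message naming the offending field.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigError(f"config file not found: {path}")
    text = path.read_text()
    data = yaml.safe_load(text)
    if not isinstance(data, Mapping):
        raise ConfigError(f"{path}: expected a mapping at top level")
    try:
        return SimulationConfig.model_validate(data)
    except ValidationError as exc:
        fields = ", ".join(".".join(str(p) for p in e["loc"]) or "<root>" for e in exc.errors())
        raise ConfigError(f"{path}: invalid config (fields: {fields})\n{exc}") from exc


def save_config(config: SimulationConfig, path) -> None:
    """Write a config as YAML; ``load_config(save_config(c)) == c``."""
    Path(path).write_text(yaml.safe_dump(config.model_dump(mode="json"), sort_keys=True))


def load_donors_csv(path) -> list[DonorPhenotype]:
    df = pd.read_csv(path)
    missing = [c for c in DONOR_CSV_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigError(f"{path}: donor CSV missing columns {missing}")
    donors = []
    for _, row in df.iterrows():
        try:
            donors.append(DonorPhenotype(**{c: row[c] for c in DONOR_CSV_COLUMNS}))
        except ValidationError as exc:
            raise ConfigError(f"{path}: invalid donor row {row['donor_id']}: {exc}") from exc
    return donors


def _config_hash(config: SimulationConfig) -> str:
    payload = json.dumps(config.model_dump(mode="json"), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


@dataclass
class RunManifest:
    """Provenance record sufficient to re-run a pipeline bit-identically."""

    config_hash: str
    seeds: list[int]
    software_version: str
    started: str = ""
    finished: str = ""
    outputs: dict[str, str] = field(default_factory=dict)  # name -> file path

    @classmethod
    def start(cls, config: SimulationConfig, seeds) -> "RunManifest":
        from . import __version__

        return cls(
            config_hash=_config_hash(config),
            seeds=[int(s) for s in seeds],
            software_version=__version__,
            started=_dt.datetime.now(_dt.timezone.utc).isoformat(),
        )

    def to_json(self, path) -> None:
        self.finished = self.finished or _dt.datetime.now(_dt.timezone.utc).isoformat()
        Path(path).write_text(json.dumps(self.__dict__, indent=2, sort_keys=True))


def write_results(tables: Mapping[str, pd.DataFrame], manifest: RunManifest, outdir) -> dict[str, str]:
    """Write each table as CSV with stable column order plus the manifest.

    Returns the file registry (also recorded in the manifest).  Re-running
    with the same tables produces byte-identical CSVs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    registry: dict[str, str] = {}
    for name, df in tables.items():
        path = outdir / f"{name}.csv"
        try:
            df.to_csv(path, index=False)
        except OSError as exc:
            raise OSError(f"failed writing {path}: {exc}") from exc
        registry[name] = str(path)
    manifest.outputs = dict(registry)
    manifest_path = outdir / "manifest.json"
    manifest.to_json(manifest_path)
    registry["manifest"] = str(manifest_path)
    return registry
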