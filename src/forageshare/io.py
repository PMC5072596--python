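"""Configuration files, result writers and run manifests.

Configurations are YAML mappings with sections mirroring the simulator's
parameter groups::

    preset: S3            # optional starting point
    domain:
      size: 1.0
    prey:
      n_patches: 4
      prey_per_patch: 20
      patch_radius: 0.05
      landscape_rate: 0.05
    predators:
      n: 2
      sensing_radius: 0.08
      speed: 1.0
      consumption_rate: 10.0
      turning_rate: 6.0
    simulation:
      dt: 0.01
      n_steps: 40000
      burn_in: 10000
      seed: 0
    network:              # exactly one of:
      full: 0.5           #   fully connected with homogeneous tie strength
      # groups: [2, 28]   #   all-or-nothing ties within groups
      # matrix_csv: w.csv #   explicit symmetric matrix

Unknown keys are rejected by name. Results round-trip through CSV/JSON at
full float precision, and every output file is recorded in a RunManifest
keyed by a canonical hash of the configuration.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import math
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from forageshare import __version__
from forageshare.abm import AbmConfig, SocialNetwork
from forageshare.presets import load_preset

__all__ = [
    "ConfigError",
    "RunManifest",
    "load_config",
    "write_results",
    "config_hash",
    "spawn_seeds",
]


class ConfigError(ValueError):
    """A configuration file is malformed or violates a constraint."""


_SECTIONS: dict[str, dict[str, str]] = {
    "domain": {"size": "domain_size"},
    "prey": {
        "n_patches": "n_patches",
        "prey_per_patch": "prey_per_patch",
        "patch_radius": "patch_radius",
        "landscape_rate": "landscape_rate",
    },
    "predators": {
        "n": "n_predators",
        "sensing_radius": "sensing_radius",
        "speed": "speed",
        "consumption_rate": "consumption_rate",
        "turning_rate": "turning_rate",
    },
    "simulation": {
        "dt": "dt",
        "n_steps": "n_steps",
        "burn_in": "burn_in",
        "seed": "seed",
    },
}


def _build_network(spec, n: int, base_dir: Path) -> SocialNetwork:
    if not isinstance(spec, dict) or len(spec) != 1:
        raise ConfigError(
            "network must have exactly one of the keys 'full', 'groups', 'matrix_csv'"
        )
    (kind, value), = spec.items()
    if kind == "full":
        return SocialNetwork.full(n, float(value))
    if kind == "groups":
        sizes = [int(k) for k in value]
        if sum(sizes) != n:
            raise ConfigError(f"network groups {sizes} do not sum to n={n}")
        return SocialNetwork.from_groups(sizes)
    if kind == "matrix_csv":
        w = pd.read_csv(base_dir / str(value), header=None).to_numpy(dtype=float)
        return SocialNetwork(w)
    raise ConfigError(f"unknown network kind {kind!r}")


def load_config(path, overrides: dict | None = None) -> AbmConfig:
    """Load and validate a simulator configuration.

    ``path`` is a YAML file (or a bare preset name such as ``"S3"``);
    ``overrides`` maps flat field names (``lam``, ``n_predators``, ...) onto
    replacement values and wins over both preset and file. Raises
    ``ConfigError`` naming the offending field on any problem.
    """
    overrides = dict(overrides or {})
    path = Path(path)
    if not path.exists() and path.suffix == "" and str(path) == path.name:
        # bare preset name
        try:
            return load_preset(path.name, **overrides)
        except (KeyError, TypeError, ValueError) as exc:
            raise ConfigError(str(exc))
    try:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    except FileNotFoundError:
        raise ConfigError(f"config file not found: {path}")
    except yaml.YAMLError as exc:
        raise ConfigError(f"config file {path} is not valid YAML: {exc}")
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError(f"config root must be a mapping, got {type(raw).__name__}")

    params: dict = {}
    preset = raw.pop("preset", None)
    if preset is not None:
        base = load_preset(str(preset))
        params = {f.name: getattr(base, f.name) for f in dataclasses.fields(AbmConfig)}
    network_spec = raw.pop("network", None)
    for section, keys in _SECTIONS.items():
        block = raw.pop(section, {}) or {}
        if not isinstance(block, dict):
            raise ConfigError(f"section {section!r} must be a mapping")
        for key, value in block.items():
            if key not in keys:
                raise ConfigError(
                    f"unknown key {key!r} in section {section!r}; "
                    f"expected one of {sorted(keys)}"
                )
            params[keys[key]] = value
    if raw:
        raise ConfigError(f"unknown top-level keys: {sorted(raw)}")

    lam = overrides.pop("lam", None)
    valid_fields = {f.name for f in dataclasses.fields(AbmConfig)}
    for key, value in overrides.items():
        if key not in valid_fields:
            raise ConfigError(f"unknown override {key!r}")
        params[key] = value
    n = int(params.get("n_predators", AbmConfig.n_predators))
    if lam is not None:
        params["network"] = SocialNetwork.full(n, float(lam))
    elif network_spec is not None:
        params["network"] = _build_network(network_spec, n, path.parent)
    elif params.get("network") is not None and params["network"].n != n:
        params["network"] = SocialNetwork.full(n, 0.0)
    try:
        return AbmConfig(**params)
    except ValueError as exc:
        raise ConfigError(str(exc))


def config_hash(config: AbmConfig) -> str:
    """Canonical sha256 of a configuration, stable under key reordering."""
    d = dataclasses.asdict(config)
    d["network"] = np.asarray(config.network.tie_strengths).tolist()
    blob = json.dumps(d, sort_keys=True, default=float)
    return hashlib.sha256(blob.encode()).hexdigest()


def spawn_seeds(master_seed: int, n: int) -> list[np.random.SeedSequence]:
    """Independent child seed sequences from one master seed.

    Uses the SeedSequence spawning tree, so growing ``n`` later extends the
    list without reshuffling earlier replicate streams.
    """
    return np.random.SeedSequence(master_seed).spawn(n)


@dataclass
class RunManifest:
    """Reproducibility record: config hash, seeds, version and outputs."""

    config_hash: str
    seeds: list[int]
    code_version: str = __version__
    created: str = field(
        default_factory=lambda: datetime.now(timezone.utc).isoformat()
    )
    outputs: list[str] = field(default_factory=list)

    def add_output(self, path) -> None:
        self.outputs.append(str(path))

    def write(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def write_results(
    records,
    path,
    format: str = "csv",
    fieldnames: list[str] | None = None,
    manifest: RunManifest | None = None,
) -> Path:
    """Write homogeneous result records to CSV or JSON.

    ``records`` is a list of flat dicts (or a DataFrame). CSV output uses
    ``repr``-precision floats so a round-trip read returns values equal to
    1e-12 or better. The manifest, if given, records the output path.
    """
    path = Path(path)
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        records = list(records)
        if records:
            keys = set(records[0])
            if any(set(r) != keys for r in records):
                raise ValueError("records are not homogeneous")
        df = pd.DataFrame(records, columns=fieldnames if not records else None)
    if format == "csv":
        df.to_csv(path, index=False)
    elif format == "json":
        with open(path, "w") as fh:
            json.dump(df.to_dict(orient="records"), fh, indent=2,
                      default=lambda x: None if (isinstance(x, float) and math.isnan(x)) else float(x))
    else:
        raise ValueError(f"unknown format {format!r}")
    if manifest is not None:
        manifest.add_output(path)
    return path
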