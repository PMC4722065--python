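"""Configuration files, result tables and run manifests.

Config files are YAML with optional blocks ``seed``, ``worlds``, ``routes``,
``eye_grid``, ``sectors`` and ``render``; an empty file yields the full
default protocol.  Unknown keys are rejected with the offending key named.

Result records round-trip through CSV with a typed header comment; run
manifests capture the config snapshot, package version, seed and SHA-256
checksums of every output so a run can be verified and reproduced.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .experiment import SweepConfig
from .worldgen import WorldConfig

__all__ = [
    "ConfigError",
    "load_config",
    "write_results",
    "read_results",
    "RunManifest",
]


class ConfigError(ValueError):
    pass


_RESULT_DTYPES = {
    "world_id": "int64",
    "world_type": "string",
    "route_id": "int64",
    "route_direction": "float64",
    "x": "float64",
    "y": "float64",
    "along_m": "float64",
    "displacement_m": "float64",
    "side": "string",
    "fov": "float64",
    "px": "int64",
    "n_sectors": "int64",
    "heading": "float64",
    "directional_error": "float64",
    "min_value": "float64",
    "signal_strength": "float64",
    "best_memory_index": "int64",
}


def _take(block: dict, allowed: dict, context: str) -> dict:
    """Pop known keys (renaming per ``allowed``); reject anything left."""
    out = {}
    for key, target in allowed.items():
        if key in block:
            out[target] = block.pop(key)
    if block:
        raise ConfigError(f"unknown key {sorted(block)[0]!r} in {context!r} block")
    return out


def load_config(path) -> tuple[SweepConfig, list[WorldConfig]]:
    """Parse a sweep config file; returns the sweep and its world configs."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config file must contain a mapping")

    sweep_kw: dict = {}
    world_kw: dict = {}
    if "seed" in raw:
        sweep_kw["rng_seed"] = int(raw.pop("seed"))
    extra = set(raw) - {"worlds", "routes", "eye_grid", "sectors", "render"}
    if extra:
        raise ConfigError(f"unknown top-level key {sorted(extra)[0]!r}")
    blocks = {k: dict(raw.get(k) or {}) for k in ("worlds", "routes", "eye_grid", "sectors", "render")}

    wblock = _take(
        blocks["worlds"],
        {
            "types": "world_types",
            "replicates": "replicates_per_type",
            "arena_radius": "arena_radius",
            "tussock_density": "tussock_density",
            "tree_count": "tree_count",
            "tree_ring": "tree_ring",
            "exclusion_radius": "exclusion_radius",
        },
        "worlds",
    )
    for key in ("world_types", "replicates_per_type"):
        if key in wblock:
            sweep_kw[key] = wblock.pop(key)
    world_kw.update(wblock)

    sweep_kw.update(
        _take(blocks["routes"], {"per_world": "routes_per_world"}, "routes")
    )
    sweep_kw.update(
        _take(blocks["eye_grid"], {"fovs": "fov_list", "pxs": "px_list"}, "eye_grid")
    )
    sweep_kw.update(
        _take(
            blocks["sectors"],
            {"counts": "sector_counts", "px": "sector_px", "fov": "sector_fov"},
            "sectors",
        )
    )
    sweep_kw.update(
        _take(
            blocks["render"],
            {"eye_height": "eye_height", "supersample": "supersample"},
            "render",
        )
    )
    for key in ("fov_list", "px_list", "world_types", "sector_counts"):
        if key in sweep_kw:
            sweep_kw[key] = tuple(
                sweep_kw[key] if isinstance(sweep_kw[key], (list, tuple)) else [sweep_kw[key]]
            )
    if "tree_ring" in world_kw:
        world_kw["tree_ring"] = tuple(world_kw["tree_ring"])

    sweep = SweepConfig(**sweep_kw)
    try:
        sweep.validate()
    except ValueError as exc:
        raise ConfigError(str(exc)) from exc

    ss = np.random.SeedSequence(sweep.rng_seed)
    seeds = ss.generate_state(
        len(sweep.world_types) * sweep.replicates_per_type, dtype=np.uint32
    ) >> np.uint32(1)
    world_cfgs = []
    i = 0
    for wt in sweep.world_types:
        for _ in range(sweep.replicates_per_type):
            cfg = WorldConfig(world_type=wt, rng_seed=int(seeds[i]), **world_kw)
            try:
                cfg.validate()
            except ValueError as exc:
                raise ConfigError(str(exc)) from exc
            world_cfgs.append(cfg)
            i += 1
    return sweep, world_cfgs


def write_results(records: pd.DataFrame, path) -> None:
    """Lossless CSV write of result records (full float precision)."""
    df = records.copy()
    cols = [c for c in _RESULT_DTYPES if c in df.columns] + [
        c for c in df.columns if c not in _RESULT_DTYPES
    ]
    df[cols].to_csv(path, index=False, float_format="%.17g")


def read_results(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed results file {path}: {exc}") from exc
    for col, dtype in _RESULT_DTYPES.items():
        if col in df.columns:
            try:
                df[col] = df[col].astype(dtype)
            except (TypeError, ValueError) as exc:
                raise ValueError(f"column {col!r} in {path} is not {dtype}: {exc}") from exc
    return df


def _sha256(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


@dataclass
class RunManifest:
    """Provenance of one output directory: config, seeds, file checksums."""

    config: dict
    seed: int
    version: str = ""
    stages: dict = field(default_factory=dict)
    checksums: dict = field(default_factory=dict)

    def mark(self, stage: str) -> None:
        self.stages[stage] = time.strftime("%Y-%m-%dT%H:%M:%S")

    def add_file(self, path) -> None:
        path = Path(path)
        self.checksums[path.name] = _sha256(path)

    def write(self, out_dir) -> Path:
        if not self.version:
            from . import __version__

            self.version = __version__
        path = Path(out_dir) / "manifest.json"
        with open(path, "w") as fh:
            json.dump(self.__dict__, fh, indent=1, default=str)
        return path

    @classmethod
    def read(cls, out_dir) -> "RunManifest":
        with open(Path(out_dir) / "manifest.json") as fh:
            return cls(**json.load(fh))

    def verify(self, out_dir) -> bool:
        """True iff every recorded checksum matches the file on disk."""
        out_dir = Path(out_dir)
        return all(
            (out_dir / name).exists() and _sha256(out_dir / name) == digest
            for name, digest in self.checksums.items()
        )
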