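"""File I/O: CSV/YAML readers and writers, result manifests.

Conventions: times in hours, densities in cells/mL, OD dimensionless;
YAML for configuration, CSV for tabular data, JSON for results and run
manifests; UTF-8 throughout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .dynamics import (
    DEFAULT_DILUTION,
    ROLES,
    InteractionMatrix,
    SpeciesParams,
    Trajectory,
    default_community,
)

PLATE_COLUMNS = ("time_h", "well", "od")
PLATEMAP_COLUMNS = ("well", "strain_id", "media_id", "replicate")
TRAJECTORY_COLUMNS = ("time_h", "N_E", "N_Y", "N_B", "cycle")


class SchemaError(ValueError):
    """A file failed schema validation."""


def _require_columns(df: pd.DataFrame, cols: tuple[str, ...], path: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required columns {missing}")


def read_plate_csv(path: str) -> pd.DataFrame:
    """Long-form plate-reader table: time_h, well, od."""
    df = pd.read_csv(path)
    _require_columns(df, PLATE_COLUMNS, path)
    bad = df.index[df["time_h"] < 0]
    if len(bad):
        raise SchemaError(f"{path}: negative time_h at data row {bad[0] + 1}")
    bad = df.index[~np.isfinite(df["od"])]
    if len(bad):
        raise SchemaError(f"{path}: non-finite od at data row {bad[0] + 1}")
    return df


def read_platemap_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, PLATEMAP_COLUMNS, path)
    if df["well"].duplicated().any():
        dup = df["well"][df["well"].duplicated()].iloc[0]
        raise SchemaError(f"{path}: duplicate well {dup!r}")
    return df


def write_trajectories_csv(trajectories: list[Trajectory], path: str) -> None:
    """Concatenate per-cycle trajectories into one table."""
    frames = [
        pd.DataFrame(
            {
                "time_h": t.times,
                "N_E": t.populations[:, 0],
                "N_Y": t.populations[:, 1],
                "N_B": t.populations[:, 2],
                "cycle": t.cycle,
            }
        )
        for t in trajectories
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_trajectory_csv(path: str) -> pd.DataFrame:
    df = pd.read_csv(path)
    _require_columns(df, TRAJECTORY_COLUMNS, path)
    for col in ("N_E", "N_Y", "N_B"):
        bad = df.index[df[col] < 0]
        if len(bad):
            raise SchemaError(f"{path}: negative {col} at data row {bad[0] + 1}")
    bad = df.index[df["time_h"] < 0]
    if len(bad):
        raise SchemaError(f"{path}: negative time_h at data row {bad[0] + 1}")
    return df


def write_fits_csv(fits: pd.DataFrame, path: str) -> None:
    fits.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

DEFAULT_PROTOCOL = {
    "cycle_hours": 24.0,
    "dilution_factor": DEFAULT_DILUTION,
    "n_cycles": 7,
    "equilibration_cycles": 3,
    "invader_density": 1e7,
}


def read_config(path: str) -> dict:
    """Parse a model-parameter YAML into domain objects.

    Expected keys (all optional, defaults applied): ``species`` mapping
    role -> {r, K, N0}; ``alphas`` mapping alpha_* -> value; ``protocol``
    with cycle_hours/dilution_factor/n_cycles/equilibration_cycles/
    invader_density; ``model``; ``threshold``; ``rtol``; ``seed``.
    """
    try:
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
    except yaml.YAMLError as exc:
        raise SchemaError(f"{path}: invalid YAML: {exc}") from exc
    if not isinstance(raw, dict):
        raise SchemaError(f"{path}: top level must be a mapping")

    defaults = {p.role: p for p in default_community()}
    species = []
    spec_raw = raw.get("species", {})
    for role in ROLES:
        entry = spec_raw.get(role, {})
        base = defaults[role]
        try:
            species.append(
                SpeciesParams(
                    role=role,
                    r=float(entry.get("r", base.r)),
                    K=float(entry.get("K", base.K)),
                    N0=float(entry.get("N0", base.N0)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: species {role}: {exc}") from exc
    try:
        alphas = InteractionMatrix(**{
            k: float(v) for k, v in raw.get("alphas", {}).items()
        })
    except (TypeError, ValueError) as exc:
        raise SchemaError(f"{path}: alphas: {exc}") from exc

    protocol = {**DEFAULT_PROTOCOL, **raw.get("protocol", {})}
    return {
        "species": tuple(species),
        "alphas": alphas,
        "protocol": protocol,
        "model": raw.get("model", "freqdep"),
        "threshold": float(raw.get("threshold", 1e4)),
        "rtol": float(raw.get("rtol", 1e-8)),
        "seed": int(raw.get("seed", 0)),
    }


def config_to_yaml_dict(config: dict) -> dict:
    """Serializable form of a parsed config (round-trips via read_config)."""
    return {
        "species": {p.role: {"r": p.r, "K": p.K, "N0": p.N0} for p in config["species"]},
        "alphas": config["alphas"].as_dict(),
        "protocol": config["protocol"],
        "model": config["model"],
        "threshold": config["threshold"],
        "rtol": config["rtol"],
        "seed": config["seed"],
    }


def write_run_manifest(
    path: str, command: str, inputs: list[str], config: dict, seed: int
) -> None:
    """JSON manifest making a CLI run reproducible: inputs, config hash,
    seed and package version."""
    payload = {
        "command": command,
        "inputs": inputs,
        "config": config,
        "config_sha256": hashlib.sha256(
            json.dumps(config, sort_keys=True, default=float).encode()
        ).hexdigest(),
        "seed": seed,
        "version": __version__,
    }
    Path(path).write_text(json.dumps(payload, indent=2, default=float), encoding="utf-8")
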