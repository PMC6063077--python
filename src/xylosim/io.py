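"""Readers and writers for tracheidogram / trajectory CSVs and parameter files.

One tabular dialect everywhere: comma-separated, UTF-8, "." decimal point,
mandatory header, optional ``# key: value`` comment lines carrying metadata
before the header.  Species parameter files are YAML with the same schema as
the bundled fixtures.
"""

from __future__ import annotations

import io as _io
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .cell import CellTrajectory, SpeciesParams
from .errors import MissingColumnError, NegativeTraitError, NonMonotonePositionError
from .fixtures import species_from_dict, species_to_dict
from .ring import SugarCurve, Tracheidogram

__all__ = [
    "read_tracheidogram",
    "write_tracheidogram",
    "write_trajectory",
    "read_species_params",
    "write_species_params",
]

_REQUIRED = ("index", "rel_position", "LA_um2", "LRD_um", "WT_um")
_FLOAT_FMT = "%.6g"


def _format_meta_value(v):
    return json.dumps(v) if isinstance(v, (dict, list)) else v


def write_tracheidogram(tr: Tracheidogram, path) -> None:
    """Write a tracheidogram CSV with metadata as leading # comments."""
    buf = _io.StringIO()
    for k, v in tr.metadata.items():
        buf.write(f"# {k}: {_format_meta_value(v)}\n")
    tr.to_frame().to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def _parse_meta(path) -> dict:
    meta = {}
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line[1:].strip()
            if ":" not in body:
                continue
            key, _, value = body.partition(":")
            value = value.strip()
            try:
                meta[key.strip()] = json.loads(value)
            except (json.JSONDecodeError, ValueError):
                meta[key.strip()] = value
    return meta


def read_tracheidogram(path) -> Tracheidogram:
    """Read a tracheidogram CSV written by :func:`write_tracheidogram`.

    The ``latewood`` column is optional and recomputed from LRD and WT when
    absent.  Violations raise the dedicated error classes (missing column,
    non-monotone positions, negative traits).
    """
    df = pd.read_csv(path, comment="#")
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise MissingColumnError(f"{path}: missing mandatory column(s) {missing}")
    pos = df["rel_position"].to_numpy(dtype=float)
    if np.any(np.diff(pos) <= 0):
        raise NonMonotonePositionError(f"{path}: rel_position must be strictly increasing")
    for col in ("LA_um2", "LRD_um", "WT_um"):
        if np.any(df[col].to_numpy(dtype=float) < 0):
            raise NegativeTraitError(f"{path}: column {col} contains negative values")
    latewood = df["latewood"].to_numpy(dtype=bool) if "latewood" in df.columns else None
    return Tracheidogram(
        rel_position=pos,
        LA=df["LA_um2"].to_numpy(dtype=float),
        LRD=df["LRD_um"].to_numpy(dtype=float),
        WT=df["WT_um"].to_numpy(dtype=float),
        latewood=latewood,
        metadata=_parse_meta(path),
    )


def write_trajectory(traj: CellTrajectory, path) -> None:
    """Write a single-cell trajectory CSV (one row per RK4 step)."""
    buf = _io.StringIO()
    for k, v in (
        ("species", traj.species),
        ("S", traj.S),
        ("dt", traj.config.dt),
        ("t_enl_end", traj.t_enl_end),
        ("t_death", traj.t_death),
        ("completed", traj.completed),
    ):
        buf.write(f"# {k}: {v}\n")
    traj.to_frame().to_csv(buf, index=False, float_format=_FLOAT_FMT)
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


def read_species_params(path) -> tuple[SpeciesParams, SugarCurve | None]:
    """Read a YAML species parameter file; validation errors name the
    violated invariant."""
    with open(path, encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    return species_from_dict(data)


def write_species_params(p: SpeciesParams, path, curve: SugarCurve | None = None) -> None:
    Path(path).write_text(yaml.safe_dump(species_to_dict(p, curve), sort_keys=False), encoding="utf-8")
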