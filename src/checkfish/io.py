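"""Delimited-text readers/writers, configs and the run manifest.

All tables are plain TSV with headers so every intermediate is
inspectable and diff-able.  Readers validate the schema and the domain
invariants (monotone time, in-arena positions, non-negative intensities)
and name the offending rows in errors.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Dict, List, Optional, Union

import numpy as np
import pandas as pd

from .arena import ArenaSpec
from .behavior import Trajectory, TrajectoryError

__all__ = [
    "read_trajectories",
    "write_trajectories",
    "read_nuclei",
    "write_nuclei",
    "RunManifest",
]

TRAJ_COLUMNS = ["animal_id", "group", "day", "session", "t", "x", "y"]
NUCLEI_REQUIRED = [
    "animal_id",
    "treatment",
    "environment",
    "region",
    "slide_id",
    "z_centroid_fraction",
    "size",
    "elongation",
    "counterstain_brightness",
    "intensity_e1_channel",
    "intensity_e2_channel",
]
NUCLEI_BOOL = ["exemplar_weakest_e1", "exemplar_weakest_e2"]


class SchemaError(ValueError):
    """Raised when an input file violates the expected schema."""


def write_trajectories(trajectories: List[Trajectory], path: Union[str, Path]) -> None:
    """Write a trajectory collection as one long TSV table."""
    frames = []
    for tr in trajectories:
        frames.append(
            pd.DataFrame(
                {
                    "animal_id": tr.animal_id,
                    "group": tr.group,
                    "day": tr.day,
                    "session": tr.session,
                    "t": tr.t,
                    "x": tr.x,
                    "y": tr.y,
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_trajectories(
    path: Union[str, Path], arena: Optional[ArenaSpec] = None
) -> List[Trajectory]:
    """Read and validate a trajectory table.

    The file must carry the header ``animal_id group day session t x y``;
    time must be strictly increasing and positions inside the arena
    within each (animal, day, session); violations name the first
    offending row (1-based, excluding the header).
    """
    arena = arena or ArenaSpec()
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in TRAJ_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty trajectory file")
        return []
    out = []
    for (animal, group, day, session), g in df.groupby(
        ["animal_id", "group", "day", "session"], sort=False
    ):
        t = g["t"].to_numpy(float)
        bad = np.flatnonzero(np.diff(t) <= 0)
        if bad.size:
            row = int(g.index[bad[0] + 1]) + 1
            raise SchemaError(f"{path}: time not strictly increasing at row {row}")
        x, y = g["x"].to_numpy(float), g["y"].to_numpy(float)
        oob = (x < 0) | (x > arena.side) | (y < 0) | (y > arena.side)
        if oob.any():
            rows = [int(i) + 1 for i in g.index[oob][:10]]
            raise SchemaError(f"{path}: out-of-arena positions at rows {rows}")
        try:
            out.append(
                Trajectory(str(animal), str(group), int(day), str(session), t, x, y, arena)
            )
        except TrajectoryError as e:
            raise SchemaError(f"{path}: {animal}/{day}/{session}: {e}") from e
    return out


def write_nuclei(nuclei: pd.DataFrame, path: Union[str, Path]) -> None:
    nuclei.to_csv(path, sep="\t", index=False)


def _parse_bool(series: pd.Series, col: str, path) -> pd.Series:
    mapping = {"true": True, "false": False, "1": True, "0": False}
    vals = series.astype(str).str.strip().str.lower()
    bad = ~vals.isin(mapping)
    if bad.any():
        row = int(series.index[bad][0]) + 1
        raise SchemaError(f"{path}: column {col} has non-boolean value at row {row}")
    return vals.map(mapping)


def read_nuclei(path: Union[str, Path]) -> pd.DataFrame:
    """Read and validate a per-nucleus feature table.

    Intensities must be non-negative, sizes positive, z-centroid
    fractions in [0, 1]; exemplar flags are parsed strictly as booleans.
    An empty file yields an empty frame with a warning.
    """
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in NUCLEI_REQUIRED if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    if df.empty:
        warnings.warn(f"{path}: empty nuclei file")
        return df
    for col, lo, hi in (
        ("z_centroid_fraction", 0.0, 1.0),
        ("intensity_e1_channel", 0.0, np.inf),
        ("intensity_e2_channel", 0.0, np.inf),
    ):
        vals = df[col].to_numpy(float)
        bad = (vals < lo) | (vals > hi) | ~np.isfinite(vals)
        if bad.any():
            row = int(df.index[bad][0]) + 1
            raise SchemaError(f"{path}: {col} out of range [{lo}, {hi}] at row {row}")
    if (df["size"].to_numpy(float) <= 0).any():
        row = int(df.index[df["size"] <= 0][0]) + 1
        raise SchemaError(f"{path}: non-positive size at row {row}")
    for col in NUCLEI_BOOL:
        if col in df.columns:
            df[col] = _parse_bool(df[col], col, path)
    for col in ("latent_active_e1", "latent_active_e2", "latent_glia"):
        if col in df.columns:
            df[col] = _parse_bool(df[col], col, path)
    return df


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


@dataclass
class RunManifest:
    """Reproducibility record written by every CLI run.

    Captures the config snapshot, seed, input digests, package version,
    timestamp and per-stage row counts; re-running deterministic stages
    with the same manifest reproduces outputs bit-identically.
    """

    command: str
    seed: Optional[int]
    config: dict = field(default_factory=dict)
    inputs: Dict[str, str] = field(default_factory=dict)
    row_counts: Dict[str, int] = field(default_factory=dict)
    version: str = ""
    timestamp: str = ""

    def add_input(self, path: Union[str, Path]) -> None:
        p = Path(path)
        self.inputs[str(p)] = _digest(p)

    def write(self, path: Union[str, Path]) -> None:
        from . import __version__

        self.version = self.version or __version__
        self.timestamp = self.timestamp or datetime.now(timezone.utc).isoformat()
        Path(path).write_text(json.dumps(self.__dict__, indent=2, default=str) + "\n")
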