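"""Trajectory container and its delimited-text file format.

A :class:`Trajectory` is a time-indexed table of the channels the
analysis stages consume — whole-body CoM, hip height, toe/heel/ankle
positions, stance-foot velocities and per-point ground reaction forces —
plus, for simulator output, the full segment states and neuron outputs.
Synthetic fixtures and the dynamics engine write the same schema, so the
metrics and fall-classification layers are agnostic to where a
trajectory came from.

The on-disk format is tab-separated text with a commented header
carrying the schema version, metadata key-value pairs and the column
names; values are written with 15 significant digits so a write/read
round trip is lossless to ~1e-12.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["Trajectory", "REQUIRED_COLUMNS", "read_trajectory", "write_trajectory"]

SCHEMA_VERSION = 1

#: Channels every trajectory must provide (analysis-layer contract).
REQUIRED_COLUMNS = (
    "t",
    "com_x", "com_y", "com_vx", "com_vy",
    "hip_x", "hip_y",
    "toe_r_x", "toe_r_y", "heel_r_x", "heel_r_y",
    "toe_l_x", "toe_l_y", "heel_l_x", "heel_l_y",
    "ankle_r_x", "ankle_r_y", "ankle_l_x", "ankle_l_y",
    "foot_r_vx", "foot_l_vx",
    "fgx_heel_r", "fgy_heel_r", "fgx_toe_r", "fgy_toe_r",
    "fgx_heel_l", "fgy_heel_l", "fgx_toe_l", "fgy_toe_l",
)


@dataclass
class Trajectory:
    """Sampled walker trajectory (simulated or synthetic)."""

    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        missing = [c for c in REQUIRED_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValueError(f"trajectory missing required columns: {missing}")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def t(self) -> np.ndarray:
        return self.data["t"].to_numpy()

    def col(self, name: str) -> np.ndarray:
        return self.data[name].to_numpy()

    def grf_y(self, side: str) -> np.ndarray:
        """Total vertical ground force under one foot ('r' or 'l')."""
        return self.col(f"fgy_heel_{side}") + self.col(f"fgy_toe_{side}")

    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.data) else 0.0


def write_trajectory(traj: Trajectory, path) -> None:
    """Write a trajectory to tab-separated text with a commented header."""
    with open(path, "w") as fh:
        fh.write(f"# gaitfall-trajectory schema={SCHEMA_VERSION}\n")
        for k, v in traj.meta.items():
            fh.write(f"# {k} = {v}\n")
        fh.write("# columns: " + "\t".join(traj.data.columns) + "\n")
        traj.data.to_csv(fh, sep="\t", index=False, float_format="%.15g")


def read_trajectory(path) -> Trajectory:
    """Read a trajectory file, validating the schema version."""
    meta: dict = {}
    n_header = 0
    with open(path) as fh:
        first = fh.readline()
        n_header += 1
        if not first.startswith("# gaitfall-trajectory schema="):
            raise ValueError(f"{path}: not a gaitfall trajectory file")
        schema = int(first.strip().rsplit("=", 1)[1])
        if schema != SCHEMA_VERSION:
            raise ValueError(
                f"{path}: unsupported schema version {schema} (expected {SCHEMA_VERSION})"
            )
        pos = fh.tell()
        while True:
            line = fh.readline()
            if not line.startswith("#"):
                fh.seek(pos)
                break
            n_header += 1
            body = line[1:].strip()
            if "=" in body and not body.startswith("columns:"):
                k, v = body.split("=", 1)
                meta[k.strip()] = v.strip()
            pos = fh.tell()
        try:
            df = pd.read_csv(fh, sep="\t")
        except pd.errors.ParserError as exc:
            raise ValueError(f"{path}: parse error after line {n_header}: {exc}") from exc
    if df.isna().any().any():
        bad = int(np.where(df.isna().any(axis=1))[0][0]) + n_header + 2
        raise ValueError(f"{path}: malformed/truncated data near line {bad}")
    return Trajectory(df, meta)
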