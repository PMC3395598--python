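"""Readers, writers and run configuration.

Cell tables travel as CSV with a fixed required header; images as
single-channel grayscale TIFF; run configuration as YAML (or JSON — YAML is
a superset).  Every stochastic output records the seed that produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .imaging import CellRecord
from .simulate import SimulationParams

__all__ = [
    "RunConfig",
    "read_cell_table",
    "write_cell_table",
    "read_image",
    "write_image",
]

REQUIRED_COLUMNS = ("cell_id", "image_id", "replicate", "channel", "raw_agv")


def read_cell_table(path) -> pd.DataFrame:
    """Read a per-cell CSV table, validating schema and types.

    Required columns: cell_id, image_id, replicate, channel, raw_agv.
    Unknown columns are preserved.  An empty file with a header yields an
    empty frame.

    Raises
    ------
    ValueError
        Naming the missing column, or the 1-based data row holding a
        non-numeric AGV.
    """
    df = pd.read_csv(path, dtype={"channel": str})
    for col in REQUIRED_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cell table {path} is missing required column {col!r}")
    agv = pd.to_numeric(df["raw_agv"], errors="coerce")
    bad = df.index[agv.isna() & df["raw_agv"].notna()]
    if len(bad):
        raise ValueError(
            f"cell table {path}: non-numeric raw_agv in data row {int(bad[0]) + 1}"
        )
    df["raw_agv"] = agv
    return df


def write_cell_table(df: pd.DataFrame | list[CellRecord], path) -> None:
    """Write cell records (frame or list of :class:`CellRecord`) as CSV."""
    if not isinstance(df, pd.DataFrame):
        df = pd.DataFrame(
            [dataclasses.asdict(r) for r in df]
        ).rename(columns={"replicate_id": "replicate"})
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, index=False)


def read_image(path) -> np.ndarray:
    """Read a single-channel grayscale TIFF."""
    image = tifffile.imread(path)
    if image.ndim != 2:
        raise ValueError(f"{path}: expected single-channel 2D image, got shape {image.shape}")
    return image


def write_image(image: np.ndarray, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(path, image)


@dataclass
class RunConfig:
    """End-to-end pipeline configuration; round-trips through YAML losslessly."""

    out_dir: str = "icepop_out"
    seed: int = 0
    simulation: SimulationParams = field(default_factory=SimulationParams)
    n_replicates: int = 3
    n_boot: int = 1000
    gate_mode: str = "union"
    exclude_saturated: bool = True
    detection_floor: float = 10.0
    log_level: str = "INFO"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        sim = d.pop("simulation", {})
        if isinstance(sim, dict):
            sim = SimulationParams(**sim)
        return cls(simulation=sim, **d)

    def to_yaml(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    def to_json(self, path) -> None:
        Path(path).parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2, sort_keys=True)
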