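"""Readers and writers for the pipeline's tabular artifacts.

All files are plain text: CSV tables with closed vocabularies, a JSON sidecar
for track metadata, and YAML/JSON run configuration.  Writers emit a
canonical row ordering so that ``write(read(x))`` is byte-identical for
canonically ordered input.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from .errors import ValidationError
from .extraction import AnnulusTrack, ExtractionConfig
from .synthdata import CohortConfig, TrackConfig
from .trending import AnalysisConfig
from .vocab import (
    COHORT_COLUMNS,
    METHODS,
    OBSERVERS,
    RATINGS,
    RATINGS_COLUMNS,
    TIMEPOINTS,
    TRACK_COLUMNS,
    WALLS,
)

_VOCABS = {
    "timepoint": TIMEPOINTS,
    "wall": WALLS,
    "method": METHODS,
    "observer": OBSERVERS,
    "rating": RATINGS,
}


def _validate(df: pd.DataFrame, columns: tuple[str, ...], what: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValidationError(f"{what}: missing column(s) {missing}")
    for col, vocab in _VOCABS.items():
        if col not in df.columns:
            continue
        bad = ~df[col].isin(vocab)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValidationError(
                f"{what}: unknown {col} token {df[col].iloc[row]!r} at row {row} "
                f"(allowed: {list(vocab)})"
            )


def _canonical(df: pd.DataFrame, columns: tuple[str, ...]) -> pd.DataFrame:
    sort_cols = [c for c in columns if c in df.columns and c not in ("mapse_mm", "n_cycles")]
    return df[list(columns)].sort_values(sort_cols, kind="stable").reset_index(drop=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read and validate a long-format measurement table."""
    df = pd.read_csv(path, float_precision="round_trip")
    _validate(df, COHORT_COLUMNS, f"cohort table {path}")
    dup = df.duplicated(subset=["patient_id", "timepoint", "wall", "method"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(f"cohort table {path}: duplicate measurement at row {row}")
    return _canonical(df, COHORT_COLUMNS)


def write_cohort(df: pd.DataFrame, path: str | Path) -> None:
    _validate(df, COHORT_COLUMNS, f"cohort table {path}")
    _canonical(df, COHORT_COLUMNS).to_csv(path, index=False)


def read_ratings(path: str | Path) -> pd.DataFrame:
    """Read and validate a multi-observer RWMA rating table."""
    df = pd.read_csv(path, float_precision="round_trip")
    _validate(df, RATINGS_COLUMNS, f"rating table {path}")
    dup = df.duplicated(subset=["patient_id", "timepoint", "wall", "observer"])
    if dup.any():
        row = int(np.flatnonzero(dup.to_numpy())[0])
        raise ValidationError(f"rating table {path}: duplicate rating at row {row}")
    return _canonical(df, RATINGS_COLUMNS)


def write_ratings(df: pd.DataFrame, path: str | Path) -> None:
    _validate(df, RATINGS_COLUMNS, f"rating table {path}")
    _canonical(df, RATINGS_COLUMNS).to_csv(path, index=False)


def _sidecar_path(path: str | Path) -> Path:
    return Path(path).with_suffix(".json")


def write_track(track: AnnulusTrack, path: str | Path) -> None:
    """Write a track as CSV plus a JSON sidecar holding R-wave times and fps."""
    df = pd.DataFrame(
        {
            "frame_index": np.arange(track.n_frames, dtype=int),
            "time_s": track.times,
            "long_pos_mm": track.long_pos_mm,
            "detected": track.detected.astype(int),
        }
    )
    df.to_csv(path, index=False)
    meta = {"r_wave_times_s": [float(t) for t in track.r_wave_times], "fps": float(track.fps)}
    _sidecar_path(path).write_text(json.dumps(meta, indent=1) + "\n")


def read_track(path: str | Path) -> AnnulusTrack:
    """Read a track CSV and its JSON sidecar back into an :class:`AnnulusTrack`."""
    df = pd.read_csv(path, float_precision="round_trip")
    _validate(df, TRACK_COLUMNS, f"track table {path}")
    sidecar = _sidecar_path(path)
    if not sidecar.exists():
        raise ValidationError(f"track {path}: missing JSON sidecar {sidecar}")
    meta = json.loads(sidecar.read_text())
    detected = df["detected"].astype(bool).to_numpy()
    pos = df["long_pos_mm"].to_numpy(dtype=float)
    pos = np.where(detected, pos, np.nan)
    return AnnulusTrack(
        times=df["time_s"].to_numpy(dtype=float),
        long_pos_mm=pos,
        detected=detected,
        r_wave_times=np.asarray(meta["r_wave_times_s"], dtype=float),
        fps=float(meta["fps"]),
    )


_CONFIG_SECTIONS = {
    "track": TrackConfig,
    "cohort": CohortConfig,
    "extraction": ExtractionConfig,
    "analysis": AnalysisConfig,
}


def load_config(path: str | Path) -> dict[str, Any]:
    """Load a YAML/JSON run configuration into config dataclasses.

    Recognized top-level sections: ``track``, ``cohort``, ``extraction``,
    ``analysis`` (each a mapping of dataclass field names), plus a scalar
    ``seed``.  Missing sections get defaults.
    """
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ValidationError(f"config {path}: expected a mapping at top level")
    out: dict[str, Any] = {}
    for key, cls in _CONFIG_SECTIONS.items():
        section = raw.get(key, {})
        if not isinstance(section, dict):
            raise ValidationError(f"config {path}: section {key!r} must be a mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(section) - known
        if unknown:
            raise ValidationError(f"config {path}: unknown {key} field(s) {sorted(unknown)}")
        out[key] = cls(**section)
    out["seed"] = int(raw.get("seed", 0))
    return out


def dump_config(config: dict[str, Any], path: str | Path) -> None:
    """Write the run configuration back to YAML (inverse of :func:`load_config`)."""
    raw: dict[str, Any] = {}
    for key in _CONFIG_SECTIONS:
        if key in config:
            raw[key] = {
                k: (dict(v) if isinstance(v, dict) else v)
                for k, v in dataclasses.asdict(config[key]).items()
            }
    raw["seed"] = int(config.get("seed", 0))
    Path(path).write_text(yaml.safe_dump(raw, sort_keys=True))
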