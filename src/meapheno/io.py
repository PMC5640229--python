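"""Readers and writers for spike tables, manifests and parameter matrices.

The interchange formats are deliberately plain: spike tables are CSV with
columns ``network_id, unit_id, time_s``; manifests are JSON or YAML;
parameter matrices are tidy TSV.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import pandas as pd
import yaml

from .model import AnalysisConfig, ExperimentManifest, NetworkRecording, TreatmentEpisode, make_recording

log = logging.getLogger(__name__)

SPIKE_COLUMNS = ["network_id", "unit_id", "time_s"]

#: column order of the tidy parameter-matrix TSV
MATRIX_COLUMNS = [
    "network_id",
    "episode_label",
    "compound",
    "concentration_M",
    "parameter_name",
    "category",
    "raw_value",
    "normalized_pct",
]


def read_spike_table(path: str | Path, t_stop: float | None = None) -> list[NetworkRecording]:
    """Read a spike-table CSV into one :class:`NetworkRecording` per network.

    Unsorted rows are sorted; duplicate ``(unit, time)`` rows are collapsed
    with a logged warning; negative times are a validation error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, dtype={"network_id": str, "unit_id": str})
    except (pd.errors.ParserError, ValueError) as exc:
        raise ValueError(f"{path}: malformed spike table: {exc}") from exc
    missing = [c for c in SPIKE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    times = pd.to_numeric(df["time_s"], errors="coerce")
    bad = df.index[times.isna()]
    if len(bad):
        raise ValueError(f"{path}: non-numeric time_s at data row {int(bad[0]) + 1}")
    df = df.assign(time_s=times)
    if (df["time_s"] < 0).any():
        row = int(df.index[df["time_s"] < 0][0]) + 1
        raise ValueError(f"{path}: negative time_s at data row {row}")

    n_before = len(df)
    df = df.drop_duplicates(subset=SPIKE_COLUMNS)
    if len(df) != n_before:
        log.warning("%s: collapsed %d duplicate spike rows", path, n_before - len(df))

    recordings = []
    for net_id, g in df.groupby("network_id", sort=True):
        unit_times = [
            (uid, np.sort(gg["time_s"].to_numpy(float)))
            for uid, gg in g.groupby("unit_id", sort=True)
        ]
        recordings.append(make_recording(str(net_id), unit_times, t_stop=t_stop))
    return recordings


def write_spike_table(recordings: list[NetworkRecording] | NetworkRecording, path: str | Path) -> None:
    if isinstance(recordings, NetworkRecording):
        recordings = [recordings]
    frames = []
    for rec in recordings:
        for train in rec.trains:
            frames.append(
                pd.DataFrame(
                    {
                        "network_id": rec.network_id,
                        "unit_id": train.unit_id,
                        "time_s": train.spike_times,
                    }
                )
            )
    df = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=SPIKE_COLUMNS)
    )
    df.to_csv(path, index=False, float_format="%.4f")


def _manifest_from_dict(d: Mapping[str, Any]) -> ExperimentManifest:
    episodes = tuple(
        TreatmentEpisode(
            label=str(e["label"]),
            compound=str(e["compound"]),
            concentration=float(e["concentration_M"]),
            start=float(e["start_s"]),
            stop=float(e["stop_s"]),
        )
        for e in d["episodes"]
    )
    background = d.get("background") or {}
    return ExperimentManifest(
        episodes=episodes,
        network_id=d.get("network_id"),
        compound=d.get("compound"),
        background_compound=background.get("compound"),
        background_concentration=(
            float(background["concentration_M"]) if background else None
        ),
    )


def read_manifest(path: str | Path) -> ExperimentManifest:
    """Read and validate a JSON or YAML experiment manifest."""
    path = Path(path)
    text = path.read_text()
    if path.suffix.lower() in {".yaml", ".yml"}:
        data = yaml.safe_load(text)
    else:
        data = json.loads(text)
    if not isinstance(data, Mapping) or "episodes" not in data:
        raise ValueError(f"{path}: manifest must be a mapping with an 'episodes' list")
    return _manifest_from_dict(data)


def manifest_to_dict(manifest: ExperimentManifest) -> dict[str, Any]:
    d: dict[str, Any] = {
        "network_id": manifest.network_id,
        "compound": manifest.compound,
        "episodes": [
            {
                "label": e.label,
                "compound": e.compound,
                "concentration_M": e.concentration,
                "start_s": e.start,
                "stop_s": e.stop,
            }
            for e in manifest.episodes
        ],
    }
    if manifest.background_compound is not None:
        d["background"] = {
            "compound": manifest.background_compound,
            "concentration_M": manifest.background_concentration,
        }
    return d


def write_manifest(manifest: ExperimentManifest, path: str | Path) -> None:
    path = Path(path)
    d = manifest_to_dict(manifest)
    if path.suffix.lower() in {".yaml", ".yml"}:
        path.write_text(yaml.safe_dump(d, sort_keys=False))
    else:
        path.write_text(json.dumps(d, indent=1))


def write_parameter_matrix(matrix: pd.DataFrame, path: str | Path) -> None:
    """Write a tidy parameter matrix as TSV with bit-stable ordering.

    Rows are ordered by (network, episode appearance, registry order); the
    registry order is whatever order ``parameter_name`` values first appear
    in, which the parameter engine emits registry-sorted.
    """
    from .parameters import registry  # local import to avoid a cycle

    df = matrix.copy()
    missing = [c for c in MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"parameter matrix missing columns {missing}")
    order = {d.name: i for i, d in enumerate(registry())}
    df["_p"] = df["parameter_name"].map(order).fillna(len(order))
    df = df.sort_values(
        ["network_id", "concentration_M", "episode_label", "_p"], kind="mergesort"
    ).drop(columns="_p")
    df[MATRIX_COLUMNS].to_csv(path, sep="\t", index=False, float_format="%.10g")


def read_parameter_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"network_id": str})
    missing = [c for c in MATRIX_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: parameter matrix missing columns {missing}")
    return df


def read_config(path: str | Path) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from YAML mirroring its field names."""
    data = yaml.safe_load(Path(path).read_text()) or {}
    return AnalysisConfig.from_dict(data)
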