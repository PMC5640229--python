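"""Cut recordings into per-episode analysis windows, apply network QC and
normalize every parameter to the native reference activity (native = 100%).

The analysis window of each treatment episode is its *tail*: the last
``stable_phase`` seconds (the steady state of a step change in drug
concentration), truncated to a whole number of rate bins. A network is
accepted when at least ``min_bursting_units`` units burst during the native
window; acceptance is decided once, on native activity only — later
suppression of bursting is the measured drug effect, not a QC failure.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .bursts import Burst, detect_all_bursts
from .model import AnalysisConfig, ExperimentManifest, NetworkRecording, TreatmentEpisode
from .parameters import compute_window_parameters, registry

log = logging.getLogger(__name__)

__all__ = ["segment", "qc_filter", "normalize", "analyze_experiment", "QCReport"]


@dataclass(frozen=True)
class QCReport:
    network_id: str
    n_units: int
    n_bursting_units: int
    accepted: bool
    reason: str

    def as_dict(self) -> dict:
        return {
            "network_id": self.network_id,
            "n_units": self.n_units,
            "n_bursting_units": self.n_bursting_units,
            "accepted": self.accepted,
            "reason": self.reason,
        }


def segment(
    recording: NetworkRecording,
    manifest: ExperimentManifest,
    cfg: AnalysisConfig,
) -> list[tuple[TreatmentEpisode, tuple[float, float]]]:
    """Analysis windows per episode: the last ``stable_phase`` seconds,
    truncated to a whole number of ``bin_width`` bins.

    Episodes shorter than ``stable_phase`` or extending past the recording
    are rejected with a log entry and omitted from the result.
    """
    out = []
    phase = cfg.bin_width * int(cfg.stable_phase // cfg.bin_width)
    if phase <= 0:
        raise ValueError("stable_phase shorter than one bin")
    for ep in manifest.episodes:
        if ep.duration < cfg.stable_phase:
            log.warning(
                "network %s: episode %r (%.0f s) shorter than stable phase %.0f s; rejected",
                recording.network_id, ep.label, ep.duration, cfg.stable_phase,
            )
            continue
        if ep.stop > recording.t_stop + 1e-6:
            log.warning(
                "network %s: episode %r ends after the recording; rejected",
                recording.network_id, ep.label,
            )
            continue
        out.append((ep, (ep.stop - phase, ep.stop)))
    return out


def qc_filter(
    recording: NetworkRecording,
    native_bursts: dict[str, list[Burst]],
    native_window: tuple[float, float],
    cfg: AnalysisConfig,
) -> QCReport:
    """Accept a network iff >= ``min_bursting_units`` units have at least one
    burst fully inside the native analysis window (threshold inclusive)."""
    w0, w1 = native_window
    n_bursting = sum(
        any(b.onset >= w0 and b.offset <= w1 for b in bl)
        for bl in native_bursts.values()
    )
    accepted = n_bursting >= cfg.min_bursting_units
    reason = (
        "ok"
        if accepted
        else f"only {n_bursting} bursting units (need >= {cfg.min_bursting_units})"
    )
    return QCReport(
        network_id=recording.network_id,
        n_units=recording.n_units,
        n_bursting_units=int(n_bursting),
        accepted=accepted,
        reason=reason,
    )


def normalize(matrix: pd.DataFrame) -> pd.DataFrame:
    """Add ``normalized_pct`` = 100 * raw / native raw per (network, parameter).

    Native rows are exactly 100 where their raw value is nonzero; a zero or
    missing native leaves the normalized value missing (never imputed).
    """
    df = matrix.copy()
    native = (
        df[df["concentration_M"] == 0]
        .set_index(["network_id", "parameter_name"])["raw_value"]
    )
    key = pd.MultiIndex.from_frame(df[["network_id", "parameter_name"]])
    ref = native.reindex(key).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        pct = 100.0 * df["raw_value"].to_numpy(float) / ref
    pct[~np.isfinite(pct)] = np.nan
    pct[np.isclose(ref, 0.0)] = np.nan
    df["normalized_pct"] = pct
    # exact identity at native where defined
    is_native = (df["concentration_M"] == 0).to_numpy()
    defined = ~np.isnan(pct)
    df.loc[is_native & defined, "normalized_pct"] = 100.0
    return df


def analyze_experiment(
    recording: NetworkRecording,
    manifest: ExperimentManifest,
    cfg: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, QCReport]:
    """Full per-network pipeline: bursts -> QC -> per-episode parameters ->
    native normalization.

    Returns the tidy parameter matrix (empty if the network fails QC) and the
    QC report. Bursts are detected once over the whole recording and filtered
    per window, so reruns are bit-identical.
    """
    cfg = cfg or AnalysisConfig()
    windows = segment(recording, manifest, cfg)
    if not windows or not windows[0][0].is_native:
        raise ValueError(
            f"network {recording.network_id}: no native episode with a full stable phase"
        )
    bursts = detect_all_bursts(recording, cfg)
    report = qc_filter(recording, bursts, windows[0][1], cfg)
    if not report.accepted:
        log.info("network %s rejected by QC: %s", recording.network_id, report.reason)
        return pd.DataFrame(columns=_matrix_columns()), report

    rows = []
    for ep, window in windows:
        values = compute_window_parameters(recording, bursts, window, cfg)
        for desc in registry():
            rows.append(
                {
                    "network_id": recording.network_id,
                    "episode_label": ep.label,
                    "compound": ep.compound,
                    "concentration_M": ep.concentration,
                    "parameter_name": desc.name,
                    "category": desc.category,
                    "raw_value": values[desc.name],
                }
            )
    matrix = pd.DataFrame(rows)
    return normalize(matrix), report


def analyze_experiments(
    pairs: list[tuple[NetworkRecording, ExperimentManifest]],
    cfg: AnalysisConfig | None = None,
) -> tuple[pd.DataFrame, list[QCReport]]:
    """Analyze several networks and concatenate their parameter matrices."""
    frames, reports = [], []
    for recording, manifest in pairs:
        try:
            m, r = analyze_experiment(recording, manifest, cfg)
        except ValueError as exc:
            log.error("network %s failed: %s", recording.network_id, exc)
            reports.append(
                QCReport(recording.network_id, recording.n_units, 0, False, str(exc))
            )
            continue
        reports.append(r)
        if len(m):
            frames.append(m)
    matrix = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(columns=_matrix_columns())
    )
    return matrix, reports


def _matrix_columns() -> list[str]:
    from .io import MATRIX_COLUMNS

    return MATRIX_COLUMNS
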