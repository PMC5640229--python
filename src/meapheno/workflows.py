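"""High-level study workflows: simulate a preset experiment, run the
pipeline, and recover concentration-response parameters.

These are the entry points the analysis drivers and the acceptance checks
share; each is a thin composition of the library stages.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .doseresponse import DoseResponseFit, fit_parameter
from .model import AnalysisConfig
from .pipeline import QCReport, analyze_experiments
from .simulate import PRESETS, DrugPreset, GeneratorParams, simulate_experiment

__all__ = ["run_preset_experiment", "recover_ec50", "ExperimentResult"]


@dataclass(frozen=True)
class ExperimentResult:
    matrix: pd.DataFrame
    reports: list[QCReport]
    ground_truth: dict


def run_preset_experiment(
    preset: DrugPreset | str,
    n_networks: int,
    seeds: list[int],
    episode_duration: float = 600.0,
    stable_phase: float = 300.0,
    params: GeneratorParams | None = None,
    ladder: tuple[float, ...] | None = None,
    cfg: AnalysisConfig | None = None,
) -> ExperimentResult:
    """Simulate one cumulative-dosing experiment and analyze it end to end.

    Defaults use 10-minute episodes with a 5-minute stable phase, a scaled
    rendering of the 60/30-minute acquisition protocol that keeps the full
    pipeline exercised at interactive runtimes.
    """
    cfg = cfg or AnalysisConfig(stable_phase=stable_phase)
    pairs, truth = simulate_experiment(
        preset,
        params=params,
        n_networks=n_networks,
        seeds=seeds,
        episode_duration=episode_duration,
        ladder=ladder,
    )
    matrix, reports = analyze_experiments(pairs, cfg)
    return ExperimentResult(matrix=matrix, reports=reports, ground_truth=truth)


def recover_ec50(
    result: ExperimentResult,
    parameter: str = "spike_rate",
    per_network: bool = False,
) -> DoseResponseFit | dict[str, DoseResponseFit]:
    """Hill-fit one registry parameter of an analyzed experiment."""
    return fit_parameter(result.matrix, parameter, per_network=per_network)


def _mean_curve(matrix: pd.DataFrame, parameter: str) -> tuple[np.ndarray, np.ndarray]:
    sel = matrix[matrix["parameter_name"] == parameter][
        ["concentration_M", "normalized_pct"]
    ].dropna()
    means = sel.groupby("concentration_M")["normalized_pct"].mean()
    return means.index.to_numpy(), means.to_numpy()


def recover_fold_shift(
    alone: ExperimentResult,
    combo: ExperimentResult,
    parameter: str = "spike_rate",
) -> dict:
    """EC50 fold shift between two analyzed experiments on one parameter,
    via the global shared-asymptote shift fit (see
    :func:`meapheno.doseresponse.fit_shift_global`)."""
    from .doseresponse import fit_shift_global

    ca, ya = _mean_curve(alone.matrix, parameter)
    cb, yb = _mean_curve(combo.matrix, parameter)
    return fit_shift_global(ca, ya, cb, yb, parameter=parameter)


def geometric_mean_ec50(fits: dict[str, DoseResponseFit]) -> float:
    """Geometric mean of converged per-network EC50s (NaN if none)."""
    vals = [f.ec50 for f in fits.values() if f.converged and np.isfinite(f.ec50)]
    if not vals:
        return float("nan")
    return float(np.exp(np.mean(np.log(vals))))
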