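"""The 40-parameter network-activity registry and its computation.

Thirteen base parameters are computed per unit and 60-s bin — five
*General Activity* rates/intervals and eight *Burst Structure* shape
metrics. Each base parameter contributes

* its grand mean over units (General Activity / Burst Structure category),
* the sample SD of the network-mean value across bins (*Oscillatory
  Behavior*: regularity over time), and
* the coefficient of variation of per-unit means across units (*CVnet*,
  *Synchronicity*: spatial homogeneity — lower = more synchronous),

except that the per-spike peak density has no CVnet entry. Two further
network-level synchrony measures, Syn All (mean distance of member bursts
from their population-burst center, ms) and Spike Simplex (1-ms coincidence
bins with spikes from >=2 units, per minute), complete the registry:
13 + 13 + 12 + 2 = 40 heat-map parameters, of which 10 form the
concentration-response curve set.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from functools import lru_cache

import numpy as np

from .bursts import Burst, PopulationBurst, detect_population_bursts
from .model import AnalysisConfig, NetworkRecording, SpikeTrain

__all__ = [
    "ParameterDescriptor",
    "registry",
    "unit_parameters",
    "aggregate",
    "spike_simplex",
    "syn_all",
    "compute_window_parameters",
]

CATEGORIES = ("GeneralActivity", "BurstStructure", "Oscillatory", "Synchronicity")

#: base per-unit parameters: (name, category of the mean descriptor, units)
GENERAL_BASES = [
    ("spike_rate", "Hz"),
    ("burst_rate", "bursts/s"),
    ("pct_spikes_in_bursts", "%"),
    ("burst_period", "ms"),
    ("burst_ibi", "ms"),
]
STRUCTURE_BASES = [
    ("burst_duration", "ms"),
    ("burst_area", "spikes"),
    ("burst_plateau", "ms"),
    ("burst_amplitude", "Hz"),
    ("burst_isi_mean", "ms"),
    ("burst_spike_rate", "Hz"),
    ("spikes_per_burst", "spikes"),
    ("burst_spike_density", "Hz/spike"),
]
BASES = [name for name, _ in GENERAL_BASES + STRUCTURE_BASES]

#: the 10 curve-set parameters shown as concentration-response curves
CURVESET = (
    "spike_rate",
    "burst_rate",
    "burst_duration",
    "burst_amplitude",
    "spike_rate_sd",
    "burst_rate_sd",
    "spike_rate_cvnet",
    "burst_rate_cvnet",
    "syn_all",
    "spike_simplex",
)


@dataclass(frozen=True)
class ParameterDescriptor:
    name: str
    category: str
    base: str
    statistic: str  # mean | sd_bins | cvnet | network
    units: str
    in_heatmap: bool = True
    in_curveset: bool = False


@lru_cache(maxsize=1)
def _registry() -> tuple[ParameterDescriptor, ...]:
    out: list[ParameterDescriptor] = []
    for name, units in GENERAL_BASES:
        out.append(ParameterDescriptor(name, "GeneralActivity", name, "mean", units))
    for name, units in STRUCTURE_BASES:
        out.append(ParameterDescriptor(name, "BurstStructure", name, "mean", units))
    for name, units in GENERAL_BASES + STRUCTURE_BASES:
        out.append(
            ParameterDescriptor(f"{name}_sd", "Oscillatory", name, "sd_bins", units)
        )
    for name, units in GENERAL_BASES + STRUCTURE_BASES:
        if name == "burst_spike_density":
            continue
        out.append(
            ParameterDescriptor(f"{name}_cvnet", "Synchronicity", name, "cvnet", "")
        )
    out.append(ParameterDescriptor("syn_all", "Synchronicity", "syn_all", "network", "ms"))
    out.append(
        ParameterDescriptor("spike_simplex", "Synchronicity", "spike_simplex", "network", "1/min")
    )
    out = [
        ParameterDescriptor(
            d.name, d.category, d.base, d.statistic, d.units,
            in_heatmap=True, in_curveset=d.name in CURVESET,
        )
        for d in out
    ]
    assert len(out) == 40 and sum(d.in_curveset for d in out) == 10
    return tuple(out)


def registry() -> tuple[ParameterDescriptor, ...]:
    """The immutable 40-descriptor activity-parameter registry."""
    return _registry()


def registry_names() -> list[str]:
    return [d.name for d in registry()]


def _bin_index(t: np.ndarray, w0: float, bin_width: float, n_bins: int) -> np.ndarray:
    idx = np.floor((t - w0) / bin_width).astype(int)
    return np.clip(idx, 0, n_bins - 1)


def unit_parameters(
    train: SpikeTrain,
    bursts: list[Burst],
    window: tuple[float, float],
    bin_width: float = 60.0,
) -> dict[str, np.ndarray]:
    """Per-bin values of the 13 base parameters for one unit.

    The window must be an integer multiple of ``bin_width`` (the episode
    pipeline enforces this). Burst-derived parameters are averaged over the
    bursts whose onset falls in a bin; bins without bursts are NaN, never 0.
    Burst period (onset-to-onset) and inter-burst interval (offset-to-next-
    onset) need a following burst and are assigned to the earlier burst's bin.
    """
    w0, w1 = window
    n_bins = int(round((w1 - w0) / bin_width))
    if n_bins < 1 or abs(n_bins * bin_width - (w1 - w0)) > 1e-6:
        raise ValueError(f"window {window} is not a whole number of {bin_width}-s bins")

    out = {name: np.full(n_bins, np.nan) for name in BASES}

    spikes = train.slice(w0, w1)
    counts = np.bincount(_bin_index(spikes, w0, bin_width, n_bins), minlength=n_bins) \
        if spikes.size else np.zeros(n_bins)
    out["spike_rate"] = counts / bin_width

    wbursts = [b for b in bursts if b.onset >= w0 and b.offset <= w1]
    onsets = np.array([b.onset for b in wbursts])
    out["burst_rate"] = (
        np.bincount(_bin_index(onsets, w0, bin_width, n_bins), minlength=n_bins) / bin_width
        if wbursts
        else np.zeros(n_bins)
    )

    if wbursts:
        bidx = _bin_index(onsets, w0, bin_width, n_bins)
        per_burst = {
            "burst_duration": np.array([b.duration for b in wbursts]),
            "burst_area": np.array([b.area for b in wbursts]),
            "burst_plateau": np.array([b.plateau for b in wbursts]),
            "burst_amplitude": np.array([b.amplitude for b in wbursts]),
            "burst_isi_mean": np.array([b.mean_intraburst_isi for b in wbursts]),
            "burst_spike_rate": np.array([b.spike_rate_in_burst for b in wbursts]),
            "spikes_per_burst": np.array([float(b.n_spikes) for b in wbursts]),
            "burst_spike_density": np.array([b.spike_density for b in wbursts]),
        }
        for name, vals in per_burst.items():
            sums = np.bincount(bidx, weights=vals, minlength=n_bins)
            n = np.bincount(bidx, minlength=n_bins)
            with np.errstate(invalid="ignore"):
                out[name] = np.where(n > 0, sums / np.maximum(n, 1), np.nan)

        if len(wbursts) >= 2:
            period = (onsets[1:] - onsets[:-1]) * 1e3
            ibi = (onsets[1:] - np.array([b.offset for b in wbursts[:-1]])) * 1e3
            pidx = bidx[:-1]
            for name, vals in (("burst_period", period), ("burst_ibi", ibi)):
                sums = np.bincount(pidx, weights=vals, minlength=n_bins)
                n = np.bincount(pidx, minlength=n_bins)
                with np.errstate(invalid="ignore"):
                    out[name] = np.where(n > 0, sums / np.maximum(n, 1), np.nan)

        # fraction of the bin's spikes lying inside any burst of this unit
        if spikes.size:
            starts = np.array([b.onset for b in wbursts])
            stops = np.array([b.offset for b in wbursts])
            pos = np.searchsorted(starts, spikes, side="right") - 1
            in_burst = (pos >= 0) & (spikes <= stops[np.clip(pos, 0, None)])
            sidx = _bin_index(spikes, w0, bin_width, n_bins)
            nb = np.bincount(sidx, weights=in_burst.astype(float), minlength=n_bins)
            with np.errstate(divide="ignore", invalid="ignore"):
                out["pct_spikes_in_bursts"] = np.where(
                    counts > 0, 100.0 * nb / np.maximum(counts, 1), np.nan
                )
    elif spikes.size:
        out["pct_spikes_in_bursts"] = np.where(counts > 0, 0.0, np.nan)

    return out


def aggregate(per_unit: list[dict[str, np.ndarray]]) -> dict[str, float]:
    """Network aggregates (mean, sd_bins, cvnet) of the 13 base parameters.

    * mean: grand mean over units of per-unit window means;
    * sd_bins: sample SD (ddof=1) across bins of the network-mean per-bin
      value;
    * cvnet: sample SD across units of per-unit window means divided by
      their mean (NaN when the mean is ~0 rather than infinite).
    """
    out: dict[str, float] = {}
    for name in BASES:
        mat = np.vstack([u[name] for u in per_unit])  # units x bins
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            unit_means = np.nanmean(mat, axis=1)
            bin_means = np.nanmean(mat, axis=0)
        defined = unit_means[~np.isnan(unit_means)]
        out[name] = float(np.mean(defined)) if defined.size else float("nan")

        bm = bin_means[~np.isnan(bin_means)]
        out[f"{name}_sd"] = float(np.std(bm, ddof=1)) if bm.size >= 2 else float("nan")

        if name != "burst_spike_density":
            if defined.size >= 2 and abs(np.mean(defined)) > 1e-12:
                out[f"{name}_cvnet"] = float(
                    np.std(defined, ddof=1) / np.mean(defined)
                )
            else:
                out[f"{name}_cvnet"] = float("nan")
    return out


def spike_simplex(
    recording: NetworkRecording,
    window: tuple[float, float],
    simplex_bin_ms: float = 1.0,
) -> float:
    """Spike Simplex: 1-ms bins in which >=2 distinct units spike, per minute.

    A coincidence-based synchrony and connectivity measure; higher values
    mean more near-simultaneous firing across units. NaN for <2 units.
    """
    if recording.n_units < 2:
        return float("nan")
    w0, w1 = window
    width = simplex_bin_ms * 1e-3
    n_bins = int(np.ceil((w1 - w0) / width - 1e-9))
    if n_bins <= 0:
        return float("nan")
    units_in_bin = np.zeros(n_bins, dtype=np.int32)
    for train in recording.trains:
        spikes = train.slice(w0, w1)
        if spikes.size == 0:
            continue
        # +1e-9 s guards against times like 0.503 landing a ulp below a
        # bin edge after division
        idx = np.floor((spikes - w0) / width + 1e-9).astype(np.int64)
        idx = np.unique(np.minimum(idx, n_bins - 1))
        units_in_bin[idx] += 1
    events = int((units_in_bin >= 2).sum())
    return events / ((w1 - w0) / 60.0)


def syn_all(population_bursts: list[PopulationBurst]) -> float:
    """Syn All: mean over population bursts of the mean absolute distance
    (ms) of member-burst midpoints from the cluster center. Lower = tighter
    network synchrony. NaN when no population bursts exist."""
    if not population_bursts:
        return float("nan")
    dists = [
        float(np.mean([abs(b.midpoint - pb.center) for b in pb.members])) * 1e3
        for pb in population_bursts
    ]
    return float(np.mean(dists))


def compute_window_parameters(
    recording: NetworkRecording,
    bursts_by_unit: dict[str, list[Burst]],
    window: tuple[float, float],
    cfg: AnalysisConfig,
) -> dict[str, float]:
    """All 40 registry parameters of one network in one analysis window."""
    per_unit = [
        unit_parameters(t, bursts_by_unit.get(t.unit_id, []), window, cfg.bin_width)
        for t in recording.trains
    ]
    values = aggregate(per_unit) if per_unit else {d.name: float("nan") for d in registry()}
    pops = detect_population_bursts(bursts_by_unit, cfg, window=window)
    values["syn_all"] = syn_all(pops)
    values["spike_simplex"] = spike_simplex(recording, window, cfg.simplex_bin)
    return {d.name: values.get(d.name, float("nan")) for d in registry()}
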