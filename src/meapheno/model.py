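"""Domain types for MEA network-activity analysis.

All times are seconds on a single 0-based recording clock; interspike
intervals and burst durations are *reported* in milliseconds. Drug
concentrations are stored in molar; nM/uM strings are formatting only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "SpikeTrain",
    "NetworkRecording",
    "TreatmentEpisode",
    "ExperimentManifest",
    "AnalysisConfig",
]


@dataclass(frozen=True)
class SpikeTrain:
    """One sorted unit's spike times on the shared recording clock.

    Parameters
    ----------
    unit_id
        Opaque identifier of the sorted unit.
    spike_times
        Strictly increasing spike times in seconds, all inside
        ``[t_start, t_stop]``.
    t_start, t_stop
        Extent of the recording this train belongs to, seconds.
    """

    unit_id: str
    spike_times: np.ndarray
    t_start: float = 0.0
    t_stop: float = float("nan")

    def __post_init__(self) -> None:
        times = np.asarray(self.spike_times, dtype=float)
        object.__setattr__(self, "spike_times", times)
        if times.ndim != 1:
            raise ValueError(f"unit {self.unit_id}: spike_times must be 1-D")
        if np.isnan(self.t_stop):
            stop = float(times[-1]) if times.size else self.t_start
            object.__setattr__(self, "t_stop", stop)
        if self.t_stop < self.t_start:
            raise ValueError(
                f"unit {self.unit_id}: t_stop {self.t_stop} < t_start {self.t_start}"
            )
        if times.size:
            if np.any(np.diff(times) <= 0):
                raise ValueError(f"unit {self.unit_id}: spike_times not strictly increasing")
            if times[0] < self.t_start or times[-1] > self.t_stop:
                raise ValueError(
                    f"unit {self.unit_id}: spikes outside [{self.t_start}, {self.t_stop}]"
                )

    @property
    def n_spikes(self) -> int:
        return int(self.spike_times.size)

    def slice(self, start: float, stop: float) -> np.ndarray:
        """Spike times with ``start <= t < stop`` (no copy of the train)."""
        i, j = np.searchsorted(self.spike_times, [start, stop])
        return self.spike_times[i:j]


@dataclass(frozen=True)
class NetworkRecording:
    """All sorted units of one MEA network culture sharing one clock."""

    network_id: str
    trains: tuple[SpikeTrain, ...]
    metadata: Mapping[str, Any] = field(default_factory=dict)

    def __post_init__(self) -> None:
        trains = tuple(self.trains)
        object.__setattr__(self, "trains", trains)
        ids = [t.unit_id for t in trains]
        if len(set(ids)) != len(ids):
            raise ValueError(f"network {self.network_id}: duplicate unit_ids")
        if trains:
            starts = {t.t_start for t in trains}
            stops = {t.t_stop for t in trains}
            if len(starts) > 1 or len(stops) > 1:
                raise ValueError(f"network {self.network_id}: trains do not share one clock")

    @property
    def n_units(self) -> int:
        return len(self.trains)

    @property
    def t_start(self) -> float:
        return self.trains[0].t_start if self.trains else 0.0

    @property
    def t_stop(self) -> float:
        return self.trains[0].t_stop if self.trains else 0.0

    @property
    def duration(self) -> float:
        return self.t_stop - self.t_start

    def unit(self, unit_id: str) -> SpikeTrain:
        for t in self.trains:
            if t.unit_id == unit_id:
                return t
        raise KeyError(unit_id)


@dataclass(frozen=True)
class TreatmentEpisode:
    """One treatment step of a cumulative-dosing experiment.

    ``compound == "native"`` with concentration 0 marks the drug-free
    reference episode every later value is normalized to.
    """

    label: str
    compound: str
    concentration: float  # molar; 0 for native
    start: float  # s
    stop: float  # s

    def __post_init__(self) -> None:
        if self.stop <= self.start:
            raise ValueError(f"episode {self.label}: stop must exceed start")
        if self.concentration < 0:
            raise ValueError(f"episode {self.label}: negative concentration")
        if self.compound == "native" and self.concentration != 0:
            raise ValueError(f"episode {self.label}: native episode must have concentration 0")

    @property
    def duration(self) -> float:
        return self.stop - self.start

    @property
    def is_native(self) -> bool:
        return self.compound == "native" and self.concentration == 0


@dataclass(frozen=True)
class ExperimentManifest:
    """Ordered treatment episodes of one cumulative concentration-response run.

    Invariants: the first episode is the unique native reference; later
    episodes carry strictly increasing concentrations of one compound
    (optionally on a fixed background compound).
    """

    episodes: tuple[TreatmentEpisode, ...]
    network_id: str | None = None
    compound: str | None = None
    background_compound: str | None = None
    background_concentration: float | None = None

    def __post_init__(self) -> None:
        eps = tuple(self.episodes)
        object.__setattr__(self, "episodes", eps)
        if not eps:
            raise ValueError("manifest has no episodes")
        problems: list[str] = []
        natives = [e.label for e in eps if e.is_native]
        if not eps[0].is_native or len(natives) != 1:
            problems.append(
                "native must be unique and first (native episodes: " + repr(natives) + ")"
            )
        concs = [e.concentration for e in eps[1:]]
        for prev, cur, ep in zip(concs, concs[1:], eps[2:]):
            if cur <= prev:
                problems.append(f"non-increasing concentration at episode {ep.label!r}")
        for prev, cur in zip(eps, eps[1:]):
            if cur.start < prev.stop:
                problems.append(f"episode {cur.label!r} overlaps {prev.label!r}")
        if problems:
            raise ValueError("invalid manifest: " + "; ".join(problems))
        if self.compound is None and len(eps) > 1:
            object.__setattr__(self, "compound", eps[1].compound)

    @property
    def native(self) -> TreatmentEpisode:
        return self.episodes[0]

    @property
    def treated(self) -> tuple[TreatmentEpisode, ...]:
        return self.episodes[1:]


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable surface of the whole pipeline.

    Attributes
    ----------
    burst_start_isi_max
        Max ISI (ms) opening a burst; the acquisition practice this models
        adjusts it in 50-150 ms.
    burst_end_isi_max
        Max ISI (ms) extending a burst; 100-300 ms range; must be >= start.
    burst_min_spikes
        Minimum spikes per burst (3 keeps intra-burst statistics defined).
    bin_width
        Temporal bin for rate/SD parameters, seconds (60).
    simplex_bin
        Coincidence bin for the Spike Simplex synchrony count, ms (1).
    min_bursting_units
        Network QC: required count of units with >=1 native burst (6,
        inclusive).
    stable_phase
        Analysis window length, seconds: the last ``stable_phase`` seconds
        of each episode are analyzed (1800 = 30 min).
    kernel_sigma
        Gaussian kernel width for the burst spike-density envelope, ms.
    population_link_window
        Single-linkage onset distance joining unit bursts into a population
        burst, ms.
    population_min_participation
        Fraction of active units required in a population burst.
    """

    burst_start_isi_max: float = 100.0
    burst_end_isi_max: float = 200.0
    burst_min_spikes: int = 3
    bin_width: float = 60.0
    simplex_bin: float = 1.0
    min_bursting_units: int = 6
    alpha_tiers: tuple[float, float, float] = (0.05, 0.01, 0.001)
    stable_phase: float = 1800.0
    kernel_sigma: float = 25.0
    population_link_window: float = 100.0
    population_min_participation: float = 0.5

    def __post_init__(self) -> None:
        positive = {
            "burst_start_isi_max": self.burst_start_isi_max,
            "burst_end_isi_max": self.burst_end_isi_max,
            "burst_min_spikes": self.burst_min_spikes,
            "bin_width": self.bin_width,
            "simplex_bin": self.simplex_bin,
            "stable_phase": self.stable_phase,
            "kernel_sigma": self.kernel_sigma,
            "population_link_window": self.population_link_window,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        if self.burst_end_isi_max < self.burst_start_isi_max:
            raise ValueError("burst_end_isi_max must be >= burst_start_isi_max")
        if not 0 < self.population_min_participation <= 1:
            raise ValueError("population_min_participation must be in (0, 1]")
        if self.min_bursting_units < 1:
            raise ValueError("min_bursting_units must be >= 1")
        if tuple(sorted(self.alpha_tiers, reverse=True)) != tuple(self.alpha_tiers):
            raise ValueError("alpha_tiers must be ordered loosest to strictest")

    def with_(self, **kwargs: Any) -> "AnalysisConfig":
        return replace(self, **kwargs)

    @classmethod
    def from_dict(cls, d: Mapping[str, Any]) -> "AnalysisConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        if "alpha_tiers" in d:
            d["alpha_tiers"] = tuple(d["alpha_tiers"])
        return cls(**d)


def make_recording(
    network_id: str,
    unit_times: Mapping[str, Iterable[float]] | Sequence[tuple[str, Iterable[float]]],
    t_start: float = 0.0,
    t_stop: float | None = None,
    metadata: Mapping[str, Any] | None = None,
) -> NetworkRecording:
    """Convenience constructor used by the simulator, readers and tests."""
    items = unit_times.items() if isinstance(unit_times, Mapping) else unit_times
    items = [(uid, np.asarray(list(t) if not isinstance(t, np.ndarray) else t, dtype=float))
             for uid, t in items]
    if t_stop is None:
        t_stop = max((float(t[-1]) for _, t in items if t.size), default=t_start)
    trains = tuple(
        SpikeTrain(unit_id=uid, spike_times=np.sort(t), t_start=t_start, t_stop=t_stop)
        for uid, t in items
    )
    return NetworkRecording(network_id=network_id, trains=trains, metadata=metadata or {})
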