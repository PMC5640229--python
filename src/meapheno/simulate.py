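"""Synthetic MEA network activity with known ground truth.

The generator emulates the stable, population-burst-dominated firing of
mature cortical cultures: population burst events follow a gamma renewal
process; each unit joins an event with fixed probability, jittered in onset
and firing a gamma-shaped packet of spikes; independent Poisson background
spiking is superposed. Drug action is modeled as concentration-dependent
multiplicative (Hill) modulation of generator parameters, so the pipeline's
recovered response EC50s can be compared against programmed truth.

Presets encode the qualitative pharmacology of the GABAergic tool compounds
the pipeline was built to fingerprint: agonists/PAMs suppress the event
rate, and either shrink bursts (muscimol-like GABA_A activation) or widen
them (baclofen-like GABA_B activation); synchrony tightens slightly as
jitter drops.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np

from .model import ExperimentManifest, NetworkRecording, TreatmentEpisode, make_recording

__all__ = [
    "GeneratorParams",
    "Modulation",
    "DrugPreset",
    "PRESETS",
    "simulate_network",
    "simulate_experiment",
]

#: spike-time deduplication resolution, seconds (0.1 ms)
TIME_RESOLUTION = 1e-4


@dataclass(frozen=True)
class GeneratorParams:
    """Ground-truth configuration of one simulated network.

    Defaults emulate a mature cortical culture on a 32-electrode MEA:
    ~25 active units firing coordinated population bursts about every 7-8 s
    over a sparse background.
    """

    n_units: int = 25
    bg_rate: float = 0.3  # Hz per unit, Poisson background
    event_rate: float = 8.0  # population bursts per minute
    event_cv: float = 0.3  # renewal CV of inter-event intervals
    p_participate: float = 0.9  # per-unit event participation probability
    onset_jitter_sd: float = 30.0  # ms, unit burst onset jitter around event
    spikes_per_burst_mean: float = 12.0  # Poisson mean, floored at 3
    burst_profile_duration: float = 300.0  # ms, length of in-burst spike packet

    def __post_init__(self) -> None:
        for name in (
            "bg_rate", "event_rate", "event_cv", "onset_jitter_sd",
            "spikes_per_burst_mean", "burst_profile_duration",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0 < self.p_participate <= 1:
            raise ValueError("p_participate must be in (0, 1]")
        if self.n_units < 1:
            raise ValueError("n_units must be >= 1")


#: generator fields a preset may modulate
MODULATABLE = (
    "bg_rate", "event_rate", "p_participate", "onset_jitter_sd",
    "spikes_per_burst_mean", "burst_profile_duration",
)


@dataclass(frozen=True)
class Modulation:
    """Hill-shaped multiplier on one generator parameter:
    m(c) = 1 + (max_multiplier - 1) * c^h / (c^h + ec50^h)."""

    target: str
    ec50: float  # molar
    max_multiplier: float
    hill: float = 1.0

    def __post_init__(self) -> None:
        if self.target not in MODULATABLE:
            raise ValueError(f"unknown modulation target {self.target!r}")
        if self.ec50 <= 0 or self.hill <= 0:
            raise ValueError("ec50 and hill must be positive")

    def multiplier(self, concentration: float) -> float:
        if concentration <= 0:
            return 1.0
        frac = concentration**self.hill / (
            concentration**self.hill + self.ec50**self.hill
        )
        return 1.0 + (self.max_multiplier - 1.0) * frac


@dataclass(frozen=True)
class DrugPreset:
    """A named drug phenotype: modulations plus its concentration ladder."""

    name: str
    modulations: tuple[Modulation, ...]
    ladder: tuple[float, ...]  # molar, strictly increasing
    baseline: tuple[Modulation, ...] = ()  # fixed background (e.g. trace co-drug)

    def __post_init__(self) -> None:
        lad = tuple(self.ladder)
        if any(b <= a for a, b in zip(lad, lad[1:])) or any(c <= 0 for c in lad):
            raise ValueError(f"preset {self.name}: ladder must be positive and strictly increasing")

    def effective_params(self, params: GeneratorParams, concentration: float) -> GeneratorParams:
        """Apply all multipliers at ``concentration`` (baseline always on)."""
        mult: dict[str, float] = {}
        for mod in self.baseline:
            mult[mod.target] = mult.get(mod.target, 1.0) * mod.max_multiplier
        for mod in self.modulations:
            mult[mod.target] = mult.get(mod.target, 1.0) * mod.multiplier(concentration)
        changes = {t: getattr(params, t) * m for t, m in mult.items()}
        if "p_participate" in changes:
            changes["p_participate"] = min(changes["p_participate"], 1.0)
        return replace(params, **changes)


def _halflog(start: float, n: int) -> tuple[float, ...]:
    """n concentrations from start upward in alternating x3.16/x3.16 steps
    rendered as the conventional 1-3-10 ladder."""
    out = [start]
    for _ in range(n - 1):
        prev = out[-1]
        exp = np.floor(np.log10(prev) + 1e-9)
        mant = prev / 10**exp
        out.append(float((10 ** (exp + 1) if mant >= 2.5 else 3 * 10**exp)))
    return tuple(out)


PRESETS: dict[str, DrugPreset] = {
    "vehicle": DrugPreset("vehicle", (), _halflog(3e-9, 7)),
    "muscimol": DrugPreset(
        "muscimol",
        (
            Modulation("event_rate", 1e-7, 0.2),
            Modulation("burst_profile_duration", 1e-7, 0.6),
            Modulation("spikes_per_burst_mean", 1e-7, 0.7),
            Modulation("onset_jitter_sd", 1e-7, 0.8),
        ),
        _halflog(3e-9, 7),  # 3 nM .. 3 uM
    ),
    "baclofen": DrugPreset(
        "baclofen",
        (
            Modulation("event_rate", 1e-6, 0.25),
            Modulation("burst_profile_duration", 1e-6, 1.6),
            Modulation("spikes_per_burst_mean", 1e-6, 1.3),
            Modulation("onset_jitter_sd", 1e-6, 1.3),
        ),
        _halflog(3e-8, 6),  # 30 nM .. 10 uM
    ),
    "diazepam": DrugPreset(
        "diazepam",
        (
            Modulation("event_rate", 1.5e-7, 0.5),
            Modulation("burst_profile_duration", 1.5e-7, 0.7),
        ),
        _halflog(1e-9, 9),  # 1 nM .. 10 uM
    ),
    "thip": DrugPreset(
        "thip",
        (
            Modulation("event_rate", 1.7e-5, 0.3),
            Modulation("burst_profile_duration", 1.7e-5, 0.7),
        ),
        _halflog(1e-6, 8),  # 1 uM .. 3 mM
    ),
    "ds1": DrugPreset(
        "ds1",
        (
            Modulation("event_rate", 1.7e-7, 0.3),
            Modulation("burst_profile_duration", 1.7e-7, 0.7),
            Modulation("onset_jitter_sd", 1.7e-7, 0.8),
        ),
        _halflog(1e-10, 10),  # 0.1 nM .. 3 uM
    ),
    # diazepam with a trace (30 nM) delta-selective ago-PAM on board:
    # 30-fold right-shifted diazepam EC50 plus a small constant suppression.
    "diazepam_ds1trace": DrugPreset(
        "diazepam_ds1trace",
        (
            Modulation("event_rate", 4.5e-6, 0.5),
            Modulation("burst_profile_duration", 4.5e-6, 0.7),
        ),
        _halflog(1e-9, 9),
        baseline=(Modulation("event_rate", 1.0, 0.9),),
    ),
}


def _gamma_renewal_times(rng: np.random.Generator, rate_per_min: float,
                         cv: float, duration: float) -> np.ndarray:
    """Event times of a gamma renewal process on [0, duration)."""
    if rate_per_min <= 0:
        return np.empty(0)
    mean = 60.0 / rate_per_min
    n_draw = max(int(duration / mean * 2) + 20, 20)
    if cv <= 0:
        intervals = np.full(n_draw, mean)
    else:
        shape = 1.0 / cv**2
        intervals = rng.gamma(shape, mean / shape, size=n_draw)
    t = np.cumsum(intervals)
    while t.size and t[-1] < duration:  # pragma: no cover - generous n_draw
        more = rng.gamma(shape, mean / shape, size=n_draw) if cv > 0 else np.full(n_draw, mean)
        t = np.concatenate([t, t[-1] + np.cumsum(more)])
    return t[t < duration]


def _simulate_episode(
    rng: np.random.Generator, params: GeneratorParams, duration: float
) -> list[np.ndarray]:
    """Raw spike times per unit on [0, duration), unsorted, with repeats."""
    spikes: list[list[np.ndarray]] = [[] for _ in range(params.n_units)]
    events = _gamma_renewal_times(rng, params.event_rate, params.event_cv, duration)
    profile_s = params.burst_profile_duration * 1e-3
    jitter_s = params.onset_jitter_sd * 1e-3
    for ev in events:
        participating = np.flatnonzero(rng.random(params.n_units) < params.p_participate)
        if participating.size == 0:
            continue
        onsets = ev + rng.normal(0.0, jitter_s, size=participating.size)
        counts = np.maximum(rng.poisson(params.spikes_per_burst_mean, size=participating.size), 3)
        offsets = rng.gamma(2.0, profile_s / 8.0, size=int(counts.sum()))
        np.clip(offsets, 0.0, profile_s, out=offsets)
        burst_times = np.repeat(onsets, counts) + offsets
        splits = np.cumsum(counts)[:-1]
        for unit, times in zip(participating, np.split(burst_times, splits)):
            spikes[unit].append(times)
    for u in range(params.n_units):
        n_bg = rng.poisson(params.bg_rate * duration)
        if n_bg:
            spikes[u].append(rng.uniform(0.0, duration, size=n_bg))
    out = []
    for parts in spikes:
        t = np.concatenate(parts) if parts else np.empty(0)
        out.append(t[(t >= 0) & (t < duration)])
    return out


def _finalize(times: np.ndarray) -> np.ndarray:
    """Sort and deduplicate at the 0.1-ms acquisition resolution."""
    if times.size == 0:
        return times
    quantized = np.round(times / TIME_RESOLUTION).astype(np.int64)
    return np.unique(quantized) * TIME_RESOLUTION


def simulate_network(
    params: GeneratorParams,
    duration: float,
    seed: int | np.random.Generator = 0,
    network_id: str = "sim",
) -> NetworkRecording:
    """One drug-free network recording of ``duration`` seconds."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    per_unit = _simulate_episode(rng, params, duration)
    unit_times = [(f"u{u:03d}", _finalize(t)) for u, t in enumerate(per_unit)]
    return make_recording(network_id, unit_times, t_stop=duration,
                          metadata={"generator": asdict(params)})


def simulate_experiment(
    preset: DrugPreset | str,
    params: GeneratorParams | None = None,
    n_networks: int = 8,
    seeds: list[int] | None = None,
    episode_duration: float = 3600.0,
    ladder: tuple[float, ...] | None = None,
) -> tuple[list[tuple[NetworkRecording, ExperimentManifest]], dict]:
    """Simulate a full cumulative concentration-response experiment.

    Every network gets a native episode followed by one episode per ladder
    concentration, contiguous on one clock, each generated under the
    preset's effective parameters at that concentration. Returns the
    (recording, manifest) pairs and a ground-truth dictionary with the
    preset and per-episode effective parameters.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset]
    params = params or GeneratorParams()
    if seeds is None:
        seeds = list(range(1, n_networks + 1))
    if len(seeds) != n_networks:
        raise ValueError(f"need exactly {n_networks} seeds, got {len(seeds)}")
    lad = tuple(ladder) if ladder is not None else preset.ladder

    concentrations = (0.0, *lad)
    episode_params = [preset.effective_params(params, c) for c in concentrations]
    episodes = []
    for i, c in enumerate(concentrations):
        label = "native" if c == 0 else f"{preset.name}_{c:.3g}M"
        episodes.append(
            TreatmentEpisode(
                label=label,
                compound="native" if c == 0 else preset.name,
                concentration=c,
                start=i * episode_duration,
                stop=(i + 1) * episode_duration,
            )
        )

    pairs = []
    for k, seed in enumerate(seeds):
        rng = np.random.default_rng(seed)
        unit_spikes: list[list[np.ndarray]] = [[] for _ in range(params.n_units)]
        for ep, ep_params in zip(episodes, episode_params):
            per_unit = _simulate_episode(rng, ep_params, episode_duration)
            for u, t in enumerate(per_unit):
                unit_spikes[u].append(t + ep.start)
        net_id = f"net{k:02d}"
        unit_times = [
            (f"u{u:03d}", _finalize(np.concatenate(parts)))
            for u, parts in enumerate(unit_spikes)
        ]
        recording = make_recording(
            net_id, unit_times, t_stop=len(episodes) * episode_duration,
            metadata={"preset": preset.name, "seed": int(seed)},
        )
        manifest = ExperimentManifest(
            episodes=tuple(episodes),
            network_id=net_id,
            compound=preset.name,
        )
        pairs.append((recording, manifest))

    ground_truth = {
        "preset": {
            "name": preset.name,
            "modulations": [asdict(m) for m in preset.modulations],
            "baseline": [asdict(m) for m in preset.baseline],
            "ladder": list(lad),
        },
        "generator": asdict(params),
        "episode_duration_s": episode_duration,
        "networks": [{"network_id": f"net{k:02d}", "seed": int(s)} for k, s in enumerate(seeds)],
        "episodes": [
            {
                "label": ep.label,
                "concentration_M": ep.concentration,
                "effective_params": asdict(p),
            }
            for ep, p in zip(episodes, episode_params)
        ],
    }
    return pairs, ground_truth


def write_experiment(
    pairs: list[tuple[NetworkRecording, ExperimentManifest]],
    ground_truth: dict,
    outdir: str | Path,
) -> None:
    """Write the standard spike CSV + per-network manifest JSONs +
    ground_truth.json."""
    from .io import write_manifest, write_spike_table

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_spike_table([rec for rec, _ in pairs], outdir / "spikes.csv")
    for rec, manifest in pairs:
        write_manifest(manifest, outdir / f"manifest_{rec.network_id}.json")
    (outdir / "ground_truth.json").write_text(json.dumps(ground_truth, indent=1))
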