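"""Per-unit burst detection and network population-burst clustering.

A burst opens when an interspike interval (ISI) <= ``burst_start_isi_max``
follows a candidate first spike, extends while ISIs stay
<= ``burst_end_isi_max``, and closes at the first longer ISI. Using the
looser threshold only for continuation is the one reading under which both
thresholds matter and end >= start is coherent.

Burst shape is summarized from a Gaussian spike-density envelope: each spike
contributes a unit-mass kernel (sigma = ``kernel_sigma`` ms), so the peak of
the summed envelope is the burst *amplitude* in Hz and its integral over the
burst recovers the spike count (the *area*).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model import AnalysisConfig, NetworkRecording, SpikeTrain

__all__ = [
    "Burst",
    "PopulationBurst",
    "detect_bursts",
    "burst_envelope",
    "detect_population_bursts",
]

_SQRT_2PI = float(np.sqrt(2.0 * np.pi))


@dataclass(frozen=True)
class Burst:
    """One detected burst of one unit; times s, durations/ISIs ms, rates Hz."""

    unit_id: str
    onset: float
    offset: float
    n_spikes: int
    mean_intraburst_isi: float  # ms
    spike_rate_in_burst: float  # Hz = n_spikes / duration
    amplitude: float  # Hz, peak of spike-density envelope
    area: float  # spike-count equivalent, envelope integral over the burst
    plateau: float  # ms with envelope >= amplitude / 2
    spike_density: float  # Hz per spike, amplitude / n_spikes

    @property
    def duration(self) -> float:
        """Burst length in ms."""
        return (self.offset - self.onset) * 1e3

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.onset + self.offset)


@dataclass(frozen=True)
class PopulationBurst:
    """A cluster of near-simultaneous unit bursts."""

    members: tuple[Burst, ...]
    center: float  # s, mean of member midpoints
    participation: float  # fraction of active units represented

    @property
    def n_members(self) -> int:
        return len(self.members)


def burst_boundaries(
    spike_times: np.ndarray,
    start_isi_max_s: float,
    end_isi_max_s: float,
    min_spikes: int,
) -> list[tuple[int, int]]:
    """Index spans ``(first, last)`` (inclusive) of bursts in a sorted train.

    Because end >= start, every burst is confined to a maximal run of ISIs
    <= end threshold; within a run the burst opens at the first ISI <= start
    threshold and extends to the run's end. This closed form is equivalent to
    the sequential automaton and vectorizes cleanly.
    """
    n = spike_times.size
    if n < 2:
        return []
    isi = np.diff(spike_times)
    le_end = isi <= end_isi_max_s
    if not le_end.any():
        return []
    # maximal runs of le_end
    padded = np.concatenate(([False], le_end, [False]))
    edges = np.flatnonzero(np.diff(padded.view(np.int8)))
    run_starts, run_stops = edges[::2], edges[1::2]  # isi index ranges [a, b)
    le_start = isi <= start_isi_max_s
    out: list[tuple[int, int]] = []
    for a, b in zip(run_starts, run_stops):
        opens = np.flatnonzero(le_start[a:b])
        if opens.size == 0:
            continue
        first = a + int(opens[0])  # burst spans spikes first .. b
        if b - first + 1 >= min_spikes:
            out.append((first, int(b)))
    return out


def burst_envelope(
    spike_times: np.ndarray,
    kernel_sigma_ms: float,
    grid_step_ms: float = 1.0,
) -> tuple[np.ndarray, np.ndarray, dict[str, float]]:
    """Gaussian spike-density envelope of one burst and its shape metrics.

    Returns ``(grid_s, envelope_hz, metrics)`` where the grid spans
    ``[onset - 3 sigma, offset + 3 sigma]`` at ``grid_step_ms`` resolution and
    metrics holds amplitude (Hz), area (spike-count equivalent over
    [onset, offset]), plateau (ms at >= half amplitude) and spike_density
    (amplitude per spike).
    """
    if kernel_sigma_ms <= 0:
        raise ValueError(f"kernel_sigma must be positive, got {kernel_sigma_ms}")
    spikes = np.asarray(spike_times, dtype=float)
    if spikes.size == 0:
        raise ValueError("burst_envelope needs at least one spike")
    sigma = kernel_sigma_ms * 1e-3
    step = grid_step_ms * 1e-3
    onset, offset = float(spikes[0]), float(spikes[-1])
    n_grid = int(np.floor((offset - onset + 6 * sigma) / step + 1e-9)) + 1
    grid = onset - 3 * sigma + np.arange(n_grid) * step
    env = np.exp(-0.5 * ((grid[None, :] - spikes[:, None]) / sigma) ** 2).sum(axis=0)
    env /= sigma * _SQRT_2PI  # unit mass per spike -> Hz
    amplitude = float(env.max())
    # integrate over the whole +-3 sigma grid so unit kernel mass makes
    # area ~= n_spikes (clipping at the bare [onset, offset] would lose half
    # a kernel per edge spike and break spike-count conservation)
    area = float(np.trapezoid(env, grid)) if grid.size > 1 else 0.0
    plateau = float((env >= 0.5 * amplitude).sum() * grid_step_ms)
    metrics = {
        "amplitude": amplitude,
        "area": area,
        "plateau": plateau,
        "spike_density": amplitude / spikes.size,
    }
    return grid, env, metrics


def _make_burst(unit_id: str, spikes: np.ndarray, cfg: AnalysisConfig) -> Burst:
    onset, offset = float(spikes[0]), float(spikes[-1])
    duration_s = offset - onset
    _, _, m = burst_envelope(spikes, cfg.kernel_sigma)
    return Burst(
        unit_id=unit_id,
        onset=onset,
        offset=offset,
        n_spikes=int(spikes.size),
        mean_intraburst_isi=float(np.mean(np.diff(spikes))) * 1e3,
        spike_rate_in_burst=spikes.size / duration_s if duration_s > 0 else float("nan"),
        amplitude=m["amplitude"],
        area=m["area"],
        plateau=m["plateau"],
        spike_density=m["spike_density"],
    )


try:  # compiled envelope kernel; pure-numpy fallback below is equivalent
    from numba import njit as _njit

    @_njit(cache=True)
    def _env_metrics_jit(spikes, starts, lens, sigma, step):  # pragma: no cover
        n = starts.size
        amp = np.empty(n)
        area = np.empty(n)
        plateau = np.empty(n)
        w = 5.0 * sigma  # kernel support; tails beyond 5 sigma are < 4e-6
        norm = 1.0 / (sigma * np.sqrt(2.0 * np.pi))
        for b in range(n):
            s0 = starts[b]
            ln = lens[b]
            onset = spikes[s0]
            offset = spikes[s0 + ln - 1]
            g0 = onset - 3.0 * sigma
            n_grid = int(np.floor((offset - onset + 6.0 * sigma) / step + 1e-9)) + 1
            env = np.zeros(n_grid)
            for k in range(ln):
                s = spikes[s0 + k]
                jlo = max(0, int(np.ceil((s - w - g0) / step)))
                jhi = min(n_grid - 1, int(np.floor((s + w - g0) / step)))
                for j in range(jlo, jhi + 1):
                    z = (g0 + j * step - s) / sigma
                    env[j] += np.exp(-0.5 * z * z)
            peak = 0.0
            for j in range(n_grid):
                env[j] *= norm
                if env[j] > peak:
                    peak = env[j]
            total = 0.0
            count = 0
            for j in range(n_grid):
                total += env[j]
                if env[j] >= 0.5 * peak:
                    count += 1
            amp[b] = peak
            area[b] = (total - 0.5 * (env[0] + env[n_grid - 1])) * step
            plateau[b] = count
        return amp, area, plateau

    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover
    _HAVE_NUMBA = False

_BATCH_CHUNK = 64  # bursts per padded batch (numpy fallback); bounds peak memory


def _make_bursts_batch(
    unit_id: str,
    spike_times: np.ndarray,
    spans: list[tuple[int, int]],
    cfg: AnalysisConfig,
) -> list[Burst]:
    """Envelope metrics for many bursts at once on padded grids.

    Same grid arithmetic as :func:`burst_envelope` (padded spikes sit at a
    far sentinel whose kernel underflows to exactly 0), so the results match
    the per-burst path while amortizing the array overhead.
    """
    sigma = cfg.kernel_sigma * 1e-3
    step = 1e-3
    if _HAVE_NUMBA and spans:
        starts = np.array([f for f, _ in spans], dtype=np.int64)
        lens = np.array([l - f + 1 for f, l in spans], dtype=np.int64)
        amps, areas, plateaus = _env_metrics_jit(spike_times, starts, lens, sigma, step)
        out = []
        for i, (f, l) in enumerate(spans):
            onset, offset = float(spike_times[f]), float(spike_times[l])
            dur = offset - onset
            n_sp = l - f + 1
            out.append(
                Burst(
                    unit_id=unit_id,
                    onset=onset,
                    offset=offset,
                    n_spikes=n_sp,
                    mean_intraburst_isi=dur / (n_sp - 1) * 1e3,
                    spike_rate_in_burst=n_sp / dur if dur > 0 else float("nan"),
                    amplitude=float(amps[i]),
                    area=float(areas[i]),
                    plateau=float(plateaus[i]),
                    spike_density=float(amps[i]) / n_sp,
                )
            )
        return out
    out: list[Burst] = []
    for c0 in range(0, len(spans), _BATCH_CHUNK):
        chunk = spans[c0 : c0 + _BATCH_CHUNK]
        arrays = [spike_times[f : l + 1] for f, l in chunk]
        n_spikes = np.array([a.size for a in arrays])
        onsets = np.array([a[0] for a in arrays])
        offsets = np.array([a[-1] for a in arrays])
        s_max = int(n_spikes.max())
        spmat = np.full((len(chunk), s_max), 1e9)
        for i, a in enumerate(arrays):
            spmat[i, : a.size] = a
        n_grid = np.floor((offsets - onsets + 6 * sigma) / step + 1e-9).astype(int) + 1
        g_max = int(n_grid.max())
        grid = (onsets - 3 * sigma)[:, None] + np.arange(g_max)[None, :] * step
        valid = np.arange(g_max)[None, :] < n_grid[:, None]
        env = np.exp(-0.5 * ((grid[:, None, :] - spmat[:, :, None]) / sigma) ** 2).sum(axis=1)
        env /= sigma * _SQRT_2PI
        env_valid = np.where(valid, env, 0.0)
        amp = env_valid.max(axis=1)
        last = env[np.arange(len(chunk)), n_grid - 1]
        area = (env_valid.sum(axis=1) - 0.5 * (env[:, 0] + last)) * step
        plateau = ((env_valid >= 0.5 * amp[:, None]) & valid).sum(axis=1).astype(float)
        duration = offsets - onsets
        for i in range(len(chunk)):
            out.append(
                Burst(
                    unit_id=unit_id,
                    onset=float(onsets[i]),
                    offset=float(offsets[i]),
                    n_spikes=int(n_spikes[i]),
                    mean_intraburst_isi=float(duration[i] / (n_spikes[i] - 1)) * 1e3,
                    spike_rate_in_burst=float(n_spikes[i] / duration[i])
                    if duration[i] > 0
                    else float("nan"),
                    amplitude=float(amp[i]),
                    area=float(area[i]),
                    plateau=float(plateau[i]),
                    spike_density=float(amp[i] / n_spikes[i]),
                )
            )
    return out


def detect_bursts(
    train: SpikeTrain,
    cfg: AnalysisConfig,
    window: tuple[float, float] | None = None,
) -> list[Burst]:
    """Detect bursts in one spike train by the two-threshold ISI rule.

    If ``window`` is given, bursts whose ``[onset, offset]`` is not fully
    inside it are discarded (not truncated), which avoids biased durations at
    window edges.
    """
    spans = burst_boundaries(
        train.spike_times,
        cfg.burst_start_isi_max * 1e-3,
        cfg.burst_end_isi_max * 1e-3,
        cfg.burst_min_spikes,
    )
    if window is not None:
        w0, w1 = window
        spans = [
            (f, l)
            for f, l in spans
            if train.spike_times[f] >= w0 and train.spike_times[l] <= w1
        ]
    return _make_bursts_batch(train.unit_id, train.spike_times, spans, cfg) if spans else []


def detect_all_bursts(
    recording: NetworkRecording, cfg: AnalysisConfig
) -> dict[str, list[Burst]]:
    """Bursts per unit over the whole recording (windowing happens later)."""
    return {t.unit_id: detect_bursts(t, cfg) for t in recording.trains}


def detect_population_bursts(
    bursts_by_unit: dict[str, list[Burst]],
    cfg: AnalysisConfig,
    window: tuple[float, float] | None = None,
) -> list[PopulationBurst]:
    """Cluster unit bursts into population bursts by onset single linkage.

    Two bursts link if their onsets differ by at most
    ``population_link_window`` ms; a cluster is kept when it contains bursts
    from at least ``population_min_participation`` of the *active* units
    (units with >=1 burst in the window).
    """
    link = cfg.population_link_window * 1e-3
    pool: list[Burst] = []
    active_units = set()
    for uid, bl in bursts_by_unit.items():
        for b in bl:
            if window is not None and (b.onset < window[0] or b.offset > window[1]):
                continue
            pool.append(b)
            active_units.add(uid)
    if not pool or not active_units:
        return []
    pool.sort(key=lambda b: (b.onset, b.unit_id))
    onsets = np.array([b.onset for b in pool])
    # single linkage on a line = split where consecutive onsets exceed link
    breaks = np.flatnonzero(np.diff(onsets) > link) + 1
    clusters = np.split(np.arange(len(pool)), breaks)
    out: list[PopulationBurst] = []
    n_active = len(active_units)
    for idx in clusters:
        members = tuple(pool[i] for i in idx)
        participation = len({b.unit_id for b in members}) / n_active
        if participation >= cfg.population_min_participation:
            center = float(np.mean([b.midpoint for b in members]))
            out.append(
                PopulationBurst(members=members, center=center, participation=participation)
            )
    return out
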