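import numpy as np
import pytest

from meapheno import AnalysisConfig, SpikeTrain, make_recording


@pytest.fixture
def cfg() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def cfg_fast() -> AnalysisConfig:
    """Config scaled for 10-minute synthetic episodes (5-minute stable phase)."""
    return AnalysisConfig(stable_phase=300.0)


@pytest.fixture
def worked_train() -> SpikeTrain:
    """Seven spikes whose ISI scan yields exactly two bursts
    (0.00-0.15 s, 4 spikes; 0.60-0.70 s, 3 spikes) at 100/200-ms thresholds."""
    return SpikeTrain("u1", np.array([0.00, 0.05, 0.10, 0.15, 0.60, 0.65, 0.70]), 0.0, 1.0)


def random_trains(n: int, seed: int, duration: float = 60.0):
    """A mix of Poisson and bursty random trains for oracle comparisons."""
    rng = np.random.default_rng(seed)
    trains = []
    for k in range(n):
        if k % 2 == 0:  # homogeneous Poisson
            rate = rng.uniform(0.5, 8.0)
            n_sp = rng.poisson(rate * duration)
            t = np.sort(rng.uniform(0, duration, n_sp))
        else:  # bursty: sparse anchors with dense packets
            anchors = np.sort(rng.uniform(0, duration, rng.integers(3, 15)))
            packets = [a + np.cumsum(rng.exponential(rng.uniform(0.01, 0.3), rng.integers(1, 12)))
                       for a in anchors]
            t = np.sort(np.concatenate(packets + [rng.uniform(0, duration, 5)]))
        t = np.unique(np.round(t, 4))
        t = t[(t >= 0) & (t <= duration)]
        trains.append(SpikeTrain(f"r{k}", t, 0.0, duration))
    return trains


def periodic_bursting_recording(
    network_id: str,
    n_bursting: int,
    n_silentish: int = 0,
    duration: float = 600.0,
    period: float = 5.0,
):
    """Recording with ``n_bursting`` units firing a tight 5-spike burst every
    ``period`` s (10-ms ISIs, well under any burst threshold) plus units too
    sparse to ever burst."""
    units = {}
    onsets = np.arange(1.0, duration - 1.0, period)
    burst = np.arange(5) * 0.01
    for u in range(n_bursting):
        units[f"b{u:02d}"] = (onsets[:, None] + burst[None, :]).ravel()
    for u in range(n_silentish):
        units[f"s{u:02d}"] = np.array([duration * 0.25 + u, duration * 0.75 + u])
    return make_recording(network_id, units, t_stop=duration)
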