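"""Registry composition and the parameter computations, checked against
hand formulas, brute-force bin scans and closed-form expectations."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from meapheno import (
    AnalysisConfig,
    SpikeTrain,
    aggregate,
    detect_bursts,
    make_recording,
    registry,
    spike_simplex,
    syn_all,
    unit_parameters,
)
from meapheno.bursts import Burst, PopulationBurst
from meapheno.parameters import BASES, CURVESET


class TestRegistry:
    def test_exactly_40_heatmap_and_10_curve_parameters(self):
        reg = registry()
        assert sum(d.in_heatmap for d in reg) == 40
        assert sum(d.in_curveset for d in reg) == 10

    def test_category_taxonomy(self):
        by_cat = {}
        for d in registry():
            by_cat.setdefault(d.category, []).append(d)
        assert {k: len(v) for k, v in by_cat.items()} == {
            "GeneralActivity": 5,
            "BurstStructure": 8,
            "Oscillatory": 13,
            "Synchronicity": 14,  # 12 CVnet + Syn All + Spike Simplex
        }

    def test_base_statistic_pairs_unique(self):
        pairs = [(d.base, d.statistic) for d in registry()]
        assert len(pairs) == len(set(pairs))

    def test_curveset_names_come_from_the_headline_parameters(self):
        headline_bases = {"spike_rate", "burst_rate", "burst_duration", "burst_amplitude"}
        for name in CURVESET:
            base = name.removesuffix("_sd").removesuffix("_cvnet")
            assert base in headline_bases | {"syn_all", "spike_simplex"}

    def test_registry_is_name_stable(self):
        """Golden list: registry order and names are part of the contract."""
        names = [d.name for d in registry()]
        expected = (
            BASES
            + [f"{b}_sd" for b in BASES]
            + [f"{b}_cvnet" for b in BASES if b != "burst_spike_density"]
            + ["syn_all", "spike_simplex"]
        )
        assert names == expected
        assert names == [d.name for d in registry()]  # cached, immutable


class TestUnitParameters:
    def test_uniform_spikes_give_one_hertz(self, cfg):
        t = np.arange(60) + 0.5
        train = SpikeTrain("u", t, 0, 60)
        vals = unit_parameters(train, [], (0.0, 60.0), 60.0)
        assert vals["spike_rate"][0] == pytest.approx(1.0)

    def test_no_bursts_leaves_burst_parameters_missing(self, cfg):
        t = np.arange(60) + 0.5
        train = SpikeTrain("u", t, 0, 60)
        vals = unit_parameters(train, [], (0.0, 60.0), 60.0)
        assert np.isnan(vals["burst_duration"][0])
        assert vals["spike_rate"][0] == pytest.approx(1.0)
        assert vals["pct_spikes_in_bursts"][0] == 0.0

    def test_worked_two_burst_train(self, worked_train, cfg):
        bursts = detect_bursts(worked_train, cfg)
        train = SpikeTrain("u", worked_train.spike_times, 0, 60)
        vals = unit_parameters(train, bursts, (0.0, 60.0), 60.0)
        assert vals["burst_rate"][0] == pytest.approx(2 / 60)
        assert vals["burst_duration"][0] == pytest.approx(125.0)  # (150+100)/2
        assert vals["spikes_per_burst"][0] == pytest.approx(3.5)
        assert vals["pct_spikes_in_bursts"][0] == pytest.approx(100.0)
        # onset-to-onset 600 ms, offset-to-next-onset 450 ms
        assert vals["burst_period"][0] == pytest.approx(600.0)
        assert vals["burst_ibi"][0] == pytest.approx(450.0)

    def test_window_must_be_whole_bins(self, worked_train):
        with pytest.raises(ValueError, match="whole number"):
            unit_parameters(worked_train, [], (0.0, 90.0), 60.0)


def _fake_unit(spike_rates_per_bin):
    """Minimal per-unit dict with only spike_rate defined."""
    out = {name: np.full(len(spike_rates_per_bin), np.nan) for name in BASES}
    out["spike_rate"] = np.asarray(spike_rates_per_bin, dtype=float)
    return out


class TestAggregate:
    def test_identical_units_have_zero_cvnet(self):
        units = [_fake_unit([2.0, 2.0, 2.0]) for _ in range(5)]
        agg = aggregate(units)
        assert agg["spike_rate_cvnet"] == 0.0
        assert agg["spike_rate"] == pytest.approx(2.0)

    def test_stationary_network_has_zero_sd(self):
        units = [_fake_unit([r, r, r]) for r in (1.0, 2.0, 3.0)]
        assert aggregate(units)["spike_rate_sd"] == 0.0

    def test_three_units_hand_formula(self):
        """Window means 1, 2, 3 Hz: grand mean 2, sample SD 1, CVnet 0.5."""
        units = [_fake_unit([r]) for r in (1.0, 2.0, 3.0)]
        agg = aggregate(units)
        assert agg["spike_rate"] == pytest.approx(2.0)
        assert agg["spike_rate_cvnet"] == pytest.approx(0.5)

    def test_zero_mean_gives_missing_not_infinite_cvnet(self):
        units = [_fake_unit([0.0, 0.0]) for _ in range(3)]
        assert np.isnan(aggregate(units)["spike_rate_cvnet"])

    @given(
        values=st.lists(st.floats(0.1, 50.0), min_size=2, max_size=8),
        scale=st.floats(0.01, 100.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_cvnet_is_scale_invariant(self, values, scale):
        a = aggregate([_fake_unit([v]) for v in values])
        b = aggregate([_fake_unit([v * scale]) for v in values])
        va, vb = a["spike_rate_cvnet"], b["spike_rate_cvnet"]
        if np.isnan(va):
            assert np.isnan(vb)
        else:
            assert vb == pytest.approx(va, rel=1e-9, abs=1e-12)
            assert vb >= 0


def brute_force_simplex(recording, window, bin_ms=1.0):
    """All-bins scan: count bins where >= 2 distinct units spike.

    Works on exact 0.1-ms integer ticks (the acquisition resolution) so bin
    edges are unambiguous."""
    w0, w1 = window
    per_tick = int(round(bin_ms * 10))  # 0.1-ms ticks per bin
    n_bins = int(np.ceil((w1 - w0) / (bin_ms * 1e-3) - 1e-9))
    count = 0
    for b in range(n_bins):
        lo, hi = b * per_tick, (b + 1) * per_tick
        units = 0
        for t in recording.trains:
            ticks = np.round((t.spike_times - w0) * 1e4).astype(int)
            units += bool(np.any((ticks >= lo) & (ticks < hi)))
        count += units >= 2
    return count / ((w1 - w0) / 60.0)


class TestSpikeSimplex:
    def test_no_spikes_is_zero(self):
        rec = make_recording("n", {"a": [], "b": []}, t_stop=60)
        assert spike_simplex(rec, (0.0, 60.0)) == 0.0

    def test_identical_pair_counts_every_bin_once(self):
        t = np.arange(10) * 0.5 + 0.1
        rec = make_recording("n", {"a": t, "b": t}, t_stop=60)
        assert spike_simplex(rec, (0.0, 60.0)) == pytest.approx(10.0)

    def test_single_unit_is_missing(self):
        rec = make_recording("n", {"a": [0.1, 0.2]}, t_stop=60)
        assert np.isnan(spike_simplex(rec, (0.0, 60.0)))

    def test_matches_brute_force_on_random_fixtures(self):
        rng = np.random.default_rng(5)
        for trial in range(100):
            n_units = rng.integers(2, 6)
            dur = 2.0
            units = {
                f"u{k}": np.unique(np.round(np.sort(rng.uniform(0, dur, rng.integers(0, 60))), 4))
                for k in range(n_units)
            }
            rec = make_recording(f"n{trial}", units, t_stop=dur)
            got = spike_simplex(rec, (0.0, dur))
            want = brute_force_simplex(rec, (0.0, dur))
            assert got == pytest.approx(want), trial

    def test_poisson_count_near_analytic_expectation(self):
        """For u independent Poisson units at rate r, the expected count is
        n_bins * P(>=2 units spike) with per-bin spike probability
        p = 1 - exp(-r * width)."""
        rng = np.random.default_rng(99)
        u, rate, dur = 10, 5.0, 600.0
        units = {
            f"u{k}": np.unique(np.round(np.sort(rng.uniform(0, dur, rng.poisson(rate * dur))), 4))
            for k in range(u)
        }
        rec = make_recording("n", units, t_stop=dur)
        got = spike_simplex(rec, (0.0, dur)) * dur / 60.0  # back to a raw count
        p = 1 - np.exp(-rate * 1e-3)
        expect = dur * 1e3 * (1 - (1 - p) ** u - u * p * (1 - p) ** (u - 1))
        assert got == pytest.approx(expect, rel=0.1)


def _burst(uid, onset, offset):
    return Burst(uid, onset, offset, 3, 10.0, 30.0, 50.0, 3.0, 60.0, 16.7)


class TestSynAll:
    def test_identical_member_bursts_give_zero(self):
        members = tuple(_burst(f"u{k}", 10.0, 10.1) for k in range(5))
        pb = PopulationBurst(members, center=10.05, participation=1.0)
        assert syn_all([pb]) == 0.0

    def test_two_members_ten_ms_apart_give_five(self):
        a, b = _burst("a", 10.000, 10.100), _burst("b", 10.010, 10.110)
        center = (a.midpoint + b.midpoint) / 2
        pb = PopulationBurst((a, b), center=center, participation=1.0)
        assert syn_all([pb]) == pytest.approx(5.0)

    def test_monte_carlo_jitter_oracle(self, cfg):
        """With Gaussian onset jitter sigma, the mean absolute deviation of k
        midpoints from their own mean is sigma * sqrt(2/pi) * sqrt(1 - 1/k)."""
        from meapheno import detect_population_bursts

        rng = np.random.default_rng(123)
        sigma_ms, k, n_events = 30.0, 20, 60
        events = np.arange(n_events) * 5.0 + 2.0
        by_unit = {}
        for u in range(k):
            onsets = events + rng.normal(0, sigma_ms * 1e-3, n_events)
            spikes = np.sort(
                np.concatenate([o + np.array([0, 0.02, 0.04]) for o in onsets])
            )
            train = SpikeTrain(f"u{u}", spikes, 0.0, 400.0)
            by_unit[f"u{u}"] = detect_bursts(train, cfg)
        wide = cfg.with_(population_link_window=200.0)
        pops = detect_population_bursts(by_unit, wide)
        assert len(pops) == n_events
        expect = sigma_ms * np.sqrt(2 / np.pi) * np.sqrt(1 - 1 / k)
        assert syn_all(pops) == pytest.approx(expect, rel=0.15)
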