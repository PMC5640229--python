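"""Domain-type invariants and file round trips."""

import numpy as np
import pandas as pd
import pytest

from meapheno import (
    AnalysisConfig,
    ExperimentManifest,
    SpikeTrain,
    TreatmentEpisode,
    detect_bursts,
    make_recording,
    read_manifest,
    read_parameter_matrix,
    read_spike_table,
    write_manifest,
    write_parameter_matrix,
    write_spike_table,
)
from meapheno.io import MATRIX_COLUMNS, read_config


def episode(label, compound, conc, start, stop):
    return TreatmentEpisode(label, compound, conc, start, stop)


class TestSpikeTrain:
    def test_rejects_unsorted_and_tied_times(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            SpikeTrain("u", np.array([0.2, 0.1]), 0, 1)
        with pytest.raises(ValueError, match="strictly increasing"):
            SpikeTrain("u", np.array([0.1, 0.1]), 0, 1)

    def test_rejects_spikes_outside_extent(self):
        with pytest.raises(ValueError, match="outside"):
            SpikeTrain("u", np.array([0.5, 1.5]), 0, 1)

    def test_rejects_inverted_extent(self):
        with pytest.raises(ValueError, match="t_stop"):
            SpikeTrain("u", np.array([]), 1.0, 0.5)

    def test_recording_requires_shared_clock_and_unique_units(self):
        a = SpikeTrain("a", np.array([0.1]), 0, 1)
        b = SpikeTrain("a", np.array([0.2]), 0, 1)
        with pytest.raises(ValueError, match="duplicate unit_ids"):
            make_recording("n", {}, t_stop=1).__class__("n", (a, b))
        c = SpikeTrain("c", np.array([0.2]), 0, 2)
        with pytest.raises(ValueError, match="clock"):
            make_recording("n", {}, t_stop=1).__class__("n", (a, c))


class TestManifest:
    def test_accepts_native_plus_rising_ladder(self):
        eps = [episode("native", "native", 0, 0, 3600)]
        concs = [3e-9, 1e-8, 3e-8, 1e-7, 3e-7, 1e-6, 3e-6]  # 7 rising steps
        for i, c in enumerate(concs):
            eps.append(episode(f"c{i}", "muscimol", c, 3600 * (i + 1), 3600 * (i + 2)))
        man = ExperimentManifest(tuple(eps))
        assert man.compound == "muscimol" and len(man.treated) == 7

    def test_rejects_non_increasing_concentrations(self):
        eps = (
            episode("native", "native", 0, 0, 100),
            episode("a", "drug", 1e-7, 100, 200),
            episode("b", "drug", 3e-8, 200, 300),
        )
        with pytest.raises(ValueError, match="non-increasing"):
            ExperimentManifest(eps)

    def test_rejects_duplicate_or_misplaced_native(self):
        eps = (
            episode("native", "native", 0, 0, 100),
            episode("native2", "native", 0, 100, 200),
        )
        with pytest.raises(ValueError, match="native must be unique and first"):
            ExperimentManifest(eps)
        eps = (episode("a", "drug", 1e-7, 0, 100),)
        with pytest.raises(ValueError, match="native"):
            ExperimentManifest(eps)

    def test_roundtrip_json_and_yaml(self, tmp_path):
        man = ExperimentManifest(
            (
                episode("native", "native", 0, 0, 600),
                episode("lo", "ds1", 1e-8, 600, 1200),
                episode("hi", "ds1", 1e-7, 1200, 1800),
            ),
            network_id="n1",
            background_compound="diazepam",
            background_concentration=5e-8,
        )
        for name in ("m.json", "m.yaml"):
            write_manifest(man, tmp_path / name)
            back = read_manifest(tmp_path / name)
            assert back == man


class TestSpikeTable:
    def test_empty_table_gives_empty_recording_set(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("network_id,unit_id,time_s\n")
        assert read_spike_table(p) == []

    def test_unsorted_rows_are_sorted(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("network_id,unit_id,time_s\nn,u,0.2\nn,u,0.1\nn,u,0.3\n")
        (rec,) = read_spike_table(p)
        assert np.allclose(rec.trains[0].spike_times, [0.1, 0.2, 0.3])

    def test_duplicates_collapse_with_warning(self, tmp_path, caplog):
        p = tmp_path / "s.csv"
        p.write_text("network_id,unit_id,time_s\nn,u,0.1\nn,u,0.1\nn,u,0.3\n")
        with caplog.at_level("WARNING"):
            (rec,) = read_spike_table(p)
        assert rec.trains[0].n_spikes == 2
        assert any("duplicate" in m for m in caplog.messages)

    def test_negative_time_is_an_error(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("network_id,unit_id,time_s\nn,u,-0.5\n")
        with pytest.raises(ValueError, match="negative"):
            read_spike_table(p)

    def test_malformed_row_names_location(self, tmp_path):
        p = tmp_path / "s.csv"
        p.write_text("network_id,unit_id,time_s\nn,u,0.1\nn,u,oops\n")
        with pytest.raises(ValueError, match="row 2"):
            read_spike_table(p)

    def test_toy_file_feeds_burst_detection(self, tmp_path, cfg):
        rows = "\n".join(f"n,u,{t}" for t in (0.00, 0.05, 0.10, 0.15, 0.60, 0.65, 0.70))
        p = tmp_path / "s.csv"
        p.write_text("network_id,unit_id,time_s\n" + rows + "\n")
        (rec,) = read_spike_table(p, t_stop=1.0)
        assert len(detect_bursts(rec.trains[0], cfg)) == 2

    def test_roundtrip_at_input_precision(self, tmp_path):
        rng = np.random.default_rng(7)
        t = np.unique(np.round(np.sort(rng.uniform(0, 60, 500)), 4))
        rec = make_recording("n", {"u0": t, "u1": t + 1e-4}, t_stop=61)
        write_spike_table(rec, tmp_path / "s.csv")
        (back,) = read_spike_table(tmp_path / "s.csv", t_stop=61)
        for a, b in zip(rec.trains, back.trains):
            assert a.unit_id == b.unit_id
            np.testing.assert_allclose(a.spike_times, b.spike_times, atol=5e-5)


class TestParameterMatrix:
    def _matrix(self):
        return pd.DataFrame(
            {
                "network_id": ["n1"] * 2,
                "episode_label": ["native"] * 2,
                "compound": ["native"] * 2,
                "concentration_M": [0.0] * 2,
                "parameter_name": ["spike_rate", "burst_rate"],
                "category": ["GeneralActivity"] * 2,
                "raw_value": [1.5, 0.2],
                "normalized_pct": [100.0, 100.0],
            }
        )

    def test_native_only_run_is_exactly_100(self, tmp_path):
        m = self._matrix()
        write_parameter_matrix(m, tmp_path / "m.tsv")
        back = read_parameter_matrix(tmp_path / "m.tsv")
        assert (back["normalized_pct"] == 100.0).all()

    def test_empty_matrix_writes_header_only(self, tmp_path):
        write_parameter_matrix(pd.DataFrame(columns=MATRIX_COLUMNS), tmp_path / "m.tsv")
        text = (tmp_path / "m.tsv").read_text().strip().splitlines()
        assert len(text) == 1 and text[0].split("\t") == MATRIX_COLUMNS

    def test_roundtrip_reproduces_matrix(self, tmp_path):
        m = self._matrix()
        write_parameter_matrix(m, tmp_path / "m.tsv")
        back = read_parameter_matrix(tmp_path / "m.tsv")
        a = m.sort_values(["parameter_name"]).reset_index(drop=True)
        b = back.sort_values(["parameter_name"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a[MATRIX_COLUMNS], b[MATRIX_COLUMNS], check_dtype=False)


class TestConfig:
    def test_yaml_mirrors_field_names(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("burst_start_isi_max: 50\nburst_end_isi_max: 120\nstable_phase: 300\n")
        cfg = read_config(p)
        assert (cfg.burst_start_isi_max, cfg.burst_end_isi_max, cfg.stable_phase) == (50, 120, 300)

    def test_unknown_keys_rejected(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("not_a_field: 1\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            read_config(p)

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"burst_start_isi_max": -1},
            {"burst_end_isi_max": 50, "burst_start_isi_max": 100},
            {"population_min_participation": 0.0},
            {"kernel_sigma": 0},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            AnalysisConfig(**kwargs)
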