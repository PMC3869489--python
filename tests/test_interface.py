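"""CLI subcommands, configuration, format round-trips, determinism."""

import json
from pathlib import Path

import pandas as pd
import pytest
from click.testing import CliRunner
from rdkit import Chem

from cliffminer.cli import main
from cliffminer.io import read_cliff_table, read_compound_table, read_sdf, write_cliff_table
from cliffminer.run import RunConfig, run_mine, run_simulate
from cliffminer.synthetic import GeneratorConfig, GroundTruth, generate_collection


@pytest.fixture(scope="module")
def sim_dir(tmp_path_factory):
    out = tmp_path_factory.mktemp("sim")
    cfg = RunConfig(out_dir=str(out), seed=13)
    run_simulate(cfg, GeneratorConfig(n_sets=1, set_size=60, seed=13))
    return out


def invoke(*args):
    runner = CliRunner()
    return runner.invoke(main, list(map(str, args)))


class TestSimulateCommand:
    def test_writes_expected_files_and_rows(self, tmp_path):
        res = invoke("simulate", "--n-sets", 1, "--set-size", 60,
                     "--seed", 4, "--out", tmp_path / "a")
        assert res.exit_code == 0, res.output
        df = read_compound_table(tmp_path / "a" / "compounds.csv")
        assert len(df) == 60
        assert (tmp_path / "a" / "ground_truth.json").exists()
        manifest = json.loads((tmp_path / "a" / "manifest.json").read_text())
        assert manifest["records_written"] == 60
        assert manifest["generator"]["seed"] == 4

    def test_fixed_seed_identical_files(self, tmp_path):
        for sub in ("r1", "r2"):
            invoke("simulate", "--n-sets", 1, "--set-size", 60,
                   "--seed", 4, "--out", tmp_path / sub)
        for name in ("compounds.csv", "ground_truth.json"):
            assert (tmp_path / "r1" / name).read_bytes() == (tmp_path / "r2" / name).read_bytes()

    def test_infeasible_config_exits_2(self, tmp_path):
        res = invoke("simulate", "--set-size", 5, "--out", tmp_path / "bad")
        assert res.exit_code == 2
        assert "infeasible" in res.output


class TestMineCommand:
    def test_cliff_table_matches_ground_truth(self, sim_dir, tmp_path):
        res = invoke("mine", sim_dir / "compounds.csv", "--mode", "mmp",
                     "--min-set-size", 50, "--out", tmp_path / "m")
        assert res.exit_code == 0, res.output
        truth = GroundTruth.from_json(sim_dir / "ground_truth.json")
        cliffs = read_cliff_table(tmp_path / "m" / "cliffs.csv")
        assert {c.pair for c in cliffs} == set(truth.cliff_pairs["T01"])
        for c in cliffs:
            assert c.delta_pki == pytest.approx(truth.cliff_pairs["T01"][c.pair], abs=1e-9)
            assert c.category is not None and c.isolated is not None

    def test_empty_input_warns_but_succeeds(self, tmp_path):
        empty = tmp_path / "empty.csv"
        empty.write_text(
            "compound_id,smiles,target_id,standard_type,standard_value,standard_units,year\n"
        )
        res = invoke("mine", empty, "--out", tmp_path / "e")
        assert res.exit_code == 0
        assert (tmp_path / "e" / "cliffs.csv").read_text().count("\n") == 1  # header only

    def test_rerun_byte_identical(self, sim_dir, tmp_path):
        for sub in ("m1", "m2"):
            invoke("mine", sim_dir / "compounds.csv", "--min-set-size", 50,
                   "--out", tmp_path / sub)
        for name in ("cliffs.csv", "mmps.csv", "network_T01.graphml"):
            assert (tmp_path / "m1" / name).read_bytes() == (tmp_path / "m2" / name).read_bytes()
        # manifests agree on everything except the echoed output path
        manifests = [
            json.loads((tmp_path / sub / "manifest.json").read_text()) for sub in ("m1", "m2")
        ]
        for m in manifests:
            m.pop("out_dir")
        assert manifests[0] == manifests[1]


class TestSurveyAndPathwaysCommands:
    def test_summary_means_equal_hand_computed(self, tmp_path):
        out = tmp_path / "sim3"
        invoke("simulate", "--seed", 6, "--out", out)
        res = invoke("survey", out / "compounds.csv", "--out", tmp_path / "s")
        assert res.exit_code == 0, res.output
        per_target = pd.read_csv(tmp_path / "s" / "per_target_stats.csv")
        summary = pd.read_csv(tmp_path / "s" / "summary.csv")
        assert summary.loc[0, "mean_cliff_pct"] == pytest.approx(
            per_target["cliff_pct"].mean()
        )
        assert summary.loc[0, "mean_compound_pct"] == pytest.approx(
            per_target["compound_pct"].mean()
        )

    def test_single_set_summary_equals_target_stats(self, sim_dir, tmp_path):
        invoke("survey", sim_dir / "compounds.csv", "--min-set-size", 50,
               "--out", tmp_path / "s1")
        per_target = pd.read_csv(tmp_path / "s1" / "per_target_stats.csv")
        summary = pd.read_csv(tmp_path / "s1" / "summary.csv")
        assert summary.loc[0, "mean_cliff_pct"] == per_target.loc[0, "cliff_pct"]

    def test_progression_statuses_match_plants(self, sim_dir, tmp_path):
        res = invoke("pathways", sim_dir / "compounds.csv", "--min-set-size", 50,
                     "--out", tmp_path / "p")
        assert res.exit_code == 0, res.output
        truth = GroundTruth.from_json(sim_dir / "ground_truth.json")
        rows = pd.read_csv(tmp_path / "p" / "progression.csv")
        found = {
            (r.compound_id_1, r.compound_id_2): r.status for r in rows.itertuples(index=False)
        }
        assert found == truth.progression["T01"]

    def test_network_command_exports_graphml(self, sim_dir, tmp_path):
        res = invoke("network", sim_dir / "compounds.csv", "--min-set-size", 50,
                     "--out", tmp_path / "n")
        assert res.exit_code == 0
        assert (tmp_path / "n" / "network_T01.graphml").exists()
        assert (tmp_path / "n" / "edges_T01.csv").exists()


class TestConfigFile:
    def test_yaml_config_with_flag_override(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("min_set_size: 40\ndelta_pki: 2.5\n")
        rc = RunConfig.from_yaml(cfg, seed=9)
        assert rc.min_set_size == 40 and rc.delta_pki == 2.5 and rc.seed == 9

    def test_unknown_keys_rejected(self, tmp_path):
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("potency: 2\n")
        with pytest.raises(ValueError, match="unknown config keys"):
            RunConfig.from_yaml(cfg)

    def test_manifest_echoes_every_parameter(self, sim_dir, tmp_path):
        invoke("mine", sim_dir / "compounds.csv", "--min-set-size", 50,
               "--potency-diff", 2.0, "--out", tmp_path / "mm")
        manifest = json.loads((tmp_path / "mm" / "manifest.json").read_text())
        for key in RunConfig().__dataclass_fields__:
            assert key in manifest
        assert "tallies" in manifest


class TestFormats:
    def test_cliff_table_round_trip_exact(self, sim_dir, tmp_path):
        run_mine(RunConfig(input=str(sim_dir / "compounds.csv"),
                           out_dir=str(tmp_path / "rt"), min_set_size=50))
        cliffs = read_cliff_table(tmp_path / "rt" / "cliffs.csv")
        rewritten = tmp_path / "rt" / "cliffs2.csv"
        write_cliff_table(cliffs, rewritten)
        assert rewritten.read_bytes() == (tmp_path / "rt" / "cliffs.csv").read_bytes()
        assert read_cliff_table(rewritten) == cliffs

    def test_sdf_input_accepted(self, tmp_path):
        records, _ = generate_collection(GeneratorConfig(n_sets=1, set_size=60, seed=2))
        sdf = tmp_path / "input.sdf"
        writer = Chem.SDWriter(str(sdf))
        for row in records.itertuples(index=False):
            mol = Chem.MolFromSmiles(row.smiles)
            mol.SetProp("compound_id", row.compound_id)
            mol.SetProp("target_id", row.target_id)
            mol.SetProp("standard_type", row.standard_type)
            mol.SetProp("standard_value", repr(row.standard_value))
            mol.SetProp("standard_units", row.standard_units)
            mol.SetProp("year", str(row.year))
            writer.write(mol)
        writer.close()
        df = read_sdf(sdf)
        assert len(df) == 60
        res = invoke("mine", sdf, "--min-set-size", 50, "--out", tmp_path / "sdfout")
        assert res.exit_code == 0, res.output
        cliffs = read_cliff_table(tmp_path / "sdfout" / "cliffs.csv")
        assert len(cliffs) > 0

    def test_missing_columns_rejected(self, tmp_path):
        bad = tmp_path / "bad.csv"
        bad.write_text("compound_id,smiles\nx,CC\n")
        with pytest.raises(ValueError, match="missing columns"):
            read_compound_table(bad)
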