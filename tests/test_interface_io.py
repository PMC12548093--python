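import json

import numpy as np
import pytest
from click.testing import CliRunner

from n2oray import generate_study_like
from n2oray.cli import main as cli_main
from n2oray.interface_io import (
    RunConfig,
    dataset_to_frame,
    read_observations,
    read_report,
    run_full_analysis,
    write_observations,
    write_report,
)

from conftest import ZERO_NOISE


@pytest.fixture()
def config():
    return RunConfig(n_boot=100, seed=3)


@pytest.fixture()
def csv_path(tmp_path, noisy_sim):
    path = tmp_path / "obs.csv"
    write_observations(noisy_sim.dataset, path)
    return path


class TestReadObservations:
    def test_round_trip(self, csv_path, config, noisy_sim):
        ds = read_observations(csv_path, config)
        assert len(ds) == len(noisy_sim.dataset)
        for a, b in zip(ds.observations, noisy_sim.dataset.observations):
            assert a.deltas.d15n_bulk == pytest.approx(b.deltas.d15n_bulk)
            assert a.f == pytest.approx(b.f)
            assert a.abscissa == pytest.approx(b.abscissa)

    def test_minimal_file(self, tmp_path, config):
        p = tmp_path / "min.csv"
        p.write_text(
            "replicate_id,time_min,n2o_nmol_cumulative,d15N_bulk,d15N_alpha,d18O\n"
            "r1,10,1100,-44.0,-43.0,20.0\n"
            "r1,20,2100,-43.5,-42.8,25.0\n"
            "r1,30,3100,-43.0,-42.5,30.0\n"
        )
        ds = read_observations(p, config)
        assert len(ds) == 3
        # beta derived from bulk and alpha
        assert ds.observations[0].deltas.d15n_beta == pytest.approx(-45.0)

    def test_in_bottle_with_removals(self, tmp_path, config):
        p = tmp_path / "bottle.csv"
        p.write_text(
            "replicate_id,time_min,n2o_nmol_in_bottle,n2o_nmol_removed,"
            "d15N_bulk,d15N_alpha,d18O\n"
            "r1,10,1100,100,-44.0,-43.0,20.0\n"
            "r1,20,2000,100,-43.5,-42.8,25.0\n"
        )
        ds = read_observations(p, config)
        assert ds.observations[1].n2o_cum == pytest.approx(2100.0)

    def test_provided_beta_taken_as_is(self, tmp_path, config):
        p = tmp_path / "beta.csv"
        p.write_text(
            "replicate_id,time_min,n2o_nmol_cumulative,d15N_bulk,d15N_alpha,"
            "d15N_beta,d18O\n"
            "r1,10,1100,-44.0,-43.0,-45.02,20.0\n"
            "r1,20,2100,-43.5,-42.8,-44.21,25.0\n"
            "r1,30,3100,-43.0,-42.5,-43.52,30.0\n"
        )
        ds = read_observations(p, config)
        assert ds.observations[0].deltas.d15n_beta == pytest.approx(-45.02)

    def test_missing_column_rejected(self, tmp_path, config):
        p = tmp_path / "bad.csv"
        p.write_text("replicate_id,time_min\nr1,10\n")
        with pytest.raises(ValueError, match="missing required column"):
            read_observations(p, config)

    def test_non_numeric_cell_located(self, tmp_path, config):
        p = tmp_path / "bad.csv"
        p.write_text(
            "replicate_id,time_min,n2o_nmol_cumulative,d15N_bulk,d15N_alpha,d18O\n"
            "r1,10,1100,oops,-43.0,20.0\n"
        )
        with pytest.raises(ValueError, match="line"):
            read_observations(p, config)

    def test_duplicate_rows_rejected(self, tmp_path, config):
        p = tmp_path / "dup.csv"
        p.write_text(
            "replicate_id,time_min,n2o_nmol_cumulative,d15N_bulk,d15N_alpha,d18O\n"
            "r1,10,1100,-44.0,-43.0,20.0\n"
            "r1,10,1100,-44.0,-43.0,20.0\n"
        )
        with pytest.raises(ValueError, match="duplicated"):
            read_observations(p, config)


class TestRunConfig:
    def test_yaml_round_trip(self, tmp_path):
        p = tmp_path / "cfg.yaml"
        p.write_text("no_initial_nmol: 9000\nn_boot: 50\nseed: 9\n")
        cfg = RunConfig.from_file(p)
        assert cfg.no_initial_nmol == 9000
        assert cfg.n_boot == 50

    def test_json_config(self, tmp_path):
        p = tmp_path / "cfg.json"
        p.write_text(json.dumps({"min_conversion": 0.2}))
        assert RunConfig.from_file(p).min_conversion == 0.2

    @pytest.mark.parametrize("field, value", [
        ("min_conversion", -0.1), ("grubbs_alpha", 2.0),
        ("outlier_policy", "maybe"), ("n_boot", 0),
    ])
    def test_validation(self, field, value):
        with pytest.raises(ValueError):
            RunConfig(**{field: value})

    def test_digest_stable(self):
        assert RunConfig().digest() == RunConfig().digest()
        assert RunConfig().digest() != RunConfig(seed=1).digest()


class TestFullAnalysis:
    def test_zero_noise_report_is_self_consistent(self, config):
        sim = generate_study_like(seed=0, **ZERO_NOISE)
        report = run_full_analysis(sim.dataset, config, bootstrap=False)
        rows = {r["measurement"]: r for r in report["table"]}
        assert rows["15N"]["epsilon"] == pytest.approx(
            report["bulk_fit"]["slope"]
        )
        assert report["d15n_s0"] == pytest.approx(-40.5, abs=0.1)
        assert rows["15N_alpha"]["epsilon"] > rows["15N_beta"]["epsilon"]
        assert not report["grubbs"]["removed"]

    def test_report_round_trip(self, tmp_path, config, noisy_sim):
        report = run_full_analysis(noisy_sim.dataset, config)
        p = tmp_path / "report.json"
        write_report(report, p)
        back = read_report(p)
        assert back["bulk_fit"] == pytest.approx(report["bulk_fit"])
        assert back["bootstrap"]["mean_kie_bulk"] == pytest.approx(
            report["bootstrap"]["mean_kie_bulk"]
        )
        assert back["provenance"]["config_hash"] == config.digest()

    def test_provenance_embedded(self, config, noisy_sim):
        report = run_full_analysis(noisy_sim.dataset, config, bootstrap=False)
        prov = report["provenance"]
        assert {"package_version", "config", "config_hash", "seed"} <= set(prov)

    def test_empty_after_filter_names_the_stage(self, config):
        sim = generate_study_like(seed=0)
        # demand an impossible minimum conversion
        cfg = RunConfig(min_conversion=0.99, n_boot=10)
        with pytest.raises(ValueError, match="no observations remain"):
            run_full_analysis(sim.dataset, cfg)


class TestCli:
    def test_simulate_fit_report_chain(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "sim.csv"
        rep = tmp_path / "rep.json"
        r = runner.invoke(cli_main, ["simulate", "--seed", "4",
                                     "--out", str(csv)])
        assert r.exit_code == 0, r.output
        assert csv.exists() and csv.with_suffix(".truth.json").exists()
        r = runner.invoke(cli_main, ["fit", str(csv), "--out", str(rep)])
        assert r.exit_code == 0, r.output
        report = read_report(rep)
        assert "table" in report and len(report["table"]) == 3
        r = runner.invoke(cli_main, ["report", str(rep)])
        assert r.exit_code == 0, r.output
        assert "15N_alpha" in r.output

    def test_bootstrap_command(self, tmp_path):
        runner = CliRunner()
        csv = tmp_path / "sim.csv"
        rep = tmp_path / "rep.json"
        runner.invoke(cli_main, ["simulate", "--seed", "4", "--out", str(csv)])
        r = runner.invoke(cli_main, [
            "bootstrap", str(csv), "--n-boot", "50", "--seed", "2",
            "--out", str(rep),
        ])
        assert r.exit_code == 0, r.output
        assert "bootstrap" in read_report(rep)


def test_dataset_frame_has_all_channels(noisy_sim):
    df = dataset_to_frame(noisy_sim.dataset)
    assert {"d15N_bulk", "d15N_alpha", "d15N_beta", "d18O", "d15N_SP",
            "f", "abscissa"} <= set(df.columns)
    assert np.all((df["f"] > 0) & (df["f"] < 1))
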