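import json

import numpy as np
import pandas as pd
import pytest
from click.testing import CliRunner

import nirquant as nq
from nirquant.cli import main as cli_main
from nirquant.errors import DomainError
from nirquant.pipeline import RunManifest, StudyConfig, report_tables, run_study

QUICK = dict(n_repeats=1, max_epochs=25)


@pytest.fixture(scope="module")
def fitted(small_dataset):
    model = nq.AdulterationRegressor.from_dataset(
        small_dataset, arch="simple_cnn",
        config=nq.TrainingConfig.for_arch("simple_cnn", batch_size=8, seed=0,
                                          **QUICK))
    return model, model.fit()


class TestModelResults:
    def test_from_dataset_applies_snv_and_split(self, small_dataset):
        model = nq.AdulterationRegressor.from_dataset(small_dataset,
                                                      train_fraction=0.5)
        assert model.X_train.shape[0] == small_dataset.n // 2
        assert np.allclose(np.abs(model.X.mean(axis=1)), 0.0, atol=1e-9)

    def test_results_metrics_consistent(self, fitted):
        model, res = fitted
        te = res.test_metrics
        direct = nq.compute_metrics(model.y_test, res.predict(model.X_test))
        assert te.r2 == pytest.approx(direct.r2)
        assert te.rpd == pytest.approx(direct.rpd)

    def test_summary_reports_protocol_and_metrics(self, fitted):
        _, res = fitted
        text = res.summary()
        assert "simple_cnn" in text
        assert "RPD" in text and "R2" in text
        assert f"cumulative: {res.epochs_run}" in text

    def test_regression_line_matches_polyfit(self, fitted):
        model, res = fitted
        slope, intercept = res.regression_line("test")
        ref = np.polyfit(model.y_test, res.predict(model.X_test), 1)
        assert slope == pytest.approx(ref[0], abs=1e-9)
        assert intercept == pytest.approx(ref[1], abs=1e-9)

    def test_coefficient_profile_on_instrument_axis(self, fitted):
        _, res = fitted
        prof = res.coefficients()
        assert len(prof.mean_weights) == 125
        assert prof.axis.instrument_tag == nq.MICRO_NIR
        feats = res.important_features(0.5)
        assert feats.n_selected >= 1

    def test_config_arch_mismatch_rejected(self, small_dataset):
        with pytest.raises(DomainError):
            nq.AdulterationRegressor(small_dataset.X, small_dataset.y,
                                     arch="resnet",
                                     config=nq.TrainingConfig.for_arch("simple_cnn"))


@pytest.fixture(scope="module")
def study_outcome(tmp_path_factory):
    cfg = StudyConfig(
        design=nq.DesignSpec(levels=(1, 5, 10, 20, 50), samples_per_level=2,
                             scans_per_sample=2, seed=7),
        architectures=("simple_cnn",), n_repeats=1, max_epochs=20,
        master_seed=7)
    out = tmp_path_factory.mktemp("study")
    return cfg, run_study(cfg, out), out


class TestPipeline:
    def test_manifest_lists_outputs_with_checksums(self, study_outcome):
        _, manifest, out = study_outcome
        expected = {"dataset.csv", "metrics.csv", "history_simple_cnn.csv",
                    "scatter_simple_cnn.csv", "coefficients_simple_cnn.csv",
                    "important_features_simple_cnn.csv"}
        assert expected <= set(manifest.files)
        for name, digest in manifest.files.items():
            assert (out / name).exists()
            assert len(digest) == 64
        assert (out / "manifest.json").exists()

    def test_metrics_csv_one_row_per_architecture(self, study_outcome):
        _, _, out = study_outcome
        df = pd.read_csv(out / "metrics.csv")
        assert len(df) == 1
        assert df.loc[0, "Regressor"] == "simple_cnn"

    def test_scatter_line_recomputable_from_persisted_pairs(self, study_outcome):
        _, manifest, out = study_outcome
        scat = pd.read_csv(out / "scatter_simple_cnn.csv")
        te = scat[scat.subset == "test"]
        slope, intercept = np.polyfit(te.existing, te.predicted, 1)
        rec = manifest.metrics["simple_cnn"]["test_line"]
        assert slope == pytest.approx(rec["slope"], abs=1e-9)
        assert intercept == pytest.approx(rec["intercept"], abs=1e-9)

    def test_same_master_seed_reproduces_dataset_checksum(self, study_outcome,
                                                          tmp_path):
        cfg, manifest, _ = study_outcome
        again = run_study(cfg, tmp_path)
        assert again.files["dataset.csv"] == manifest.files["dataset.csv"]


class TestReportTables:
    @staticmethod
    def fake_manifest(adulterant, instrument, metrics):
        return {"config": {"design": {"adulterant": adulterant,
                                      "instrument": instrument}},
                "metrics": metrics}

    @staticmethod
    def entry(rpd, rmse):
        return {"test": {"rpd": rpd, "rmse": rmse, "r2": 0.99, "bias": 0.0,
                         "n": 135, "band": "excellent"}}

    def test_single_architecture_trivially_best(self):
        man = self.fake_manifest("corn_flour", nq.MICRO_NIR,
                                 {"simple_cnn": self.entry(12.0, 1.0)})
        df = report_tables([man])
        assert df.loc[0, "Best Regressor"] == "simple_cnn"

    def test_highest_rpd_wins(self):
        man = self.fake_manifest("corn_flour", nq.MICRO_NIR,
                                 {"a": self.entry(10.0, 1.0),
                                  "b": self.entry(12.0, 2.0)})
        assert report_tables([man]).loc[0, "Best Regressor"] == "b"

    def test_rmse_breaks_rpd_ties(self):
        man = self.fake_manifest("corn_flour", nq.FT_NIR,
                                 {"a": self.entry(10.0, 0.6),
                                  "b": self.entry(10.0, 0.5)})
        assert report_tables([man]).loc[0, "Best Regressor"] == "b"

    def test_name_breaks_full_ties(self):
        man = self.fake_manifest("corn_flour", nq.FT_NIR,
                                 {"b": self.entry(10.0, 0.5),
                                  "a": self.entry(10.0, 0.5)})
        assert report_tables([man]).loc[0, "Best Regressor"] == "a"

    def test_empty_input_rejected(self):
        with pytest.raises(DomainError):
            report_tables([])


class TestConfigRoundTrip:
    def test_yaml_round_trip(self, tmp_path):
        cfg = StudyConfig(architectures=("simple_cnn", "resnet"), n_repeats=2,
                          master_seed=11, threshold_fraction=0.4)
        p = tmp_path / "cfg.yaml"
        cfg.to_yaml(p)
        back = StudyConfig.from_yaml(p)
        assert back.architectures == ("simple_cnn", "resnet")
        assert back.n_repeats == 2 and back.master_seed == 11
        assert back.threshold_fraction == 0.4
        assert back.design == cfg.design
        assert back.noise == cfg.noise


class TestCli:
    def test_simulate_and_split_commands(self, tmp_path):
        runner = CliRunner()
        out_csv = tmp_path / "ds.csv"
        res = runner.invoke(cli_main, [
            "simulate", "--instrument", nq.MICRO_NIR,
            "--adulterant", "corn_flour", "--seed", "5",
            "--out", str(out_csv)])
        assert res.exit_code == 0, res.output
        assert "n=450 m=125" in res.output

        split_json = tmp_path / "split.json"
        res = runner.invoke(cli_main, ["split", str(out_csv),
                                       "--out", str(split_json)])
        assert res.exit_code == 0, res.output
        split = json.loads(split_json.read_text())
        assert len(split["train_idx"]) == 315 and len(split["test_idx"]) == 135

    def test_preprocess_command(self, small_dataset, tmp_path):
        p = tmp_path / "ds.csv"
        nq.write_dataset_csv(small_dataset, p)
        out = tmp_path / "snv.csv"
        res = CliRunner().invoke(cli_main, ["preprocess", str(p), "--out", str(out)])
        assert res.exit_code == 0, res.output
        back = nq.read_dataset_csv(out)
        assert back.snv_applied
        assert np.all(np.abs(back.X.mean(axis=1)) < 1e-6)
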