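"""Tests for file I/O, model serialization, config parsing and the CLI."""

import json

import numpy as np
import pytest
from click.testing import CliRunner

import relsom as rs
from relsom import modelio
from relsom.cli import main
from relsom.errors import InvalidConfigError, ModelFormatError, ParseError

from conftest import reference_config


@pytest.fixture()
def tiny_model():
    x = np.linspace(0.0, 1.0, 15)
    data = rs.PairedSeries(np.arange(1.0, 16.0), x, x)
    return rs.train(data, reference_config(n_neurons=12, max_epochs=30))


class TestSeriesCsv:
    def test_round_trip_full_precision(self, tmp_path):
        rng = np.random.default_rng(3)
        series = rs.PairedSeries(
            np.sort(rng.uniform(0, 10, 9)), rng.normal(size=9), rng.normal(size=9),
            labels=("dose", "volume"),
        )
        path = tmp_path / "series.csv"
        modelio.write_series_csv(series, path)
        back = modelio.read_series_csv(path)
        assert np.array_equal(back.series_a, series.series_a)
        assert np.array_equal(back.series_b, series.series_b)
        assert back.labels == series.labels

    def test_two_column_file_uses_time_as_covariate(self, tmp_path):
        path = tmp_path / "two.csv"
        path.write_text("t,volume\n1,5.0\n2,6.5\n3,9.0\n")
        series = modelio.read_series_csv(path)
        assert len(series) == 3
        assert np.array_equal(series.series_a, [1.0, 2.0, 3.0])

    def test_duplicate_timestamp_cites_row(self, tmp_path):
        path = tmp_path / "dup.csv"
        path.write_text("t,v\n1,1\n2,2\n2,3\n")
        with pytest.raises(ParseError, match="row 3"):
            modelio.read_series_csv(path)

    def test_non_numeric_cell_cites_row(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("t,v\n1,1\n2,oops\n3,3\n")
        with pytest.raises(ParseError, match="row 2"):
            modelio.read_series_csv(path)

    def test_single_column_rejected(self, tmp_path):
        path = tmp_path / "one.csv"
        path.write_text("t\n1\n2\n")
        with pytest.raises(ParseError):
            modelio.read_series_csv(path)


class TestModelFile:
    def test_round_trip_is_bitwise(self, tmp_path, tiny_model):
        path = tmp_path / "m.json"
        modelio.save_model(tiny_model, path)
        back = modelio.load_model(path)
        assert np.array_equal(back.pop_a.preferred_values, tiny_model.pop_a.preferred_values)
        assert np.array_equal(back.pop_b.tuning_widths, tiny_model.pop_b.tuning_widths)
        assert np.array_equal(back.link.weights, tiny_model.link.weights)
        assert back.norm_bounds == tiny_model.norm_bounds
        assert back.history == tiny_model.history

    def test_loaded_model_infers_identically(self, tmp_path, tiny_model):
        path = tmp_path / "m.json"
        modelio.save_model(tiny_model, path)
        back = modelio.load_model(path)
        grid = np.linspace(0.05, 0.95, 10)
        before = [rs.infer(tiny_model, float(x)) for x in grid]
        after = [rs.infer(back, float(x)) for x in grid]
        assert before == after

    def test_unknown_version_rejected(self, tmp_path, tiny_model):
        path = tmp_path / "m.json"
        modelio.save_model(tiny_model, path)
        doc = json.loads(path.read_text())
        doc["format"] = "relsom-model-99"
        path.write_text(json.dumps(doc))
        with pytest.raises(ModelFormatError, match="relsom-model-99"):
            modelio.load_model(path)

    def test_truncated_file_rejected(self, tmp_path, tiny_model):
        path = tmp_path / "m.json"
        modelio.save_model(tiny_model, path)
        path.write_text(path.read_text()[:100])
        with pytest.raises(ModelFormatError):
            modelio.load_model(path)


class TestConfigFile:
    def test_yaml_round_trip(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_neurons: 30\nseed: 9\nmax_epochs: 50\nnormalization: maxdiv\n")
        cfg = modelio.read_config(path)
        assert cfg.n_neurons == 30 and cfg.seed == 9 and cfg.normalization == "maxdiv"
        assert cfg.schedule.sigma_start == 15.0  # N/2 default tracks n_neurons

    def test_json_is_accepted(self, tmp_path):
        path = tmp_path / "cfg.json"
        path.write_text('{"n_neurons": 20, "seed": 3}')
        assert modelio.read_config(path).n_neurons == 20

    def test_unknown_keys_rejected(self, tmp_path):
        path = tmp_path / "cfg.yaml"
        path.write_text("n_neurons: 30\nlearningrate: 0.5\n")
        with pytest.raises(InvalidConfigError, match="learningrate"):
            modelio.read_config(path)


class TestCli:
    """End-to-end exercise of every subcommand on generated fixtures."""

    def test_simulate_is_seeded_and_repeatable(self, tmp_path):
        runner = CliRunner()
        p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
        for p in (p1, p2):
            result = runner.invoke(
                main, ["simulate", "--law", "cubic", "--seed", "1", "--horizon", "10",
                       "--rate", "1", "--out", str(p)]
            )
            assert result.exit_code == 0, result.output
        assert p1.read_text() == p2.read_text()

    def test_train_infer_export_pipeline(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data.csv"
        model = tmp_path / "model.json"
        history = tmp_path / "history.csv"
        preds = tmp_path / "preds.csv"
        rel = tmp_path / "relation.csv"
        heat = tmp_path / "link.png"

        r = runner.invoke(main, ["simulate", "--law", "cubic", "--seed", "2", "--horizon", "30",
                                 "--rate", "2", "--jitter", "0.1", "--out", str(data)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["train", "--input", str(data), "--neurons", "30",
                                 "--epochs", "600", "--seed", "5", "--out", str(model),
                                 "--history-out", str(history)])
        assert r.exit_code == 0, r.output
        assert model.exists() and history.exists()

        r = runner.invoke(main, ["infer", "--model", str(model), "--x", "10", "--x", "20",
                                 "--out", str(preds)])
        assert r.exit_code == 0, r.output
        lines = preds.read_text().strip().splitlines()
        assert len(lines) == 3  # header + 2 predictions

        r = runner.invoke(main, ["export-relation", "--model", str(model), "--n-grid", "40",
                                 "--out", str(rel), "--heatmap", str(heat)])
        assert r.exit_code == 0, r.output
        assert heat.exists()
        import pandas as pd

        table = pd.read_csv(rel)
        assert len(table) == 40
        # the exported relation should track the generating cubic law
        assert np.corrcoef(table["y"], table["x"] ** 3)[0, 1] > 0.98

    def test_crossval_command(self, tmp_path):
        runner = CliRunner()
        data = tmp_path / "data.csv"
        out = tmp_path / "cv.csv"
        cfg = tmp_path / "cfg.yaml"
        cfg.write_text("n_neurons: 20\nmax_epochs: 40\nseed: 3\n")
        r = runner.invoke(main, ["simulate", "--law", "logistic", "--seed", "3", "--horizon",
                                 "12", "--rate", "1", "--out", str(data)])
        assert r.exit_code == 0, r.output
        r = runner.invoke(main, ["crossval", "--input", str(data), "--config", str(cfg),
                                 "--folds", "3", "--out", str(out)])
        assert r.exit_code == 0, r.output
        import pandas as pd

        table = pd.read_csv(out, index_col=0)
        assert "mean" in table.index and "smape" in table.columns

    def test_evaluate_perfect_predictions(self, tmp_path):
        runner = CliRunner()
        src = tmp_path / "pred.csv"
        out = tmp_path / "report.json"
        src.write_text("y,y_m\n1.0,1.0\n2.0,2.0\n3.0,3.0\n")
        r = runner.invoke(main, ["evaluate", "--input", str(src), "--out", str(out)])
        assert r.exit_code == 0, r.output
        rep = json.loads(out.read_text())[0]
        assert rep["sse"] == 0.0 and rep["rmse"] == 0.0 and rep["smape"] == 0.0

    def test_unknown_subcommand_exits_2(self):
        result = CliRunner().invoke(main, ["transmogrify"])
        assert result.exit_code == 2
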