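"""NSSModel/NSSResults orchestration, serialization, caching, and the CLI."""

import json

import numpy as np
import pandas as pd
import pytest

from nsstruct import NSSModel, get_profile
from nsstruct import pipeline
from nsstruct.profiles import PipelineProfile
from nsstruct.synthetic import make_benchmark, write_benchmark

import conftest


@pytest.fixture(scope="module")
def tiny_fit(tiny_benchmark, tiny_profile):
    bench = tiny_benchmark
    model = NSSModel(
        bench.images, bench.labels, tiny_profile, train_mask=bench.is_train
    )
    return model, model.fit(seed=conftest.SEED)


class TestModelFit:
    def test_results_are_self_consistent(self, tiny_fit):
        model, res = tiny_fit
        n = len(model.images)
        assert len(res.train_idx) + len(res.test_idx) == n
        assert res.counts.shape[0] == n
        K_sel = len(res.selected_ids)
        assert res.spectra.shape == (n, K_sel, res.profile.N_c)
        assert res.features.shape == (n, K_sel * (1 + res.profile.N_c))
        assert res.confusion_matrix.values.shape == (2, 2)
        assert np.allclose(res.confusion_matrix.sum(axis=1), 1.0)
        assert 0.0 <= res.accuracy <= 1.0

    def test_selection_mask_consistency(self, tiny_fit):
        _, res = tiny_fit
        book = res.nss_codebook
        assert np.array_equal(np.flatnonzero(book.selected), res.selected_ids)
        assert book.size == len(book.source_category)

    def test_fit_is_deterministic(self, tiny_benchmark, tiny_profile):
        bench = tiny_benchmark
        accs, cms = [], []
        for _ in range(2):
            model = NSSModel(
                bench.images, bench.labels, tiny_profile,
                train_mask=bench.is_train,
            )
            res = model.fit(seed=3)
            accs.append(res.accuracy)
            cms.append(res.confusion_matrix.values)
        assert accs[0] == accs[1]
        assert np.array_equal(cms[0], cms[1])

    def test_summary_mentions_key_quantities(self, tiny_fit):
        _, res = tiny_fit
        s = res.summary()
        assert "accuracy" in s and "NSS" in s
        assert f"{res.accuracy:.3f}" in s

    def test_occurrence_matrix_diagonal(self, tiny_fit):
        _, res = tiny_fit
        M = res.occurrence_matrix()
        assert np.allclose(np.diag(M.values), 1.0)

    def test_fisher_matrix_shape(self, tiny_fit):
        _, res = tiny_fit
        F = res.fisher_matrix(sel_pos=0)
        assert F.shape == (2, 2)
        assert np.allclose(F.values, F.values.T)


class TestCrossValidate:
    def test_grid_search_returns_table(self, tiny_benchmark, tiny_profile):
        bench = tiny_benchmark
        model = NSSModel(
            bench.images, bench.labels, tiny_profile, train_mask=bench.is_train
        )
        grid = [{"C": 0.125}, {"C": 8.0}]
        best, table = model.cross_validate(grid, n_folds=3, seed=conftest.SEED)
        assert set(best) == {"C"}
        assert len(table) == 2
        assert table["cv_accuracy"].between(0, 1).all()


class TestSerialization:
    def test_ic_bank_roundtrip(self, tiny_fit, tmp_path):
        _, res = tiny_fit
        path = tmp_path / "bank.npz"
        pipeline.save_ic_bank(res.filters, res.cluster_set, path, {"k": 1})
        filters, cset, header = pipeline.load_ic_bank(path)
        assert header == {"k": 1}
        assert len(filters) == len(res.filters)
        assert cset.n_clusters == res.cluster_set.n_clusters
        for a, b in zip(filters, res.filters):
            assert np.array_equal(a.weights, b.weights)
            assert a.cluster_id == b.cluster_id
            assert np.isclose(a.gabor.theta, b.gabor.theta)

    def test_codebook_roundtrip(self, tiny_fit, tmp_path):
        _, res = tiny_fit
        path = tmp_path / "book.npz"
        pipeline.save_codebook(res.nss_codebook, path, {"h": "x"})
        book, header = pipeline.load_codebook(path)
        assert np.allclose(book.centroids, res.nss_codebook.centroids)
        assert np.array_equal(book.selected, res.nss_codebook.selected)
        assert header == {"h": "x"}

    def test_profile_yaml_roundtrip(self, tmp_path):
        p = get_profile("synthetic", L_c=5)
        path = tmp_path / "prof.yaml"
        p.to_yaml(path)
        assert PipelineProfile.from_yaml(path) == p


@pytest.fixture(scope="module")
def disk_dataset(tmp_path_factory):
    out = tmp_path_factory.mktemp("dataset")
    bench = make_benchmark(2, 6, seed=conftest.SEED, size=(160, 160))
    write_benchmark(bench, out)
    return out


class TestRunPipeline:
    def test_run_and_cache(self, disk_dataset, tiny_profile, tmp_path):
        out = tmp_path / "run"
        report = pipeline.run_pipeline(
            tiny_profile, disk_dataset, out, seed=conftest.SEED
        )
        assert (out / "ic_bank.npz").exists()
        assert (out / "codebook.npz").exists()
        assert (out / "report.json").exists()
        assert 0 <= report["mean_per_class_accuracy"] <= 1
        # identical rerun hits the cache and reproduces the report
        again = pipeline.run_pipeline(
            tiny_profile, disk_dataset, out, seed=conftest.SEED
        )
        assert again == report
        # corrupting provenance forces a recompute (with a warning)
        blob = json.loads((out / "report.json").read_text())
        blob["provenance"]["profile_hash"] = "deadbeef"
        (out / "report.json").write_text(json.dumps(blob))
        with pytest.warns(UserWarning):
            fresh = pipeline.run_pipeline(
                tiny_profile, disk_dataset, out, seed=conftest.SEED
            )
        assert fresh["mean_per_class_accuracy"] == report["mean_per_class_accuracy"]

    def test_from_directory_respects_split_tags(self, disk_dataset, tiny_profile):
        model = NSSModel.from_directory(disk_dataset, tiny_profile)
        assert model.train_mask is not None
        # write_benchmark tags 60% of each category as training
        assert model.train_mask.sum() == 2 * int(round(0.6 * 6))


class TestCLI:
    def test_synth_and_run(self, tmp_path, tiny_profile):
        from click.testing import CliRunner
        from nsstruct.cli import main

        runner = CliRunner()
        data = tmp_path / "data"
        r = runner.invoke(
            main, ["synth", "--out", str(data), "--seed", "1",
                   "--n-per-category", "4"]
        )
        assert r.exit_code == 0, r.output
        assert len(list(data.rglob("*.png"))) == 12

        cfg = tmp_path / "prof.yaml"
        tiny_profile.to_yaml(cfg)
        out = tmp_path / "run"
        r = runner.invoke(
            main,
            ["run", str(data), "--out", str(out), "--config", str(cfg),
             "--seed", "1"],
        )
        assert r.exit_code == 0, r.output
        assert (out / "report.json").exists()
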