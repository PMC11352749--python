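"""The planted-signal cohort generator: counts, determinism, signal recovery."""

import numpy as np
import pytest

from fcgan import (FixtureConfig, connectivity_matrix, edge_index,
                   extract_features, make_dataset, make_feature_fixture,
                   n_edges, target_correlations, vectorize_upper)
from fcgan.simulate import _nearest_correlation


class TestMakeDataset:
    def test_exact_site_and_class_counts(self):
        cfg = FixtureConfig(sites=(("A", 10, 10), ("B", 3, 5)), seed=0)
        series, pheno = make_dataset(cfg)
        assert len(series) == 28 and len(pheno) == 28
        counts = {}
        for rec in pheno:
            counts[(rec.site_id, rec.dx_label)] = counts.get(
                (rec.site_id, rec.dx_label), 0) + 1
        assert counts == {("A", "ASD"): 10, ("A", "HC"): 10,
                          ("B", "ASD"): 3, ("B", "HC"): 5}

    def test_timepoints_vary_within_range(self):
        cfg = FixtureConfig(sites=(("A", 30, 30),), timepoints=(50, 90), seed=1)
        series, _ = make_dataset(cfg)
        lengths = {ts.n_timepoints for ts in series}
        assert len(lengths) > 1
        assert all(50 <= t <= 90 for t in lengths)

    def test_seed_determinism(self):
        cfg = FixtureConfig(sites=(("A", 4, 4),), seed=5)
        s1, _ = make_dataset(cfg)
        s2, _ = make_dataset(cfg)
        for a, b in zip(s1, s2):
            assert np.array_equal(a.values, b.values)

    def test_planted_edges_recovered_in_mean_fc(self):
        # Monte-Carlo: empirical FC difference (ASD-HC) concentrates on the
        # planted edges near Δr and near 0 elsewhere
        cfg = FixtureConfig(sites=(("A", 200, 200),), seed=7)
        series, pheno = make_dataset(cfg)
        feats = extract_features(series, pheno)
        y = feats.label_ints()
        diff = (feats.values[y == 1].mean(axis=0)
                - feats.values[y == 0].mean(axis=0))
        planted = np.array([edge_index(i, j, cfg.regions)
                            for i, j in cfg.planted_edges])
        mask = np.zeros(n_edges(cfg.regions), dtype=bool)
        mask[planted] = True
        assert np.abs(diff[mask] - cfg.effect).max() < 0.1
        assert np.abs(diff[~mask]).max() < 0.1

    def test_null_effect_centers_at_zero(self):
        cfg = FixtureConfig(sites=(("A", 150, 150),), effect=0.0, seed=3)
        series, pheno = make_dataset(cfg)
        feats = extract_features(series, pheno)
        y = feats.label_ints()
        diff = (feats.values[y == 1].mean(axis=0)
                - feats.values[y == 0].mean(axis=0))
        assert np.abs(diff).max() < 0.08

    def test_empirical_fc_converges_with_t(self):
        target = target_correlations(FixtureConfig(seed=0))["HC"]
        errs = {}
        for t in (50, 500):
            cfg = FixtureConfig(sites=(("A", 0, 40),), timepoints=(t, t), seed=2)
            series, _ = make_dataset(cfg)
            mats = [connectivity_matrix(ts).matrix for ts in series]
            errs[t] = np.abs(np.mean(mats, axis=0) - target).max()
        assert errs[500] < errs[50]


class TestTargets:
    def test_target_matrices_valid(self):
        targets = target_correlations(FixtureConfig())
        for mat in targets.values():
            assert np.allclose(np.diag(mat), 1.0)
            assert np.array_equal(mat, mat.T)
            assert np.linalg.eigvalsh(mat).min() > 0

    def test_asd_target_differs_only_on_planted_edges(self):
        cfg = FixtureConfig()
        targets = target_correlations(cfg)
        diff = targets["ASD"] - targets["HC"]
        for i, j in cfg.planted_edges:
            assert diff[i, j] == pytest.approx(cfg.effect)
            diff[i, j] = diff[j, i] = 0.0
        assert np.abs(diff).max() == 0.0

    def test_nearest_correlation_repairs_indefinite(self, caplog):
        import logging

        bad = np.array([[1.0, 0.9, -0.2], [0.9, 1.0, 0.6], [-0.2, 0.6, 1.0]])
        assert np.linalg.eigvalsh(bad).min() < 0
        with caplog.at_level(logging.WARNING):
            fixed = _nearest_correlation(bad)
        assert np.linalg.eigvalsh(fixed).min() >= 0
        assert np.allclose(np.diag(fixed), 1.0)
        assert any("repairing" in r.message for r in caplog.records)

    def test_hopelessly_indefinite_rejected(self):
        bad = np.array([[1.0, 0.99, -0.99], [0.99, 1.0, 0.99],
                        [-0.99, 0.99, 1.0]])
        with pytest.raises(ValueError, match="indefinite"):
            _nearest_correlation(bad)


class TestFeatureFixture:
    def test_planted_coordinates_linearly_separable(self):
        cfg = FixtureConfig(sites=(("A", 60, 60),), seed=1)
        table = make_feature_fixture(cfg, noise_sigma=0.1)
        planted = [edge_index(i, j, cfg.regions) for i, j in cfg.planted_edges]
        # closed-form separator: mean of planted coords thresholded at
        # background + Δ/2 must reach >= 0.9 training accuracy
        score = table.values[:, planted].mean(axis=1)
        pred = score > cfg.base_correlation + cfg.effect / 2
        truth = table.label_ints().astype(bool)
        assert (pred == truth).mean() >= 0.9

    def test_null_effect_is_label_symmetric(self):
        cfg = FixtureConfig(sites=(("A", 100, 100),), effect=0.0, seed=2)
        table = make_feature_fixture(cfg)
        y = table.label_ints()
        diff = (table.values[y == 1].mean(axis=0)
                - table.values[y == 0].mean(axis=0))
        assert np.abs(diff).max() < 0.08

    def test_values_clipped(self):
        cfg = FixtureConfig(sites=(("A", 20, 20),), base_correlation=0.9,
                            effect=0.3, seed=0)
        table = make_feature_fixture(cfg, noise_sigma=0.5)
        assert table.values.max() <= 1.0 and table.values.min() >= -1.0


def test_written_dataset_readable_by_loaders(tmp_path):
    from fcgan import read_phenotype, read_roi_timeseries
    from fcgan.simulate import write_dataset

    cfg = FixtureConfig(sites=(("A", 2, 2),), seed=0)
    series, pheno = make_dataset(cfg)
    write_dataset(series, pheno, tmp_path)
    recs = read_phenotype(tmp_path / "phenotype.csv")
    assert len(recs) == 4
    ts = read_roi_timeseries(tmp_path / "roi" / f"{series[0].subject_id}.1D")
    assert np.allclose(ts.values, series[0].values, atol=1e-9)
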