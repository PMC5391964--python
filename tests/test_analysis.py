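"""Post-processing statistics: distributions, normalization, clustering,
PCA, level calls and density maps."""

import numpy as np
import pandas as pd
import pytest

from racipe.analysis import (assign_expression_levels, axis_silhouette,
                             density_map, half_functional_fractions,
                             hierarchical_clustering, normalize_expression,
                             pca_projection, state_count_distribution)


class TestStateCountDistribution:
    def test_counts_once_per_model(self, ts_ensemble):
        dist = state_count_distribution(ts_ensemble)
        assert dist.sum() == pytest.approx(1.0)
        # weights come from models, not rows: a bistable model counts once
        n_models = ts_ensemble.expression["model_id"].nunique()
        assert dist.loc[2] == pytest.approx(
            (ts_ensemble.states_per_model() == 2).sum() / n_models)

    def test_single_model_degenerate(self, ts_ensemble):
        sub = ts_ensemble
        one = sub.expression[sub.expression["model_id"]
                             == sub.expression["model_id"].iloc[0]]
        import dataclasses
        res = dataclasses.replace(sub, expression=one)
        dist = state_count_distribution(res)
        assert set(dist.index) == {one["n_states"].iloc[0]}
        assert dist.iloc[0] == 1.0


class TestHalfFunctional:
    def test_forced_thresholds_give_extreme_fractions(self, ts_ensemble):
        import dataclasses
        params = ts_ensemble.parameters.copy()
        params[["x0[A->B]", "x0[B->A]"]] = 1e-9
        res = dataclasses.replace(ts_ensemble, parameters=params)
        assert (half_functional_fractions(res) == 1.0).all()
        params[["x0[A->B]", "x0[B->A]"]] = 1e9
        res = dataclasses.replace(ts_ensemble, parameters=params)
        assert (half_functional_fractions(res) == 0.0).all()


class TestNormalization:
    def test_constant_column_maps_to_zero(self):
        df = pd.DataFrame({"g1": [5.0, 5.0, 5.0], "g2": [1.0, 10.0, 100.0]})
        z = normalize_expression(df)
        assert np.allclose(z["g1"], 0.0)

    def test_two_point_standardization(self):
        z = normalize_expression(pd.DataFrame({"g": [10.0, 1000.0]}))
        assert np.allclose(sorted(z["g"]), [-1.0, 1.0])

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            normalize_expression(pd.DataFrame({"g": [1.0, 0.0]}))

    def test_ts_ensemble_is_bimodal_per_gene(self, ts_ensemble):
        z = normalize_expression(ts_ensemble.levels())
        for gene in ("A", "B"):
            # central dip: fewer rows near zero than in the two flanks
            vals = z[gene]
            center = ((vals > -0.25) & (vals < 0.25)).mean()
            flank = ((vals > 0.5) & (vals < 1.0)).mean()
            assert center < flank


class TestClustering:
    def test_ts_two_mirror_clusters(self, ts_ensemble):
        z = normalize_expression(ts_ensemble.levels())
        labels = hierarchical_clustering(z, 2)
        table = assign_expression_levels(ts_ensemble.levels(), labels)
        calls = {tuple(row) for _, row in table.calls.iterrows()}
        assert ("HIGH", "LOW") in calls and ("LOW", "HIGH") in calls

    def test_labels_ordered_by_occupancy(self, ts_ensemble):
        z = normalize_expression(ts_ensemble.levels())
        labels = hierarchical_clustering(z, 3)
        counts = pd.Series(labels).value_counts()
        assert list(counts.index) == sorted(counts.index)
        assert counts.is_monotonic_decreasing

    def test_duplicated_rows_stay_together(self):
        base = np.array([[0.0, 0.0], [0.01, 0.0], [5.0, 5.0], [5.0, 5.01]])
        labels = hierarchical_clustering(base, 2)
        assert labels[0] == labels[1] and labels[2] == labels[3]
        assert labels[0] != labels[2]

    def test_deterministic(self, ts_ensemble):
        z = normalize_expression(ts_ensemble.levels())
        a = hierarchical_clustering(z, 2)
        b = hierarchical_clustering(z, 2)
        assert np.array_equal(a, b)

    def test_too_many_clusters_rejected(self):
        with pytest.raises(ValueError):
            hierarchical_clustering(np.zeros((3, 2)), 4)


class TestPCA:
    def test_rank_one_matrix(self):
        rng = np.random.default_rng(0)
        u = rng.normal(size=30)
        X = np.outer(u, [1.0, 2.0])
        coords, evr, comps = pca_projection(X)
        assert evr[0] == pytest.approx(1.0)

    def test_mirror_symmetric_ts_loadings(self, ts_ensemble):
        z = normalize_expression(ts_ensemble.levels())
        coords, evr, comps = pca_projection(z)
        # anti-correlated genes: PC1 loadings of A and B have opposite signs
        assert comps[0, 0] * comps[0, 1] < 0
        # two separated clouds along PC1: strong bimodality
        assert evr[0] > 0.8

    def test_sign_convention_deterministic(self, ts_ensemble):
        z = normalize_expression(ts_ensemble.levels())
        a = pca_projection(z)[0]
        b = pca_projection(-1.0 * z.iloc[::-1].reset_index(drop=True))[0]
        # largest-magnitude loading forced positive: orientation is fixed
        assert abs(a[0, 0]) == pytest.approx(abs(b[-1, 0]), rel=1e-6)

    def test_degenerate_matrix_rejected(self):
        with pytest.raises(ValueError):
            pca_projection(np.ones((5, 3)))


class TestLevelCalls:
    def test_extremes_called_high_and_low(self):
        levels = pd.DataFrame({"g": np.r_[np.full(10, 1.0),
                                          np.full(10, 1000.0)]})
        labels = np.r_[np.zeros(10, int), np.ones(10, int)]
        table = assign_expression_levels(levels, labels)
        assert table.calls.loc[0, "g"] == "LOW"
        assert table.calls.loc[1, "g"] == "HIGH"

    def test_monotone_rescaling_invariance(self, ts_ensemble):
        levels = ts_ensemble.levels()
        z = normalize_expression(levels)
        labels = hierarchical_clustering(z, 2)
        a = assign_expression_levels(levels, labels)
        squashed = levels.copy()
        squashed["A"] = np.sqrt(squashed["A"])   # monotone per-gene map
        b = assign_expression_levels(squashed, labels)
        pd.testing.assert_frame_equal(a.calls, b.calls)

    def test_incomplete_labels_rejected(self):
        with pytest.raises(ValueError):
            assign_expression_levels(pd.DataFrame({"g": [1.0, 2.0]}), [0])


class TestDensityMap:
    def test_normalized_to_unit_mass(self, ts_ensemble):
        hist, xe, ye = density_map(ts_ensemble.levels(), ("A", "B"),
                                   bins=40, log=True)
        assert hist.sum() == pytest.approx(1.0)
        # bimodal: occupied cells in at least two well-separated regions
        occupied = np.argwhere(hist > 0.002)
        assert len(occupied) >= 2
        spread = np.abs(occupied - occupied.mean(axis=0)).sum(axis=1)
        assert spread.max() > 5

    def test_single_row(self):
        hist, _, _ = density_map(pd.DataFrame({"A": [3.0], "B": [4.0]}),
                                 ("A", "B"), bins=10)
        assert hist.max() == pytest.approx(1.0)

    def test_unknown_gene(self, ts_ensemble):
        with pytest.raises(ValueError):
            density_map(ts_ensemble.levels(), ("A", "Z"))


class TestAxisSilhouette:
    def test_separable_beats_overlapping_projection(self):
        rng = np.random.default_rng(1)
        n = 200
        labels = np.r_[np.zeros(n, int), np.ones(n, int)]
        sep = np.r_[rng.normal(1, 0.1, n), rng.normal(10, 1.0, n)]
        mixed = rng.lognormal(0, 1, 2 * n)
        df = pd.DataFrame({"good": sep, "noise1": mixed,
                           "noise2": rng.lognormal(0, 1, 2 * n)})
        good = axis_silhouette(df, labels, ("good", "noise1"))
        bad = axis_silhouette(df, labels, ("noise1", "noise2"))
        assert good > bad
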