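import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score
from sklearn.utils.estimator_checks import check_estimator  # noqa: F401  (import sanity)

from regscreen.cluster import (
    ClusterAssignment,
    FuzzyCMeans,
    assign_clusters,
    fold_change_profiles,
    reference_clusters,
    standardize,
)
from regscreen.diffexpr import fit_contrasts
from regscreen.simulate import SimulationConfig, simulate_experiment


class TestStandardize:
    def test_arithmetic_identity(self):
        out = standardize(pd.DataFrame([[1.0, 2.0, 3.0]], index=["g"]))
        assert np.allclose(out.matrix.loc["g"], [-1.0, 0.0, 1.0])

    def test_constant_rows_dropped(self):
        out = standardize(
            pd.DataFrame([[5.0, 5.0, 5.0], [1.0, 2.0, 3.0]], index=["flat", "g"])
        )
        assert out.dropped_genes == ["flat"]
        assert list(out.matrix.index) == ["g"]

    def test_rows_have_zero_mean_unit_sd(self):
        rng = np.random.default_rng(0)
        out = standardize(pd.DataFrame(rng.normal(size=(100, 6))))
        assert np.abs(out.matrix.mean(axis=1)).max() < 1e-9
        assert np.abs(out.matrix.std(axis=1, ddof=1) - 1).max() < 1e-9

    def test_single_column_rejected(self):
        with pytest.raises(ValueError, match=">=2 columns"):
            standardize(pd.DataFrame([[1.0]]))


class TestFuzzyCMeans:
    def _two_groups(self, rng, spread=0.05):
        a = rng.normal(0.0, spread, size=(20, 3))
        b = rng.normal(0.0, spread, size=(20, 3)) + 4.0
        return np.vstack([a, b])

    def test_separated_groups_recovered_crisply(self):
        rng = np.random.default_rng(0)
        X = self._two_groups(rng)
        model = FuzzyCMeans(n_clusters=2, m=1.25, random_state=0).fit(X)
        assert model.membership_.max(axis=1).min() > 0.99
        centers = model.cluster_centers_[np.argsort(model.cluster_centers_[:, 0])]
        assert np.allclose(centers[0], X[:20].mean(axis=0), atol=0.05)
        assert np.allclose(centers[1], X[20:].mean(axis=0), atol=0.05)

    def test_memberships_row_stochastic(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(50, 4))
        model = FuzzyCMeans(n_clusters=5, m=1.5, random_state=1).fit(X)
        assert np.all(model.membership_ >= 0)
        assert np.all(model.membership_ <= 1)
        assert np.allclose(model.membership_.sum(axis=1), 1.0, atol=1e-9)

    def test_equidistant_point_gets_symmetric_membership(self):
        model = FuzzyCMeans(n_clusters=2, m=2.0)
        model.cluster_centers_ = np.array([[-1.0, 0.0], [1.0, 0.0]])
        model.n_features_in_ = 2
        U = model.predict_proba(np.array([[0.0, 0.5]]))
        assert np.allclose(U, [[0.5, 0.5]], atol=1e-12)

    def test_point_on_centroid_gets_full_membership(self):
        model = FuzzyCMeans(n_clusters=2, m=2.0)
        model.cluster_centers_ = np.array([[-1.0, 0.0], [1.0, 0.0]])
        model.n_features_in_ = 2
        U = model.predict_proba(np.array([[-1.0, 0.0]]))
        assert np.allclose(U, [[1.0, 0.0]], atol=0)

    def test_converged_solution_is_stationary(self):
        # one extra alternating update changes nothing beyond 1e-6
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 4))
        model = FuzzyCMeans(n_clusters=3, m=1.6, tol=1e-10, max_iter=2000,
                            random_state=2).fit(X)
        U, V = model.membership_, model.cluster_centers_
        Um = U**model.m
        V_next = (Um.T @ X) / Um.sum(axis=0)[:, None]
        assert np.abs(V_next - V).max() < 1e-6
        d2 = ((X[:, None, :] - V[None, :, :]) ** 2).sum(axis=2)
        w = d2 ** (-1.0 / (model.m - 1.0))
        U_next = w / w.sum(axis=1, keepdims=True)
        assert np.abs(U_next - U).max() < 1e-6

    def test_objective_trace_non_increasing(self):
        rng = np.random.default_rng(3)
        X = rng.normal(size=(60, 5))
        for seed in range(10):
            model = FuzzyCMeans(n_clusters=4, m=1.3, n_init=1, random_state=seed).fit(X)
            assert np.all(np.diff(model.objective_trace_) <= 1e-9)

    def test_gene_permutation_permutes_outputs(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 4))
        perm = rng.permutation(30)
        a = FuzzyCMeans(n_clusters=3, m=1.25, random_state=7).fit(X)
        b = FuzzyCMeans(n_clusters=3, m=1.25, random_state=7)
        b.cluster_centers_ = a.cluster_centers_
        b.n_features_in_ = 4
        assert np.array_equal(a.predict(X)[perm], b.predict(X[perm]))

    def test_invalid_inputs_rejected(self):
        X = np.zeros((5, 2))
        with pytest.raises(ValueError):
            FuzzyCMeans(n_clusters=5).fit(X)  # c >= n samples
        with pytest.raises(ValueError):
            FuzzyCMeans(n_clusters=2, m=1.0).fit(X)
        with pytest.raises(ValueError):
            FuzzyCMeans(n_clusters=2).fit(np.array([[np.nan, 1.0]] * 5))

    def test_sklearn_params_roundtrip(self):
        model = FuzzyCMeans(n_clusters=4, m=1.5)
        assert model.get_params()["m"] == 1.5
        model.set_params(n_clusters=3)
        assert model.n_clusters == 3

    def test_planted_cluster_recovery(self):
        cfg = SimulationConfig(
            n_genes=600, n_scaffolds=6, n_clusters=6, cluster_sizes=[100] * 6,
            noise_sd=0.5, n_regions=0, n_regulators=0, rng_seed=0,
        )
        ds = simulate_experiment(cfg)
        std = standardize(fold_change_profiles(fit_contrasts(ds.expression)))
        model = FuzzyCMeans(n_clusters=6, m=1.25, random_state=0).fit(
            std.matrix.to_numpy()
        )
        truth = ds.truth.cluster_labels.reindex(std.matrix.index).to_numpy()
        assert adjusted_rand_score(truth, model.labels_) >= 0.8


class TestAssignment:
    def _assignment(self, rows, alpha=0.5):
        model = FuzzyCMeans(n_clusters=len(rows[0]))
        model.membership_ = np.array(rows)
        model.cluster_centers_ = np.zeros((len(rows[0]), 2))
        return assign_clusters(model, pd.Index([f"g{i}" for i in range(len(rows))]), alpha)

    def test_dominant_membership_is_core(self):
        table = self._assignment([[0.7, 0.2, 0.1]]).table
        assert table.loc["g0", "cluster"] == 0
        assert bool(table.loc["g0", "core"])

    def test_sub_threshold_max_is_not_core(self):
        table = self._assignment([[0.34, 0.33, 0.33]]).table
        assert table.loc["g0", "cluster"] == 0
        assert not bool(table.loc["g0", "core"])

    def test_exact_tie_breaks_to_lowest_cluster(self):
        table = self._assignment([[0.5, 0.5]]).table
        assert table.loc["g0", "cluster"] == 0
        assert bool(table.loc["g0", "core"])


class TestReferenceClusters:
    def _assignment(self, labels):
        table = pd.DataFrame(
            {"cluster": labels, "max_membership": 1.0, "core": True},
            index=pd.Index([f"g{i}" for i in range(len(labels))], name="gene_id"),
        )
        return ClusterAssignment(table=table)

    def test_cumulative_coverage_flags_top_clusters(self):
        # references split 8/5/1 over clusters 0/1/2; 90% coverage -> {0, 1}
        labels = [0] * 8 + [1] * 5 + [2] * 1 + [0] * 3 + [1] * 2
        assignment = self._assignment(labels)
        refs = [f"g{i}" for i in range(14)]
        flagged, co = reference_clusters(assignment, refs, coverage=0.9)
        assert flagged == [0, 1]
        assert set(co) == {"g14", "g15", "g16", "g17", "g18"}

    def test_single_cluster_references(self):
        assignment = self._assignment([3, 3, 3, 1])
        flagged, co = reference_clusters(assignment, ["g0", "g1", "g2"])
        assert flagged == [3]
        assert co == []

    def test_empty_reference_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            reference_clusters(self._assignment([0, 1]), [])

    def test_zero_noise_co_clustered_equals_planted_membership(self, tiny_zero_noise):
        ds = tiny_zero_noise
        std = standardize(fold_change_profiles(fit_contrasts(ds.expression)))
        planted = set(ds.truth.cluster_labels[ds.truth.cluster_labels >= 0].index)
        # zero-noise background genes have constant (zero) fold-change rows
        # and are dropped; the retained genes are exactly the planted clusters
        assert set(std.matrix.index) == planted
        model = FuzzyCMeans(n_clusters=2, m=1.25, random_state=0).fit(
            std.matrix.to_numpy()
        )
        assignment = assign_clusters(model, std.matrix.index)
        flagged, co = reference_clusters(assignment, ds.reference_genes)
        assert set(co) == planted - set(ds.reference_genes)
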