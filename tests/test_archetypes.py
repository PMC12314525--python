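"""Tests for feature selection, QC, classical/deep archetypal analysis,
projection and group summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import linear_sum_assignment

from clonearch import archetypes as aa
from clonearch import synthetic as syn


def matched_cosine(Z_hat, Z_true):
    """Mean cosine similarity after optimal archetype permutation."""
    num = Z_hat @ Z_true.T
    den = (np.linalg.norm(Z_hat, axis=1)[:, None]
           * np.linalg.norm(Z_true, axis=1)[None, :])
    C = num / den
    r, c = linear_sum_assignment(-C)
    return C[r, c].mean()


class TestSelectFeatures:
    def _phases(self, n_genes=30, seed=0):
        rng = np.random.default_rng(seed)
        genes = [f"g{i}" for i in range(n_genes)]
        # variance decreasing in gene index, identically ranked in all phases
        scale = np.linspace(4.0, 0.1, n_genes)
        mats = {
            phase: rng.normal(0, 1, (40, n_genes)) * scale[None, :]
            for phase in ("drug", "regrowth", "parental")
        }
        return mats, genes

    def test_nested_rankings_give_smallest_top_set(self):
        mats, genes = self._phases()
        fm = aa.select_features(
            mats, {"drug": 20, "regrowth": 10, "parental": 5}, genes)
        assert len(fm.feature_names) == 5
        assert set(fm.feature_names) <= {f"g{i}" for i in range(8)}
        assert fm.selection_provenance["intersection_size"] == 5

    def test_result_is_z_scored(self):
        mats, genes = self._phases()
        fm = aa.select_features(
            mats, {"drug": 20, "regrowth": 10, "parental": 5}, genes)
        assert np.allclose(fm.values.mean(axis=0), 0.0, atol=1e-6)
        assert np.allclose(fm.values.std(axis=0), 1.0, atol=1e-6)

    def test_disjoint_top_sets_raise(self):
        genes = [f"g{i}" for i in range(10)]
        rng = np.random.default_rng(1)
        base = rng.normal(0, 0.01, (20, 10))
        a = base.copy()
        a[:, :5] += rng.normal(0, 5, (20, 5))
        b = base.copy()
        b[:, 5:] += rng.normal(0, 5, (20, 5))
        with pytest.raises(ValueError, match="intersection"):
            aa.select_features({"drug": a, "parental": b},
                               {"drug": 5, "parental": 5}, genes)

    def test_planted_shared_high_variance_genes_recovered(self):
        rng = np.random.default_rng(2)
        genes = [f"g{i}" for i in range(50)]
        planted = {"g3", "g17", "g29", "g41"}
        mats = {}
        for phase in ("drug", "regrowth", "parental"):
            M = rng.normal(0, 0.1, (30, 50))
            for g in planted:
                M[:, genes.index(g)] = rng.normal(0, 10, 30)
            mats[phase] = M
        fm = aa.select_features(mats, {p: 4 for p in mats}, genes)
        assert set(fm.feature_names) == planted


class TestQcFilter:
    def _matrix(self):
        genes = ["MT-CO1", "MT-ND1"] + [f"g{i}" for i in range(1500)]
        return genes

    def test_mito_and_gene_count_boundaries(self):
        genes = self._matrix()
        n = len(genes)
        cells = np.zeros((4, n), dtype=int)
        # cell 0: exactly 30% mito reads, plenty of genes -> retained
        cells[0, 2:1202] = 1
        cells[0, 0] = 514  # 514 mito + 514·(1200/514)... set explicitly below
        cells[0, 2:1202] = 1
        cells[0, 0] = int(round(0.3 / 0.7 * 1200))
        # cell 1: 40% mito -> removed
        cells[1, 2:1202] = 1
        cells[1, 0] = 800
        # cell 2: exactly 1000 genes -> retained
        cells[2, 2:1002] = 1
        # cell 3: 999 genes -> removed
        cells[3, 2:1001] = 1
        mito_frac = cells[:, :2].sum(1) / cells.sum(1)
        assert mito_frac[0] <= 0.30 < mito_frac[1]
        filtered, keep, report = aa.qc_filter_cells(cells, genes)
        assert list(keep) == [True, False, True, False]
        assert report["n_removed_mito"] == 1
        assert report["n_removed_min_genes"] == 1

    def test_clean_matrix_is_identity(self):
        genes = self._matrix()
        cells = np.zeros((3, len(genes)), dtype=int)
        cells[:, 2:1202] = 1
        filtered, keep, report = aa.qc_filter_cells(cells, genes)
        assert keep.all()
        assert filtered.shape == cells.shape

    def test_no_mito_genes_errors_unless_disabled(self):
        genes = [f"g{i}" for i in range(1200)]
        cells = np.ones((2, 1200), dtype=int)
        with pytest.raises(ValueError, match="mito"):
            aa.qc_filter_cells(cells, genes)
        _, keep, _ = aa.qc_filter_cells(cells, genes, mito_fraction_max=None)
        assert keep.all()

    def test_doublet_flags_removed(self):
        genes = self._matrix()
        cells = np.zeros((2, len(genes)), dtype=int)
        cells[:, 2:1202] = 1
        _, keep, report = aa.qc_filter_cells(
            cells, genes, doublet_flags=[False, True])
        assert list(keep) == [True, False]
        assert report["n_removed_doublet"] == 1


class TestClassicalAA:
    def test_k1_archetype_is_the_mean_with_total_variance_loss(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_classical(X, 1, seed=0)
        assert np.allclose(model.Z[0], X.mean(axis=0), atol=1e-6)
        assert model.loss == pytest.approx(np.sum((X - X.mean(0)) ** 2), rel=1e-9)

    def test_vertex_dataset_recovered_exactly(self, vertex_dataset):
        X, Z_true = vertex_dataset
        model = aa.fit_archetypes_classical(X, 4, seed=0)
        assert model.loss < 1e-8
        assert model.A.max(axis=1).min() > 1 - 1e-6  # one-hot rows
        assert matched_cosine(model.Z, Z_true) > 0.9999

    def test_noiseless_simulation_recovery(self, archetype_sim):
        X, _, Z_true = archetype_sim
        model = aa.fit_archetypes_classical(X, 4, seed=0)
        assert matched_cosine(model.Z, Z_true) > 0.99

    def test_objective_monotone_non_increasing(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_classical(X, 3, seed=1)
        hist = model.fit_metadata["loss_history"]
        assert all(hist[i + 1] <= hist[i] * (1 + 1e-12) + 1e-9
                   for i in range(len(hist) - 1))

    def test_rows_of_a_and_b_are_stochastic(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_classical(X, 4, seed=0)
        for mat in (model.A, model.B):
            assert (mat >= -1e-12).all()
            assert np.allclose(mat.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(model.Z, model.B @ X, atol=1e-10)

    def test_loss_non_increasing_in_k(self, archetype_sim):
        X, _, _ = archetype_sim
        losses = [aa.fit_archetypes_classical(X, k, seed=0).loss
                  for k in range(1, 6)]
        assert all(losses[i + 1] <= losses[i] * (1 + 1e-9)
                   for i in range(len(losses) - 1))

    def test_k_out_of_range_rejected(self, archetype_sim):
        X, _, _ = archetype_sim
        with pytest.raises(ValueError):
            aa.fit_archetypes_classical(X, X.shape[0] + 1)


class TestDeepAA:
    def test_vertex_dataset_trains_to_one_hot(self, vertex_dataset):
        X, _ = vertex_dataset
        model = aa.fit_archetypes_deep(X, 4, hidden_sizes=(64, 64),
                                       epochs=1500, seed=0)
        assert model.loss < 1e-3 * model.fit_metadata["initial_loss"]
        assert model.A.max(axis=1).min() > 0.95

    def test_rows_stochastic_by_construction(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_deep(X[:100], 3, hidden_sizes=(16, 16),
                                       epochs=30, seed=0)
        assert np.allclose(model.A.sum(axis=1), 1.0, atol=1e-6)
        assert np.allclose(model.B.sum(axis=1), 1.0, atol=1e-6)
        assert (model.A >= 0).all() and (model.B >= 0).all()

    def test_two_cluster_1d_archetypes_bracket_data(self):
        rng = np.random.default_rng(0)
        x = np.concatenate([rng.normal(-2, 0.05, 100),
                            rng.normal(2, 0.05, 100)])[:, None]
        model = aa.fit_archetypes_deep(x, 2, hidden_sizes=(16, 16),
                                       epochs=15000, learning_rate=1e-2, seed=1)
        lo, hi = sorted(model.Z[:, 0])
        assert (x[:, 0] >= lo - 0.05).all()
        assert (x[:, 0] <= hi + 0.05).all()

    def test_minibatch_training_runs_and_matches_shapes(self, vertex_dataset):
        X, _ = vertex_dataset
        model = aa.fit_archetypes_deep(X, 4, hidden_sizes=(32, 32),
                                       epochs=50, batch_size=64, seed=0)
        assert model.A.shape == (X.shape[0], 4)
        assert model.B.shape == (4, X.shape[0])

    @pytest.mark.filterwarnings("ignore::RuntimeWarning")
    def test_divergence_raises_informative_error(self, vertex_dataset):
        X, _ = vertex_dataset
        with pytest.raises(aa.TrainingDivergedError, match="epoch"):
            aa.fit_archetypes_deep(X, 4, epochs=200,
                                   learning_rate=1e200, seed=0)

    def test_seeded_refit_is_identical(self, vertex_dataset):
        X, _ = vertex_dataset
        m1 = aa.fit_archetypes_deep(X, 3, hidden_sizes=(16,), epochs=20, seed=7)
        m2 = aa.fit_archetypes_deep(X, 3, hidden_sizes=(16,), epochs=20, seed=7)
        assert np.array_equal(m1.A, m2.A)
        assert np.array_equal(m1.Z, m2.Z)


class TestProjection:
    def test_archetype_profile_projects_to_unit_weight(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_classical(X, 4, seed=0)
        A_new = aa.project_onto_archetypes(model, model.Z)
        assert np.allclose(np.sort(A_new.max(axis=1)), 1.0, atol=1e-4)

    def test_midpoint_projects_to_half_half(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_classical(X, 4, seed=0)
        mid = (model.Z[0] + model.Z[1]) / 2
        w = aa.project_onto_archetypes(model, mid[None, :])[0]
        # oracle: the quadratic program has the symmetric solution
        assert w[0] == pytest.approx(0.5, abs=1e-3)
        assert w[1] == pytest.approx(0.5, abs=1e-3)
        assert w[2:].max() < 1e-3

    def test_projecting_training_data_reproduces_weights(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_classical(X, 4, seed=0)
        A_new = aa.project_onto_archetypes(model, X)
        assert np.abs(A_new - model.A).mean() < 0.05

    def test_projection_idempotent_on_decoded_profiles(self, vertex_dataset):
        X, _ = vertex_dataset
        model = aa.fit_archetypes_deep(X, 4, hidden_sizes=(64, 64),
                                       epochs=1500, seed=0)
        A1 = aa.project_onto_archetypes(model, model.Z)
        A2 = aa.project_onto_archetypes(model, A1 @ model.Z)
        assert np.abs(A1 - A2).max() < 1e-3

    def test_feature_mismatch_errors(self, archetype_sim):
        X, _, _ = archetype_sim
        model = aa.fit_archetypes_classical(X, 3, seed=0)
        with pytest.raises(ValueError, match="feature"):
            aa.project_onto_archetypes(model, X[:, :5])
        model.feature_names = [f"f{i}" for i in range(X.shape[1])]
        df = pd.DataFrame(X[:, :8], columns=[f"f{i}" for i in range(8)])
        with pytest.raises(ValueError, match="f8"):
            aa.project_onto_archetypes(model, df)


class TestGroupMeans:
    def test_single_label_equals_column_means(self, rng):
        A = rng.dirichlet(np.ones(3), size=20)
        out = aa.archetype_group_means(A, ["all"] * 20)
        assert np.allclose(out.loc["all"], A.mean(axis=0))

    def test_one_hot_groups_recover_identity_rows(self):
        A = np.vstack([np.tile([1, 0, 0], (5, 1)), np.tile([0, 1, 0], (5, 1))])
        out = aa.archetype_group_means(A, ["g1"] * 5 + ["g2"] * 5)
        assert np.allclose(out.loc["g1"], [1, 0, 0])
        assert np.allclose(out.loc["g2"], [0, 1, 0])

    def test_rows_sum_to_one(self, rng):
        A = rng.dirichlet(np.ones(4), size=30)
        labels = rng.choice(["a", "b", "c"], size=30)
        out = aa.archetype_group_means(A, labels)
        assert np.allclose(out.sum(axis=1), 1.0, atol=1e-9)

    def test_unassigned_cells_warned_and_skipped(self, rng):
        A = rng.dirichlet(np.ones(2), size=4)
        with pytest.warns(UserWarning, match="unassigned"):
            out = aa.archetype_group_means(A, ["a", None, "a", None])
        assert list(out.index) == ["a"]
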