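import numpy as np
import pandas as pd
import pytest

from trussmorph.discrimination import (
    PCAConfig,
    dfa_fit,
    dfa_loocv,
    mahalanobis_centroids,
    pca,
    upgma,
)
from trussmorph.errors import SingularityError, ValidationError
from tests.conftest import make_corrected


# ---------------------------------------------------------------------------
# PCA
# ---------------------------------------------------------------------------


class TestPCA:
    def _exact_corr_pair(self, rng, r, n=100):
        """Two variables whose sample correlation is exactly r."""
        z = rng.normal(size=(n, 2))
        z -= z.mean(axis=0)
        q, _ = np.linalg.qr(z)
        z1, z2 = q[:, 0], q[:, 1]
        x = z1
        y = r * z1 + np.sqrt(1 - r**2) * z2
        return np.column_stack([x, y])

    def test_two_variable_closed_form(self, rng):
        """Correlation r = 0.8 gives eigenvalues 1 ± r and one retained component."""
        X = self._exact_corr_pair(rng, 0.8)
        res = pca(pd.DataFrame(X, columns=["a", "b"]))
        np.testing.assert_allclose(res.eigenvalues, [1.8, 0.2], atol=1e-10)
        assert res.retained == 1

    def test_independent_variables_identity_limit(self, rng):
        n = 20000
        X = rng.normal(size=(n, 4))
        res = pca(pd.DataFrame(X))
        np.testing.assert_allclose(res.eigenvalues, 1.0, atol=0.06)
        assert res.retained == 4

    def test_threshold_boundary_inclusive(self, rng):
        """Eigenvalues (2.5, 1.0, 0.7, 0.3) with threshold 0.7 retain 3 components."""
        target = np.array([2.5, 1.0, 0.7, 0.3])
        n = 50
        Z = rng.normal(size=(n, 4))
        Z -= Z.mean(axis=0)
        q, _ = np.linalg.qr(Z)
        X = q * np.sqrt((n - 1) * target)  # exact sample covariance = diag(target)
        res = pca(pd.DataFrame(X), PCAConfig(matrix="covariance"))
        np.testing.assert_allclose(res.eigenvalues, target, atol=1e-8)
        assert res.retained == 3

    def test_eigenvalues_sum_to_variable_count(self, rng):
        X = rng.normal(size=(40, 7)) @ rng.normal(size=(7, 7))
        res = pca(pd.DataFrame(X))
        assert res.eigenvalues.sum() == pytest.approx(7, abs=1e-8)
        assert res.variance_pct.sum() == pytest.approx(100, abs=1e-8)

    def test_scores_uncorrelated(self, rng):
        X = rng.normal(size=(60, 5)) @ rng.normal(size=(5, 5))
        res = pca(pd.DataFrame(X))
        c = np.cov(res.scores.values, rowvar=False)
        np.testing.assert_allclose(c - np.diag(np.diag(c)), 0, atol=1e-8)

    def test_constant_variable_named(self, rng):
        X = np.column_stack([np.ones(10), rng.normal(size=10)])
        with pytest.raises(ValidationError, match="v0"):
            pca(pd.DataFrame(X, columns=["v0", "v1"]))


# ---------------------------------------------------------------------------
# DFA
# ---------------------------------------------------------------------------


def _clusters(rng, centers, n_per, scale=1.0):
    X = np.vstack([rng.normal(c, scale, size=(n_per, len(c))) for c in centers])
    labels = sum([[f"g{i}"] * n_per for i in range(len(centers))], [])
    return make_corrected(X, labels)


class TestDFA:
    def test_separated_clusters_classified_perfectly(self, rng):
        centers = [(0, 0, 0), (15, 0, 0)]
        table = _clusters(rng, centers, 10)
        res = dfa_fit(table, loocv=True)
        assert res.classification_original.overall_pct == 100.0
        assert res.classification_loocv.overall_pct == 100.0

    def test_rows_sum_to_100(self, rng):
        table = _clusters(rng, [(0, 0), (1, 0), (0, 1)], 8)
        res = dfa_fit(table)
        np.testing.assert_allclose(
            res.classification_original.percentages.sum(axis=1), 100, atol=0.1
        )

    def test_chance_level_under_permuted_labels(self, rng):
        """Random labels on one Gaussian cloud give ~20% accuracy with 5 groups."""
        reps = 300
        accs = []
        for _ in range(reps):
            X = rng.normal(size=(50, 3))
            labels = np.repeat([f"g{i}" for i in range(5)], 10)
            rng.shuffle(labels)
            table = make_corrected(X, labels)
            accs.append(dfa_fit(table).classification_original.overall_pct)
        # resubstitution on noise is optimistically biased above 1/k; LOOCV
        # removes that bias but is slower, so allow the documented band
        assert abs(np.mean(accs) - 20.0) < 15.0

    def test_chance_level_loocv(self, rng):
        accs = []
        for _ in range(60):
            X = rng.normal(size=(50, 3))
            labels = np.repeat([f"g{i}" for i in range(5)], 10)
            rng.shuffle(labels)
            table = make_corrected(X, labels)
            accs.append(dfa_loocv(table).overall_pct)
        assert abs(np.mean(accs) - 20.0) < 5.0

    def test_affine_invariance_of_classification(self, rng):
        table = _clusters(rng, [(0, 0, 0), (2, 1, 0), (0, 1, 2)], 12)
        res1 = dfa_fit(table)
        A = rng.normal(size=(3, 3)) + 3 * np.eye(3)
        table2 = make_corrected(table.values.values @ A, table.species)
        res2 = dfa_fit(table2)
        pd.testing.assert_frame_equal(
            res1.classification_original.counts, res2.classification_original.counts
        )

    def test_number_of_functions(self, rng):
        table = _clusters(rng, [(0, 0, 0, 0), (1, 0, 0, 0), (0, 1, 0, 0)], 10)
        res = dfa_fit(table)
        assert res.canonical_coefficients.shape == (4, 2)  # min(k-1, p) = 2

    def test_agrees_with_reference_lda(self, rng):
        """Predictions match scikit-learn's LDA with uniform priors."""
        from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

        X = np.vstack(
            [rng.normal(c, 1.0, size=(15, 4)) for c in [(0,) * 4, (1, 0, 2, 0), (0, 2, 0, 1)]]
        )
        labels = np.repeat(["a", "b", "c"], 15)
        table = make_corrected(X, labels)
        res = dfa_fit(table)

        lda = LinearDiscriminantAnalysis(priors=[1 / 3] * 3)
        lda.fit(X, labels)
        ours = []
        from trussmorph.discrimination import _check_groups, _classify, _scatter_matrices, _solve_pooled

        W, _, _, means = _scatter_matrices(X, labels, ["a", "b", "c"])
        Sinv = _solve_pooled(W, 45, 3, None)
        ours = _classify(X, means, Sinv, ["a", "b", "c"])
        assert list(lda.predict(X)) == ours
        # confusion matrices agree
        np.testing.assert_array_equal(
            res.classification_original.counts.values,
            pd.crosstab(pd.Series(labels), pd.Series(lda.predict(X))).values,
        )

    def test_singular_covariance_raises(self, rng):
        X = rng.normal(size=(8, 10))  # more variables than specimens
        table = make_corrected(X, ["a"] * 4 + ["b"] * 4)
        with pytest.raises(SingularityError):
            dfa_fit(table)
        # ridge flag makes it solvable
        res = dfa_fit(table, ridge=1e-8)
        assert res.classification_original.overall_pct == 100.0


class TestLOOCV:
    def test_separated_clusters_100pct(self, rng):
        table = _clusters(rng, [(0, 0, 0), (15, 0, 0)], 10)
        assert dfa_loocv(table).overall_pct == 100.0

    def test_duplicate_shield_equals_resubstitution(self, rng):
        """With every specimen duplicated, leaving one out leaves its twin in
        training, so LOOCV reproduces the resubstitution classification."""
        table = _clusters(rng, [(0, 0), (2.5, 1)], 8)
        dup_vals = np.repeat(table.values.values, 2, axis=0)
        dup_species = np.repeat(table.species.values, 2)
        dup = make_corrected(dup_vals, dup_species)
        resub = dfa_fit(dup).classification_original
        loo = dfa_loocv(dup)
        pd.testing.assert_frame_equal(resub.counts, loo.counts)

    def test_single_specimen_group_errors(self, rng):
        X = rng.normal(size=(5, 2))
        table = make_corrected(X, ["a", "a", "a", "a", "lonely"])
        with pytest.raises(ValidationError, match="lonely"):
            dfa_loocv(table)


# ---------------------------------------------------------------------------
# Mahalanobis centroid distances
# ---------------------------------------------------------------------------


class TestMahalanobis:
    def test_identical_centroids(self, rng):
        base = rng.normal(size=(10, 3))
        X = np.vstack([base, base])
        table = make_corrected(X, ["a"] * 10 + ["b"] * 10)
        res = mahalanobis_centroids(table)
        assert res.d2.loc["a", "b"] == pytest.approx(0, abs=1e-20)
        assert res.p.loc["a", "b"] == 1.0

    def test_one_variable_closed_form(self):
        # per-group SS = 2, so pooled variance = (2 + 2)/(6 − 2) = 1
        a = np.array([-1.0, 0.0, 1.0])
        b = a + 1.0
        table = make_corrected(np.concatenate([a, b])[:, None], ["a"] * 3 + ["b"] * 3)
        res = mahalanobis_centroids(table)
        assert res.d2.loc["a", "b"] == pytest.approx(1.0, rel=1e-12)

    def test_affine_invariance(self, rng):
        X = np.vstack([rng.normal(c, 1, (12, 4)) for c in [(0,) * 4, (1, 2, 0, 0)]])
        labels = ["a"] * 12 + ["b"] * 12
        t1 = make_corrected(X, labels)
        A = rng.normal(size=(4, 4)) + 2 * np.eye(4)
        t2 = make_corrected(X @ A + rng.normal(size=4), labels)
        d1 = mahalanobis_centroids(t1).d2
        d2 = mahalanobis_centroids(t2).d2
        np.testing.assert_allclose(d1.values, d2.values, rtol=1e-8)

    def test_symmetry_and_zero_diagonal(self, rng):
        X = np.vstack([rng.normal(i, 1, (8, 3)) for i in range(3)])
        table = make_corrected(X, sum([[g] * 8 for g in "abc"], []))
        res = mahalanobis_centroids(table)
        np.testing.assert_allclose(res.d2.values, res.d2.values.T)
        np.testing.assert_allclose(np.diag(res.d2.values), 0)
        assert (res.d2.values >= 0).all()


# ---------------------------------------------------------------------------
# UPGMA
# ---------------------------------------------------------------------------


def brute_force_upgma(d: pd.DataFrame):
    """Independent agglomeration oracle: cluster distances recomputed each step
    as the mean over all cross-pairs of the ORIGINAL matrix (the defining
    property of unweighted average linkage)."""
    labels = list(d.index)
    clusters = [frozenset([l]) for l in labels]
    heights = {}
    merges = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                dist = np.mean(
                    [d.loc[a, b] for a in clusters[i] for b in clusters[j]]
                )
                key = tuple(sorted(clusters[i] | clusters[j]))
                cand = (dist, key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        dist, _, i, j = best
        merged = clusters[i] | clusters[j]
        merges.append((clusters[i], clusters[j], dist / 2))
        clusters = [c for k, c in enumerate(clusters) if k not in (i, j)] + [merged]
    coph = pd.DataFrame(0.0, index=labels, columns=labels)
    for a_set, b_set, h in merges:
        for a in a_set:
            for b in b_set:
                coph.loc[a, b] = coph.loc[b, a] = 2 * h
    return coph


class TestUPGMA:
    def test_hand_agglomeration(self):
        d = pd.DataFrame(
            [[0, 2, 8], [2, 0, 8], [8, 8, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        tree = upgma(d)
        assert tree.height == pytest.approx(4.0)
        inner = [c for c in tree.children if not c.is_leaf][0]
        assert sorted(inner.leaves()) == ["A", "B"]
        assert inner.height == pytest.approx(1.0)

    def test_two_taxa(self):
        d = pd.DataFrame([[0, 6], [6, 0]], index=["x", "y"], columns=["x", "y"], dtype=float)
        tree = upgma(d)
        assert tree.height == pytest.approx(3.0)
        assert sorted(tree.leaves()) == ["x", "y"]

    def test_ultrametric_input_reproduced_exactly(self):
        # cophenetic matrix of ((A,B),(C,D)) with heights 1 and 3
        d = pd.DataFrame(
            [[0, 2, 6, 6], [2, 0, 6, 6], [6, 6, 0, 2], [6, 6, 2, 0]],
            index=list("ABCD"), columns=list("ABCD"), dtype=float,
        )
        tree = upgma(d)
        pd.testing.assert_frame_equal(tree.cophenetic(), d, check_names=False)

    def test_matches_brute_force_oracle_on_random_matrices(self, rng):
        for _ in range(100):
            n = int(rng.integers(2, 6))
            labels = [f"t{i}" for i in range(n)]
            m = rng.uniform(1, 10, size=(n, n))
            m = (m + m.T) / 2
            np.fill_diagonal(m, 0)
            d = pd.DataFrame(m, index=labels, columns=labels)
            tree = upgma(d)
            pd.testing.assert_frame_equal(
                tree.cophenetic(), brute_force_upgma(d), check_names=False, atol=1e-10
            )

    def test_matches_scipy_average_linkage(self, rng):
        from scipy.cluster.hierarchy import cophenet, linkage
        from scipy.spatial.distance import squareform

        n = 7
        m = rng.uniform(1, 10, size=(n, n))
        m = (m + m.T) / 2
        np.fill_diagonal(m, 0)
        labels = [f"t{i}" for i in range(n)]
        d = pd.DataFrame(m, index=labels, columns=labels)
        tree = upgma(d)
        Z = linkage(squareform(m), method="average")
        coph = pd.DataFrame(squareform(cophenet(Z)), index=labels, columns=labels)
        pd.testing.assert_frame_equal(tree.cophenetic(), coph, check_names=False, atol=1e-10)

    def test_newick_roundtrip_with_dendropy(self):
        import dendropy

        d = pd.DataFrame(
            [[0, 2, 8], [2, 0, 8], [8, 8, 0]], index=list("ABC"), columns=list("ABC"), dtype=float
        )
        nwk = upgma(d).to_newick()
        tree = dendropy.Tree.get(data=nwk, schema="newick")
        assert sorted(t.taxon.label for t in tree.leaf_node_iter()) == ["A", "B", "C"]
        # ultrametric: root-to-leaf path lengths all equal the root height
        depths = [leaf.distance_from_root() for leaf in tree.leaf_node_iter()]
        np.testing.assert_allclose(depths, 4.0, atol=1e-9)

    def test_nan_rejected(self):
        d = pd.DataFrame(
            [[0, np.nan], [np.nan, 0]], index=["a", "b"], columns=["a", "b"]
        )
        with pytest.raises(ValidationError):
            upgma(d)
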