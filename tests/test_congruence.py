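"""Mantel tests, PCA of binary tip data, and Blomberg's K."""

import numpy as np
import pytest

from traitphylo.congruence import (
    blomberg_k,
    first_principal_component,
    k_over_posterior,
    mantel_test,
    mantel_test_exact,
    posterior_mean_distances,
)
from traitphylo.errors import DegenerateInputError, ValidationError
from traitphylo.traits import TraitMatrix
from traitphylo.trees import parse_tree, patristic_matrix

from conftest import random_time_tree


def _random_distance_matrix(rng, n):
    pts = rng.normal(size=(n, 3))
    D = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
    return D


def simulate_brownian(tree, taxa, rng, sigma=1.0):
    """Brownian motion tip values via the path-length covariance, built from
    patristic distances (independent of the package's covariance code):
    cov(i,j) = (depth_i + depth_j - d_ij) / 2."""
    D = patristic_matrix(tree, taxa)
    depth = {lab: tree.root.age - tree.find_tip(lab).age for lab in taxa}
    d = np.array([depth[lab] for lab in taxa])
    V = (d[:, None] + d[None, :] - D) / 2.0
    L = np.linalg.cholesky(V + 1e-12 * np.eye(len(taxa)))
    return dict(zip(taxa, sigma * (L @ rng.normal(size=len(taxa)))))


class TestMantel:
    def test_self_congruence(self):
        rng = np.random.default_rng(0)
        D = _random_distance_matrix(rng, 8)
        res = mantel_test(D, D.copy(), permutations=999, seed=1)
        assert res.r == pytest.approx(1.0)
        assert res.p == pytest.approx(1 / 1000)

    def test_exact_enumeration_agreement(self):
        """Seeded permutation p converges to the exhaustive-null p on 5
        taxa (all 120 relabelings)."""
        rng = np.random.default_rng(3)
        D1 = _random_distance_matrix(rng, 5)
        D2 = D1 + 0.3 * _random_distance_matrix(rng, 5)
        z, p_exact = mantel_test_exact(D1, D2)
        res = mantel_test(D1, D2, permutations=9999, seed=5)
        assert res.z == pytest.approx(z)
        assert res.p == pytest.approx(p_exact, abs=0.02)

    def test_matches_skbio_r(self):
        """Independent route: scikit-bio's Mantel r on the same matrices."""
        from skbio import DistanceMatrix
        from skbio.stats.distance import mantel as skbio_mantel

        rng = np.random.default_rng(7)
        D1 = _random_distance_matrix(rng, 10)
        D2 = _random_distance_matrix(rng, 10) + 0.5 * D1
        res = mantel_test(D1, D2, permutations=999, seed=0)
        r_sk, p_sk, _ = skbio_mantel(
            DistanceMatrix(D1), DistanceMatrix(D2), method="pearson",
            permutations=999, alternative="greater",
        )
        assert res.r == pytest.approx(float(r_sk), abs=1e-12)
        assert res.p == pytest.approx(float(p_sk), abs=0.03)

    def test_constant_matrix_z_still_reported(self):
        D1 = np.ones((5, 5)) - np.eye(5)
        rng = np.random.default_rng(1)
        D2 = _random_distance_matrix(rng, 5)
        res = mantel_test(D2, D1, permutations=99, seed=0)
        assert res.r is None
        assert res.z > 0

    def test_dimension_mismatch(self):
        with pytest.raises(ValidationError):
            mantel_test(np.zeros((4, 4)), np.zeros((5, 5)))

    def test_type_one_error_calibrated(self):
        """Independent random matrices reject at ~alpha under the null."""
        rng = np.random.default_rng(11)
        rejections = 0
        n_pairs = 400
        for k in range(n_pairs):
            D1 = _random_distance_matrix(rng, 8)
            D2 = _random_distance_matrix(rng, 8)
            res = mantel_test(D1, D2, permutations=199, seed=k)
            rejections += res.p <= 0.05
        assert 0.02 <= rejections / n_pairs <= 0.08


class TestPosteriorMeanDistances:
    def test_identical_trees_equal_single_tree(self, six_tip_tree):
        order = sorted(six_tip_tree.tip_labels)
        avg = posterior_mean_distances(
            [six_tip_tree.copy() for _ in range(5)], order, normalise=False
        )
        assert np.allclose(avg, patristic_matrix(six_tip_tree, order))

    def test_normalisation_collapses_scale(self, six_tip_tree):
        order = sorted(six_tip_tree.tip_labels)
        scaled = six_tip_tree.copy()
        for node in scaled.preorder():
            node.age *= 7.0
        avg = posterior_mean_distances([six_tip_tree, scaled], order, normalise=True)
        single = posterior_mean_distances([six_tip_tree], order, normalise=True)
        assert np.allclose(avg, single, atol=1e-10)

    def test_hand_mean_of_three_trees(self):
        t1 = parse_tree("((A:1,B:1):1,(C:1,D:1):1);")
        t2 = parse_tree("((A:2,B:2):1,(C:2,D:2):1);")
        t3 = parse_tree("((A:1,C:1):2,(B:1,D:1):2);")
        order = ["A", "B", "C", "D"]
        avg = posterior_mean_distances([t1, t2, t3], order, normalise=False)
        expected = (
            patristic_matrix(t1, order)
            + patristic_matrix(t2, order)
            + patristic_matrix(t3, order)
        ) / 3.0
        assert np.allclose(avg, expected, atol=1e-12)


class TestPCA:
    def test_two_blocks_two_scores(self):
        states = np.array([[1, 1, 0, 0]] * 3 + [[0, 0, 1, 1]] * 3, dtype=np.int8)
        m = TraitMatrix(
            taxa=[f"t{i}" for i in range(6)], states=states,
            char_ids=[f"c{j}" for j in range(4)],
        )
        scores = first_principal_component(m)
        assert len(np.unique(np.round(scores, 9))) == 2
        assert scores[0] != scores[3]

    def test_character_permutation_invariance(self):
        rng = np.random.default_rng(2)
        states = rng.choice([0, 1], size=(6, 8)).astype(np.int8)
        m1 = TraitMatrix(taxa=[f"t{i}" for i in range(6)], states=states,
                         char_ids=[f"c{j}" for j in range(8)])
        perm = rng.permutation(8)
        m2 = TraitMatrix(taxa=m1.taxa, states=states[:, perm],
                         char_ids=[f"c{j}" for j in perm])
        assert np.allclose(
            first_principal_component(m1), first_principal_component(m2), atol=1e-9
        )

    def test_eigendecomposition_oracle(self):
        states = np.array([[1, 1, 1], [0, 1, 1], [0, 1, 0], [1, 0, 0]], dtype=np.int8)
        m = TraitMatrix(taxa=["a", "b", "c", "d"], states=states,
                        char_ids=["c1", "c2", "c3"])
        scores = first_principal_component(m)
        X = states.astype(float) - states.mean(axis=0)
        evals, evecs = np.linalg.eigh(X.T @ X)
        v = evecs[:, -1]
        if v[np.argmax(np.abs(v))] < 0:
            v = -v
        expected = X @ v
        assert np.allclose(scores, expected, atol=1e-10)

    def test_zero_variance_rejected(self):
        m = TraitMatrix(taxa=["a", "b"], states=np.ones((2, 3), dtype=np.int8),
                        char_ids=["c1", "c2", "c3"])
        with pytest.raises(DegenerateInputError):
            first_principal_component(m)

    def test_missing_entries_imputed(self):
        states = np.array([[1, -1], [0, 1], [1, 0], [0, -1]], dtype=np.int8)
        m = TraitMatrix(taxa=list("abcd"), states=states, char_ids=["c1", "c2"])
        scores = first_principal_component(m)
        assert np.all(np.isfinite(scores))


class TestBlombergK:
    def test_frozen_phylosig_oracle(self, six_tip_tree):
        """Value computed once with an independent R implementation
        (phytools::phylosig) on this exact tree and trait vector."""
        x = {"A": 0.31, "B": -1.2, "C": -0.95, "D": -1.05, "E": 2.1, "F": 1.8}
        assert blomberg_k(six_tip_tree, x) == pytest.approx(2.27898211022, abs=1e-9)

    def test_affine_invariance(self, six_tip_tree):
        x = {"A": 0.31, "B": -1.2, "C": -0.95, "D": -1.05, "E": 2.1, "F": 1.8}
        y = {k: 3.7 * v - 11.0 for k, v in x.items()}
        assert blomberg_k(six_tip_tree, y) == pytest.approx(
            blomberg_k(six_tip_tree, x), abs=1e-10
        )

    def test_star_tree_k_is_exactly_one(self):
        """On a star tree the Brownian expectation collapses and K = 1 for
        any trait vector (the analytic degenerate case)."""
        from traitphylo.trees import Node, TimeTree

        root = Node(age=1.0)
        for i in range(6):
            root.add_child(Node(age=0.0, label=f"t{i}"))
        star = TimeTree(root)
        rng = np.random.default_rng(0)
        for _ in range(5):
            x = dict(zip([f"t{i}" for i in range(6)], rng.normal(size=6)))
            assert blomberg_k(star, x) == pytest.approx(1.0, abs=1e-10)

    def test_constant_trait_rejected(self, six_tip_tree):
        with pytest.raises(DegenerateInputError):
            blomberg_k(six_tip_tree, {lab: 1.0 for lab in six_tip_tree.tip_labels})

    def test_permutation_destroys_bm_signal(self):
        """Shuffling BM-generated values across tips lowers K nearly always."""
        rng = np.random.default_rng(5)
        wins = 0
        trials = 60
        for k in range(trials):
            tree = random_time_tree(k + 1, n_tips=10)
            taxa = tree.tip_labels
            x = simulate_brownian(tree, taxa, rng)
            k_true = blomberg_k(tree, x)
            vals = np.array([x[t] for t in taxa])
            perm = rng.permutation(len(taxa))
            k_perm = blomberg_k(tree, dict(zip(taxa, vals[perm])))
            wins += k_perm < k_true
        assert wins / trials >= 0.9

    def test_bm_calibration_mean_near_one(self):
        """Mean K over BM replicates on one tree sits near 1."""
        tree = random_time_tree(3, n_tips=16)
        rng = np.random.default_rng(8)
        ks = [
            blomberg_k(tree, simulate_brownian(tree, tree.tip_labels, rng))
            for _ in range(150)
        ]
        assert 0.8 <= np.mean(ks) <= 1.2


class TestKOverPosterior:
    def test_singleton_equals_single_tree(self, six_tip_tree):
        x = {"A": 0.31, "B": -1.2, "C": -0.95, "D": -1.05, "E": 2.1, "F": 1.8}
        res = k_over_posterior([six_tip_tree], x, permutations=99, seed=0)
        assert res.k_mean == pytest.approx(blomberg_k(six_tip_tree, x), abs=1e-10)

    def test_p_floor_with_999_permutations(self):
        """Strong BM signal on many trees bottoms out at p = 0.001."""
        tree = random_time_tree(2, n_tips=12)
        rng = np.random.default_rng(1)
        x = simulate_brownian(tree, tree.tip_labels, rng, sigma=3.0)
        res = k_over_posterior([tree, tree.copy()], x, permutations=999, seed=0)
        assert res.p >= 0.001
        if res.p == pytest.approx(0.001):
            assert res.p == pytest.approx(1 / (1 + 999))

    def test_bm_signal_detected(self):
        """BM-simulated traits on the generating topology give small p."""
        rng = np.random.default_rng(9)
        detected = 0
        trials = 20
        for k in range(trials):
            tree = random_time_tree(100 + k, n_tips=12)
            x = simulate_brownian(tree, tree.tip_labels, rng)
            res = k_over_posterior([tree], x, permutations=199, seed=k)
            detected += res.p <= 0.05
        assert detected / trials >= 0.7
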