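import numpy as np
import pytest

from sbipred.corpus import EdgeList
from sbipred.topology_features import (
    OneHotProfile,
    PCATransform,
    jaccard,
    onehot_profile,
    partner_universe,
    reduce_pca,
    similarity_matrix,
)


def _profile(bits, drug="d", network="SSI"):
    return OneHotProfile(drug_id=drug, network=network, bits=np.asarray(bits, float))


class TestOneHot:
    def test_direct_encoding(self):
        el = EdgeList("SPI", frozenset({("d", "p2"), ("d", "p5"), ("x", "p1")}))
        partners = ["p1", "p2", "p3", "p4", "p5", "p6"]
        prof = onehot_profile("d", el, partners)
        np.testing.assert_array_equal(prof.bits, [0, 1, 0, 0, 1, 0])
        assert prof.degree == 2

    def test_isolated_drug_zero_vector(self):
        el = EdgeList("SPI", frozenset({("x", "p1")}))
        prof = onehot_profile("lonely", el, ["p1", "p2"])
        assert prof.degree == 0

    def test_intra_network_sees_both_endpoints(self):
        el = EdgeList("SSI", frozenset({("a", "b")}))
        partners = partner_universe(el)
        assert partners == ("a", "b")
        assert onehot_profile("b", el, partners).degree == 1

    def test_handshake_lemma_on_fixture_graph(self, tiny_universe):
        el = tiny_universe.edge_lists["SSI"]
        partners = partner_universe(el)
        total = sum(
            onehot_profile(d, el, partners).degree for d in tiny_universe.smd_ids
        )
        assert total == 2 * len(el.edges)


class TestJaccard:
    def test_hand_example(self):
        a = np.zeros(6); a[[1, 2, 3]] = 1
        b = np.zeros(6); b[[2, 3, 4]] = 1
        assert jaccard(a, b) == pytest.approx(0.5)

    def test_bounds(self):
        a = np.array([1.0, 1, 0, 0])
        assert jaccard(a, a) == 1.0
        assert jaccard(a, np.array([0.0, 0, 1, 1])) == 0.0

    def test_empty_supports_convention(self):
        z = np.zeros(5)
        assert jaccard(z, z) == 0.0

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="dimensions"):
            jaccard(np.zeros(3), np.zeros(4))

    def test_matches_set_arithmetic_oracle(self):
        rng = np.random.default_rng(42)
        for _ in range(200):
            a = (rng.random(30) < 0.3).astype(float)
            b = (rng.random(30) < 0.3).astype(float)
            sa, sb = set(np.flatnonzero(a)), set(np.flatnonzero(b))
            union = len(sa | sb)
            expected = len(sa & sb) / union if union else 0.0
            assert abs(jaccard(a, b) - expected) < 1e-12
            assert jaccard(a, b) == jaccard(b, a)


class TestSimilarityMatrix:
    def test_symmetry_and_diagonal(self, tiny_universe):
        el = tiny_universe.edge_lists["BPI"]
        partners = partner_universe(el)
        profiles = [
            onehot_profile(d, el, partners) for d in tiny_universe.biod_ids
        ]
        sim = similarity_matrix(profiles)
        n = len(tiny_universe.biod_ids)
        assert sim.matrix.shape == (n, n)
        np.testing.assert_allclose(sim.matrix, sim.matrix.T)
        for i, p in enumerate(profiles):
            assert sim.matrix[i, i] == (1.0 if p.degree else 0.0)
        assert ((sim.matrix >= 0) & (sim.matrix <= 1)).all()

    def test_single_profile(self):
        sim = similarity_matrix([_profile([1, 0, 1])])
        np.testing.assert_array_equal(sim.matrix, [[1.0]])

    def test_pairwise_entries_match_scalar_jaccard(self):
        rng = np.random.default_rng(0)
        profiles = [
            _profile((rng.random(12) < 0.4).astype(float), drug=f"d{i}")
            for i in range(6)
        ]
        sim = similarity_matrix(profiles)
        for i in range(6):
            for j in range(6):
                assert sim.matrix[i, j] == pytest.approx(
                    jaccard(profiles[i], profiles[j]), abs=1e-12
                )

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(1)
        profiles = [
            _profile((rng.random(10) < 0.5).astype(float), drug=f"d{i}")
            for i in range(5)
        ]
        sim = similarity_matrix(profiles)
        perm = [3, 1, 4, 0, 2]
        sim_p = similarity_matrix([profiles[i] for i in perm])
        np.testing.assert_allclose(
            sim_p.matrix, sim.matrix[np.ix_(perm, perm)]
        )

    def test_mixed_networks_rejected(self):
        with pytest.raises(ValueError, match="mixed"):
            similarity_matrix([_profile([1]), _profile([1], network="BBI")])


class TestPCA:
    def _rows(self, n=20, d=12, seed=7):
        rng = np.random.default_rng(seed)
        return rng.random((n, d))

    def test_orthonormal_components(self):
        scores, t = reduce_pca(self._rows(), k=5)
        np.testing.assert_allclose(
            t.components @ t.components.T, np.eye(5), atol=1e-8
        )

    def test_explained_variance_non_increasing(self):
        _, t = reduce_pca(self._rows(), k=8)
        assert (np.diff(t.explained_variance) <= 1e-12).all()

    def test_full_basis_reconstruction(self):
        rows = self._rows(n=10, d=10)
        scores, t = reduce_pca(rows, k=10)
        recon = scores @ t.components + t.mean
        np.testing.assert_allclose(recon, rows, atol=1e-8)

    def test_k_above_rank_kept_at_rank(self, caplog):
        rows = self._rows(n=5, d=10)
        with caplog.at_level("WARNING"):
            scores, t = reduce_pca(rows, k=8)
        assert t.components.shape[0] == 5
        assert "exceeds" in caplog.text

    def test_heldout_projection_matches_eigen_oracle(self):
        rows = self._rows(n=20, d=12, seed=3)
        held = np.random.default_rng(4).random(12)
        scores, t = reduce_pca(rows, k=5)
        # independent oracle: eigen-decomposition of the training covariance
        mean = rows.mean(axis=0)
        C = np.cov((rows - mean).T, ddof=1)
        evals, evecs = np.linalg.eigh(C)
        order = np.argsort(evals)[::-1][:5]
        V = evecs[:, order].T
        for i in range(5):  # apply the same sign convention
            j = int(np.argmax(np.abs(V[i])))
            if V[i, j] < 0:
                V[i] = -V[i]
        np.testing.assert_allclose(t.components, V, atol=1e-8)
        np.testing.assert_allclose(t.project(held)[0], (held - mean) @ V.T, atol=1e-8)

    def test_transform_round_trips_through_disk(self, tmp_path):
        _, t = reduce_pca(self._rows(), k=4)
        t.save(tmp_path / "pca.npz")
        t2 = PCATransform.load(tmp_path / "pca.npz")
        np.testing.assert_array_equal(t.components, t2.components)

    def test_deterministic(self):
        rows = self._rows()
        s1, t1 = reduce_pca(rows, k=6)
        s2, t2 = reduce_pca(rows, k=6)
        np.testing.assert_array_equal(s1, s2)
        np.testing.assert_array_equal(t1.components, t2.components)
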