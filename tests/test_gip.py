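"""WNN-GIP predictor: GIP kernels, WNN imputation, Kronecker RLS."""

import numpy as np
import pytest

import smilesim as sm


def kron_rls_bruteforce(Kd, Kt, Y, sigma):
    """Materialize the Kronecker system and solve it directly."""
    K = np.kron(Kt, Kd)  # vec is column-major stacking of drug-columns
    y = Y.reshape(-1, order="F")
    scores = K @ np.linalg.solve(K + sigma * np.eye(K.shape[0]), y)
    return scores.reshape(Y.shape, order="F")


class TestGipKernel:
    def test_identical_profiles_give_one(self):
        K = sm.gip_kernel(np.array([[1.0, 0.0], [1.0, 0.0]]))
        assert np.allclose(K.values, 1.0)

    def test_orthogonal_profiles(self):
        K = sm.gip_kernel(np.array([[1.0, 0.0], [0.0, 1.0]]))
        # mean squared norm = 1 so gamma = 1; distance^2 = 2
        assert K.values[0, 1] == pytest.approx(np.exp(-2))

    def test_symmetric_unit_diagonal(self):
        rng = np.random.default_rng(0)
        K = sm.gip_kernel(rng.integers(0, 2, size=(6, 4)).astype(float))
        assert np.allclose(K.values, K.values.T)
        assert np.allclose(np.diag(K.values), 1.0)

    def test_zero_rows_excluded_from_bandwidth(self):
        profiles = np.array([[1.0, 1.0], [0.0, 0.0]])
        K = sm.gip_kernel(profiles)
        assert K.meta["gamma"] == pytest.approx(1 / 2)  # mean over nonzero rows only

    def test_all_zero_profiles_rejected(self):
        with pytest.raises(ValueError, match="all-zero"):
            sm.gip_kernel(np.zeros((3, 4)))


class TestWnnImpute:
    def test_single_training_drug_copied(self):
        out = sm.wnn_impute(np.array([0.2]), np.array([[1.0, 0.0, 1.0]]), decay=0.3)
        assert out.tolist() == [1.0, 0.0, 1.0]

    def test_weighted_sum_example(self):
        out = sm.wnn_impute(
            np.array([0.9, 0.1]), np.array([[1.0, 0.0], [0.0, 1.0]]), decay=0.5
        )
        assert out.tolist() == [1.0, 0.5]

    def test_clipping_at_one(self):
        out = sm.wnn_impute(
            np.array([0.5, 0.5]), np.array([[1.0, 1.0], [1.0, 1.0]]), decay=1.0
        )
        assert out.tolist() == [1.0, 1.0]

    def test_ties_broken_by_training_order(self):
        sims = np.array([0.5, 0.5])
        train = np.array([[1.0, 0.0], [0.0, 1.0]])
        out = sm.wnn_impute(sims, train, decay=0.5)
        assert out.tolist() == [1.0, 0.5]  # first training drug ranks first

    def test_empty_training_set(self):
        with pytest.raises(ValueError, match="at least one"):
            sm.wnn_impute(np.array([]), np.zeros((0, 3)), decay=0.5)


class TestCombine:
    def test_degenerate_alphas(self):
        a = sm.SimilarityMatrix(["x", "y"], np.array([[1.0, 0.3], [0.3, 1.0]]))
        b = sm.SimilarityMatrix(["x", "y"], np.array([[1.0, 0.9], [0.9, 1.0]]))
        assert np.allclose(sm.combine_kernels(a, b, 1.0).values, a.values)
        assert np.allclose(sm.combine_kernels(a, b, 0.0).values, b.values)
        assert np.allclose(np.diag(sm.combine_kernels(a, b, 0.5).values), 1.0)

    def test_label_mismatch(self):
        a = sm.SimilarityMatrix(["x"], np.eye(1))
        b = sm.SimilarityMatrix(["z"], np.eye(1))
        with pytest.raises(ValueError, match="mismatch"):
            sm.combine_kernels(a, b, 0.5)


class TestKronRls:
    @pytest.mark.parametrize("shape", [(3, 2), (5, 4), (4, 3)])
    @pytest.mark.parametrize("sigma", [0.1, 1.0])
    def test_matches_explicit_kronecker_solve(self, shape, sigma):
        rng = np.random.default_rng(shape[0] * 10 + shape[1])
        n, m = shape
        A = rng.normal(size=(n, n))
        B = rng.normal(size=(m, m))
        Kd, Kt = A @ A.T, B @ B.T  # PSD by construction
        Y = rng.integers(0, 2, size=(n, m)).astype(float)
        fast = sm.kron_rls(Kd, Kt, Y, sigma)
        slow = kron_rls_bruteforce(Kd, Kt, Y, sigma)
        assert np.abs(fast - slow).max() <= 1e-8

    def test_identity_kernels_halve_labels(self):
        Y = np.array([[1.0, 0.0], [0.0, 1.0], [1.0, 1.0]])
        assert np.allclose(sm.kron_rls(np.eye(3), np.eye(2), Y, 1.0), Y / 2)

    def test_small_sigma_reproduces_labels(self):
        rng = np.random.default_rng(5)
        A = rng.normal(size=(4, 4))
        Kd = A @ A.T + np.eye(4)
        Y = rng.integers(0, 2, size=(4, 3)).astype(float)
        out = sm.kron_rls(Kd, np.eye(3), Y, sigma=1e-10)
        assert np.allclose(out, Y, atol=1e-5)

    def test_asymmetric_kernel_rejected(self):
        bad = np.array([[1.0, 0.5], [0.2, 1.0]])
        with pytest.raises(ValueError, match="make_kernel"):
            sm.kron_rls(bad, np.eye(2), np.zeros((2, 2)), 1.0)

    def test_indefinite_kernel_rejected(self):
        bad = np.array([[0.0, 1.0], [1.0, 0.0]])  # eigenvalues +-1
        with pytest.raises(ValueError, match="negative eigen"):
            sm.kron_rls(bad, np.eye(2), np.zeros((2, 2)), 1.0)


class TestPredict:
    @pytest.fixture
    def setup(self, synth_bundle):
        spec, records, clusters, network, tsim = synth_bundle
        K = sm.pairwise_matrix(records, sm.get_kernel("lingosim"))
        return records, network, K, tsim

    def test_empty_test_set(self, setup):
        _, network, K, tsim = setup
        out = sm.predict(network, K, tsim, test_drugs=[])
        assert out.empty

    def test_unknown_test_drug(self, setup):
        _, network, K, tsim = setup
        with pytest.raises(KeyError, match="nope"):
            sm.predict(network, K, tsim, test_drugs=["nope"])

    def test_duplicate_smiles_drug_recovers_twin_targets(self, synth_bundle):
        """A held-out drug whose SMILES duplicates a training drug should
        rank its twin's known targets on top."""
        spec, records, clusters, network, tsim = synth_bundle
        twin = sm.CompoundRecord("dup", records[0].raw_smiles, records[0].norm_smiles)
        corpus = records + [twin]
        adjacency = np.vstack([network.adjacency, np.zeros(len(network.target_ids))])
        net2 = sm.InteractionNetwork(
            network.drug_ids + ["dup"], network.target_ids, adjacency.astype(int)
        )
        K = sm.pairwise_matrix(corpus, sm.get_kernel("lingosim"))
        scores = sm.predict(net2, K, tsim, test_drugs=["dup"])
        truth = network.adjacency[0]
        n_pos = int(truth.sum())
        top = np.argsort(-scores.to_numpy()[0])[:n_pos]
        assert truth[top].mean() >= 0.8  # twin's targets dominate the top ranks

    def test_permutation_invariance(self, setup):
        """Scores do not depend on drug order when similarities are
        tie-free (with ties, WNN ranking follows training order)."""
        records, network, K, tsim = setup
        rng = np.random.default_rng(3)
        n = len(network.drug_ids)
        # distinct off-diagonal similarities so WNN ranking has no ties
        vals = (rng.permutation(n * (n - 1) // 2) + 1) / (n * n)
        M = np.eye(n)
        M[np.triu_indices(n, k=1)] = vals
        M = np.maximum(M, M.T)
        K_distinct = sm.SimilarityMatrix(network.drug_ids, M)
        perm = rng.permutation(n)
        ids = [network.drug_ids[i] for i in perm]
        net2 = sm.InteractionNetwork(
            ids, network.target_ids, network.adjacency[perm].astype(int)
        )
        test = network.drug_ids[:4]
        a = sm.predict(network, K_distinct, tsim, test_drugs=test)
        b = sm.predict(net2, K_distinct.reorder(ids), tsim, test_drugs=test)
        assert np.allclose(a.to_numpy(), b.to_numpy(), atol=1e-8)

    def test_alpha_one_identity_kernels_depend_only_on_labels(self, setup):
        records, network, K, tsim = setup
        n, m = network.adjacency.shape
        I_d = sm.SimilarityMatrix(network.drug_ids, np.eye(n))
        I_t = sm.SimilarityMatrix(network.target_ids, np.eye(m))
        cfg = sm.GipConfig(alpha=1.0, wnn_enabled=False)
        test = network.drug_ids[:3]
        out = sm.predict(network, I_d, I_t, cfg, test_drugs=test)
        # with identity kernels and hidden rows zeroed, test scores are Y/ (1+sigma) rows = 0
        assert np.allclose(out.to_numpy(), 0.0, atol=1e-10)

    def test_planted_network_beats_chance(self, setup):
        records, network, K, tsim = setup
        test = network.drug_ids[:5]
        scores = sm.predict(network, K, tsim, test_drugs=test)
        y = network.adjacency[:5].ravel().astype(int)
        assert sm.auc_roc(scores.to_numpy().ravel(), y) > 0.5


class TestConfig:
    @pytest.mark.parametrize(
        "kwargs", [{"alpha": 1.5}, {"sigma": 0.0}, {"wnn_decay": 0.0}, {"gamma_scale": -1}]
    )
    def test_invalid_hyperparameters_rejected(self, kwargs):
        with pytest.raises(ValueError):
            sm.GipConfig(**kwargs)

    def test_adjacency_tsv_roundtrip(self, tmp_path, synth_bundle):
        _, _, _, network, _ = synth_bundle
        path = tmp_path / "adj.tsv"
        sm.write_adjacency_tsv(path, network)
        back = sm.read_adjacency_tsv(path)
        assert back.drug_ids == network.drug_ids
        assert np.array_equal(back.adjacency, network.adjacency)

    def test_nonbinary_adjacency_rejected(self):
        with pytest.raises(ValueError, match="0 or 1"):
            sm.InteractionNetwork(["d"], ["t"], np.array([[0.5]]))
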