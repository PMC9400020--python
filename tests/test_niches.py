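"""Pairwise MSN matrix construction, niche clustering, and dispersal
contrasts."""

import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from nichedrift import (
    MsnConfig,
    PairwiseMsnMatrix,
    SiteSampleBank,
    SyntheticConfig,
    cluster_sites,
    dispersal_contrast,
    pairwise_msn_matrix,
    simulate_bank,
)

TINY_CFG = MsnConfig(n_iterations=200, burn_in=100, thin=2)


@pytest.fixture(scope="module")
def tiny_bank():
    cfg = SyntheticConfig(regime="neutral", n_sites=4, n_individuals=3,
                          J_target=120, theta=10.0, m=0.1, seed=0)
    return simulate_bank(cfg)


def planted_matrix(blocks, high=30.0, low=5.0, diag=35.0):
    """Noise-free block M matrix from a site -> block assignment."""
    n = len(blocks)
    M = np.full((n, n), low)
    for i in range(n):
        for j in range(n):
            if blocks[i] == blocks[j]:
                M[i, j] = high
    np.fill_diagonal(M, diag)
    return M


class TestPairwiseMatrix:
    def test_pair_count_and_symmetry(self, tiny_bank):
        mat = pairwise_msn_matrix(tiny_bank, TINY_CFG, n_draws_per_pair=1, rng=1)
        assert mat.n_pairs == 6  # C(4, 2)
        np.testing.assert_array_equal(mat.M, mat.M.T)
        assert np.all(np.diag(mat.M) > 0)
        assert mat.theta.shape == (4,)

    def test_permutation_equivariance(self, tiny_bank):
        mat = pairwise_msn_matrix(tiny_bank, TINY_CFG, n_draws_per_pair=1, rng=1)
        perm = [2, 0, 3, 1]
        shuffled = SiteSampleBank(
            [tiny_bank.site_ids[i] for i in perm],
            [tiny_bank.samples[i] for i in perm],
        )
        mat_p = pairwise_msn_matrix(shuffled, TINY_CFG, n_draws_per_pair=1, rng=1)
        inv = np.argsort(perm)
        np.testing.assert_allclose(mat_p.M, mat.M[np.ix_(perm, perm)])
        np.testing.assert_allclose(mat_p.theta, mat.theta[perm])
        assert inv is not None

    def test_small_sites_excluded(self, tiny_bank):
        bank = SiteSampleBank(
            tiny_bank.site_ids,
            [s if i else s[:1] for i, s in enumerate(tiny_bank.samples)],
        )
        mat = pairwise_msn_matrix(bank, TINY_CFG, n_draws_per_pair=1, rng=1)
        assert len(mat.site_ids) == 3


class TestClustering:
    def test_constant_matrix_single_cluster(self):
        mat = PairwiseMsnMatrix(["a", "b", "c"], np.full((3, 3), 7.0),
                                np.ones(3), 3)
        cl = cluster_sites(mat)
        assert cl.K_selected == 1
        assert set(cl.labels.values()) == {0}

    def test_planted_blocks_recovered_exactly(self):
        blocks = [0, 0, 1, 1, 2, 2, 3, 3, 4, 4]
        ids = [f"s{i}" for i in range(10)]
        mat = PairwiseMsnMatrix(ids, planted_matrix(blocks), np.ones(10), 45)
        cl = cluster_sites(mat)
        labels = [cl.labels[s] for s in ids]
        assert adjusted_rand_score(blocks, labels) == 1.0
        assert cl.K_selected == 5

    def test_invariant_to_scalar_rescaling(self):
        blocks = [0, 0, 1, 1, 2]
        ids = list("abcde")
        M = planted_matrix(blocks)
        a = cluster_sites(PairwiseMsnMatrix(ids, M, np.ones(5), 10))
        b = cluster_sites(PairwiseMsnMatrix(ids, 3.7 * M, np.ones(5), 10))
        assert a.labels == b.labels and a.K_selected == b.K_selected

    def test_empty_K_range_rejected(self):
        mat = PairwiseMsnMatrix(list("abc"), planted_matrix([0, 0, 1]),
                                np.ones(3), 3)
        with pytest.raises(ValueError):
            cluster_sites(mat, K_range=[])


class TestDispersalContrast:
    def make_matrix(self, iso_factor=3.0, theta_factor=3.0):
        rng = np.random.default_rng(0)
        n = 6
        M = 30.0 + rng.normal(0, 1, (n, n))
        M = (M + M.T) / 2
        M[0, 1:] /= iso_factor
        M[1:, 0] /= iso_factor
        theta = np.full(n, 35.0)
        theta[0] *= theta_factor
        return PairwiseMsnMatrix([f"s{i}" for i in range(n)], M, theta, 15)

    def test_isolated_focal_detected(self):
        res = dispersal_contrast(self.make_matrix(), "s0")
        assert res["M_ratio"] <= 0.5
        assert res["theta_ratio"] >= 2.0
        assert res["ranksum_p"] < 0.05

    def test_exchangeable_sites_near_unity(self):
        ratios = []
        for seed in range(10):
            rng = np.random.default_rng(seed)
            M = 30.0 + rng.normal(0, 2, (6, 6))
            M = (M + M.T) / 2
            mat = PairwiseMsnMatrix([f"s{i}" for i in range(6)], M,
                                    np.full(6, 35.0), 15)
            ratios.append(dispersal_contrast(mat, "s0")["M_ratio"])
        assert 0.8 <= np.mean(ratios) <= 1.25

    def test_unknown_focal_rejected(self):
        with pytest.raises(ValueError):
            dispersal_contrast(self.make_matrix(), "nope")
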