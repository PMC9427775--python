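"""Spectral consensus clustering, stability metrics and model selection."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.linalg import eigh
from sklearn.metrics import adjusted_rand_score

from icfuse.config import ConsensusParams
from icfuse.consensus import (
    ConsensusResult,
    KResult,
    cophenetic_coefficient,
    pac,
    run_consensus,
    select_k,
    silhouette,
    spectral_cluster,
)
from icfuse.types import ValidationError
from oracles import (
    average_linkage_cophenetic_oracle,
    pearson_oracle,
    silhouette_oracle,
)


def _block_similarity(sizes, within=1.0, between=0.05, noise=0.0, rng=None):
    n = sum(sizes)
    groups = np.repeat(np.arange(len(sizes)), sizes)
    S = np.where(groups[:, None] == groups[None, :], within, between).astype(float)
    if noise and rng is not None:
        E = rng.uniform(0, noise, size=(n, n))
        S = S + (E + E.T) / 2
    np.fill_diagonal(S, 1.0)
    return S, groups


class TestSpectral:
    def test_disconnected_blocks_recovered_exactly(self):
        S, groups = _block_similarity([4, 5, 3], between=0.0)
        labels = spectral_cluster(S, 3, seed=0)
        assert adjusted_rand_score(groups, labels) == 1.0

    def test_degenerate_all_ones_deterministic(self):
        S = np.ones((6, 6))
        a = spectral_cluster(S, 2, seed=42)
        b = spectral_cluster(S, 2, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_matches_exhaustive_kmeans_oracle(self, rng):
        S, _ = _block_similarity([4, 4], between=0.3, noise=0.2, rng=rng)
        labels = spectral_cluster(S, 2, seed=1)
        # oracle: same embedding, exhaustive search over all 2-partitions
        deg = S.sum(axis=1)
        M = S / np.sqrt(np.outer(deg, deg))
        M = (M + M.T) / 2
        _, vecs = eigh(M, subset_by_index=(6, 7))
        U = vecs / np.linalg.norm(vecs, axis=1, keepdims=True)
        best, best_cost = None, np.inf
        for bits in itertools.product([0, 1], repeat=8):
            lab = np.array(bits)
            if len(set(bits)) < 2:
                continue
            cost = sum(
                ((U[lab == g] - U[lab == g].mean(axis=0)) ** 2).sum()
                for g in (0, 1)
            )
            if cost < best_cost - 1e-12:
                best, best_cost = lab, cost
        assert adjusted_rand_score(best, labels) == 1.0

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ValidationError):
            spectral_cluster(np.ones((3, 3)), 4)

    def test_canonical_first_occurrence_labels(self):
        S, _ = _block_similarity([3, 3], between=0.0)
        labels = spectral_cluster(S, 2, seed=0)
        assert labels[0] == 0  # first sample always opens cluster 0


class TestPAC:
    def test_binary_matrix_zero(self):
        M, _ = _block_similarity([3, 3], within=1.0, between=0.0)
        assert pac(M) == 0.0

    def test_all_ambiguous_one(self):
        M = np.full((4, 4), 0.5)
        np.fill_diagonal(M, 1.0)
        assert pac(M) == 1.0

    def test_direct_count(self):
        M = np.zeros((4, 4))
        np.fill_diagonal(M, 1.0)
        M[0, 1] = M[1, 0] = 0.5
        assert pac(M) == pytest.approx(2 / 12)

    def test_strict_bounds(self):
        M = np.full((3, 3), 0.9)  # exactly at the upper bound: not ambiguous
        np.fill_diagonal(M, 1.0)
        assert pac(M) == 0.0


class TestCophenetic:
    def test_two_block_consensus_is_one(self):
        M, _ = _block_similarity([4, 4], within=1.0, between=0.0)
        assert cophenetic_coefficient(M) == pytest.approx(1.0, abs=1e-10)

    def test_ultrametric_input_is_one(self):
        # three-level ultrametric distance -> tree-consistent
        D = np.array([
            [0.0, 1.0, 4.0, 4.0],
            [1.0, 0.0, 4.0, 4.0],
            [4.0, 4.0, 0.0, 2.0],
            [4.0, 4.0, 2.0, 0.0],
        ])
        M = 1 - D / D.max() * 0.9
        assert cophenetic_coefficient(M) == pytest.approx(1.0, abs=1e-10)

    def test_matches_independent_traversal_oracle(self, rng):
        M = rng.uniform(0, 1, size=(8, 8))
        M = (M + M.T) / 2
        np.fill_diagonal(M, 1.0)
        got = cophenetic_coefficient(M)
        D = 1 - M
        np.fill_diagonal(D, 0.0)
        coph = average_linkage_cophenetic_oracle(D)
        iu = np.triu_indices(8, 1)
        expected = pearson_oracle(D[iu], coph[iu])
        assert got == pytest.approx(expected, abs=1e-8)


class TestSilhouette:
    def test_separated_blocks_high(self):
        M, groups = _block_similarity([5, 5], between=0.0)
        assert silhouette(1 - M, groups) > 0.9

    def test_uniform_distances_zero(self):
        D = np.ones((6, 6)) - np.eye(6)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert silhouette(D, labels) == pytest.approx(0.0)

    def test_hand_instance(self, rng):
        D = rng.uniform(0.1, 1, size=(6, 6))
        D = (D + D.T) / 2
        np.fill_diagonal(D, 0.0)
        labels = np.array([0, 0, 1, 1, 2, 2])
        assert silhouette(D, labels) == pytest.approx(
            silhouette_oracle(D, labels), abs=1e-10
        )

    def test_single_cluster_rejected(self):
        with pytest.raises(ValidationError):
            silhouette(np.zeros((4, 4)), np.zeros(4, dtype=int))


def _params(**kw):
    defaults = dict(k_min=2, k_max=4, reps=50, p_item=0.8, seed=3)
    defaults.update(kw)
    return ConsensusParams(**defaults)


class TestRunConsensus:
    def test_perfect_two_blocks_unambiguous(self):
        S, _ = _block_similarity([6, 6], between=0.02)
        res = run_consensus(pd.DataFrame(S), _params(k_max=3, reps=50))
        M2 = res.per_k[2].consensus_matrix
        off = M2[~np.eye(12, dtype=bool)]
        assert np.all((off < 1e-12) | (off > 1 - 1e-12))
        assert res.per_k[2].pac == 0.0

    def test_single_rep_full_subsample_is_comembership(self):
        S, _ = _block_similarity([5, 4], between=0.05)
        res = run_consensus(pd.DataFrame(S), _params(reps=1, p_item=1.0,
                                                     k_max=2))
        M = res.per_k[2].consensus_matrix
        assert set(np.unique(M)) <= {0.0, 1.0}
        # equals the 0/1 co-membership matrix of one spectral run (the block
        # structure is unambiguous, so any k-means seed finds it)
        labels = spectral_cluster(S, 2, seed=0)
        np.testing.assert_array_equal(
            M, (labels[:, None] == labels[None, :]).astype(float)
        )

    def test_consensus_converges_to_block_indicator(self):
        S, groups = _block_similarity([5, 5], between=0.02)
        res = run_consensus(pd.DataFrame(S), _params(reps=200, k_max=2))
        M = res.per_k[2].consensus_matrix
        indicator = (groups[:, None] == groups[None, :]).astype(float)
        assert np.abs(M - indicator).max() <= 0.02

    def test_matrix_invariants(self, rng):
        S, _ = _block_similarity([4, 4, 4], between=0.1, noise=0.3, rng=rng)
        res = run_consensus(pd.DataFrame(S), _params(reps=30))
        for r in res.per_k.values():
            M = r.consensus_matrix
            assert M.min() >= 0 and M.max() <= 1
            np.testing.assert_allclose(np.diag(M), 1.0)
            np.testing.assert_allclose(M, M.T)

    def test_deterministic_under_seed(self):
        S, _ = _block_similarity([5, 5], between=0.3)
        a = run_consensus(pd.DataFrame(S), _params(seed=9))
        b = run_consensus(pd.DataFrame(S), _params(seed=9))
        assert a.chosen_k == b.chosen_k
        for k in a.per_k:
            np.testing.assert_array_equal(a.per_k[k].labels, b.per_k[k].labels)
            np.testing.assert_allclose(a.per_k[k].consensus_matrix,
                                       b.per_k[k].consensus_matrix)


def _mk_result(metrics: dict[int, tuple[float, float, float]]) -> ConsensusResult:
    per_k = {
        k: KResult(k=k, consensus_matrix=np.eye(2), labels=np.array([0, 1]),
                   cophenetic=c, pac=p, mean_silhouette=s)
        for k, (c, p, s) in metrics.items()
    }
    return ConsensusResult(per_k=per_k)


class TestSelectK:
    def test_dominating_k_chosen(self):
        res = _mk_result({2: (0.8, 0.5, 0.4), 3: (0.99, 0.01, 0.9),
                          4: (0.7, 0.6, 0.3)})
        assert select_k(res) == 3

    def test_full_tie_falls_back_to_smallest(self):
        res = _mk_result({k: (0.9, 0.1, 0.8) for k in (2, 3, 4, 5)})
        assert select_k(res) == 2

    def test_partial_tie_prefers_finest_stable_partition(self):
        # the coarse and the fine solution are both perfectly stable;
        # intermediate k is ambiguous -> the finer stable solution wins
        res = _mk_result({2: (1.0, 0.0, 1.0), 3: (0.95, 0.3, 0.8),
                          5: (1.0, 0.0, 1.0)})
        assert select_k(res) == 5

    def test_sub_resolution_differences_are_ties(self):
        # 0.999 vs 1.0 is below stability resolution -> tied with k=2; the
        # clearly worse k=3 keeps the tie from spanning the whole range
        res = _mk_result({2: (1.0, 0.0, 1.0), 3: (0.9, 0.4, 0.7),
                          5: (0.999, 0.001, 0.998)})
        assert select_k(res) == 5
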