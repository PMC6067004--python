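"""Seed rule, random walk with restart, and ranked network selection."""

import math

import networkx as nx
import numpy as np
import pytest

from mlpr.fingerprinting import FingerprintTable
from mlpr.pair_features import PAIR_COMPONENTS, PairVector
from mlpr.reconstruct import (ConvergenceError, is_reliable_seed,
                              random_walk_with_restart, score_and_rank_pairs,
                              seed_priors, select_top)


def _vec(**named):
    values = {name: 0.0 for name in PAIR_COMPONENTS}
    values.update(named)
    return PairVector(**values)


class TestSeedRule:
    def test_all_zero_is_not_seed(self):
        assert not is_reliable_seed(_vec())

    def test_two_databases_and_majority_nonzero(self):
        v = _vec(EPPI1=1, EPPI2=1, D=1, MF=0.5, mf=1, BP=0.5, bp=1, CC=0.5,
                 cc=1)  # 9 of 17 non-zero, 2 database indicators
        assert is_reliable_seed(v)

    def test_single_database_fails_even_when_dense(self):
        values = {name: 1.0 for name in PAIR_COMPONENTS}
        values.update(EPPI2=0.0, TAP1=0.0, TAP5=0.0)  # only EPPI1 indicates
        assert not is_reliable_seed(PairVector(**values))

    def test_exactly_half_nonzero_fails(self):
        # 8 of 17 is not strictly more than half
        v = _vec(EPPI1=1, EPPI2=1, TAP1=1, TAP5=1, D=1, S=1, CE=1, CD=1)
        assert not is_reliable_seed(v)

    def test_indicator_set_is_configurable(self):
        v = _vec(TAP2=1, TAP3=1, D=1, S=1, CE=1, CD=1, MF=1, BP=1, CC=1)
        assert not is_reliable_seed(v)
        assert is_reliable_seed(v, indicators=("TAP2", "TAP3"))


def _table(*keys):
    return FingerprintTable(
        keys=tuple(tuple(k) for k in keys),
        members=tuple(((f"A{i}", f"B{i}"),) for i in range(len(keys))))


class TestSeedPriors:
    def test_equal_mass_on_seeds(self):
        seed_key = tuple(_vec(EPPI1=1, EPPI2=1, TAP1=1, TAP5=1, D=1, S=1,
                              CE=1, CD=1, MF=1))
        zero = tuple(_vec())
        table = _table(zero, seed_key, seed_key[:-1] + (0.5,), zero, zero)
        f0, seeds = seed_priors(table)
        assert seeds.size == 2
        assert f0.sum() == pytest.approx(1.0)
        assert set(np.nonzero(f0)[0]) == set(seeds)
        assert np.allclose(f0[seeds], 0.5)

    def test_no_seeds_is_an_error(self):
        with pytest.raises(ValueError, match="relax"):
            seed_priors(_table(tuple(_vec()), tuple(_vec(D=1))))


class TestRandomWalk:
    def test_alpha_one_returns_prior(self):
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = random_walk_with_restart(M, np.array([1.0, 0.0]), alpha=1.0)
        assert np.allclose(res.posterior, [1.0, 0.0])

    def test_two_node_worked_value(self):
        """Fixed point of F = 0.2*M@F + 0.8*F0 on a 2-cycle is (5/6, 1/6)."""
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        res = random_walk_with_restart(M, np.array([1.0, 0.0]), alpha=0.8,
                                       tol=1e-10)
        assert np.allclose(res.posterior, [25 / 30, 5 / 30], atol=1e-8)
        assert res.posterior[0] == pytest.approx(0.83333, abs=1e-5)
        assert res.posterior[1] == pytest.approx(0.16667, abs=1e-5)

    def test_uniform_prior_on_regular_graph_stays_uniform(self):
        g = nx.random_regular_graph(4, 10, seed=1)
        M = nx.to_numpy_array(g) / 4.0
        f0 = np.full(10, 0.1)
        res = random_walk_with_restart(M, f0, alpha=0.8)
        assert np.allclose(res.posterior, 0.1, atol=1e-6)

    @pytest.mark.parametrize("n,seed", [(5, 0), (20, 1), (50, 2)])
    def test_matches_direct_linear_solve(self, n, seed):
        """Posterior equals the solve of (I - (1-a)M)F = a*F0 within 1e-8."""
        rng = np.random.default_rng(seed)
        A = (rng.random((n, n)) < 0.3).astype(float)
        np.fill_diagonal(A, 0)
        A[0, 1] = A[1, 0] = 1  # no isolated first rows
        rows = A.sum(axis=1, keepdims=True)
        rows[rows == 0] = 1
        M = A / rows
        f0 = np.zeros(n)
        f0[rng.choice(n, 3, replace=False)] = 1 / 3
        alpha = 0.8
        res = random_walk_with_restart(M, f0, alpha=alpha, tol=1e-12)
        direct = np.linalg.solve(np.eye(n) - (1 - alpha) * M, alpha * f0)
        assert np.allclose(res.posterior, direct, atol=1e-8)

    def test_l1_contraction_on_regular_graphs(self):
        """On doubly stochastic M, successive L1 differences shrink by at
        least the factor (1 - alpha), and the iteration count obeys
        log(tol)/log(1-alpha)."""
        alpha, tol = 0.8, 1e-6
        for n, d, seed in [(20, 4, 0), (50, 6, 1)]:
            g = nx.random_regular_graph(d, n, seed=seed)
            M = nx.to_numpy_array(g) / d
            f0 = np.zeros(n)
            f0[:3] = 1 / 3
            # replay the update rule and record L1 step differences
            f = f0.copy()
            diffs = []
            while True:
                f_next = (1 - alpha) * M @ f + alpha * f0
                diffs.append(np.abs(f_next - f).sum())
                f = f_next
                if diffs[-1] < tol:
                    break
            for prev, cur in zip(diffs, diffs[1:]):
                assert cur <= (1 - alpha) * prev + 1e-15
            bound = math.log(tol) / math.log(1 - alpha)
            res = random_walk_with_restart(M, f0, alpha=alpha, tol=tol)
            assert res.n_iter <= math.ceil(bound) + 1
            assert len(diffs) <= math.ceil(bound) + 1

    def test_linearity_in_prior(self):
        rng = np.random.default_rng(3)
        g = nx.random_regular_graph(4, 12, seed=3)
        M = nx.to_numpy_array(g) / 4
        f0 = np.zeros(12)
        f0[:2] = 0.5
        base = random_walk_with_restart(M, f0, tol=1e-12).posterior
        scaled = random_walk_with_restart(M, 7.0 * f0, tol=1e-12).posterior
        assert np.allclose(scaled, 7.0 * base, atol=1e-8)
        # the induced ranking is identical
        assert list(np.argsort(-base)) == list(np.argsort(-scaled))

    def test_unseeded_component_gets_exactly_zero(self):
        M = np.zeros((4, 4))
        M[0, 1] = M[1, 0] = 1.0  # component {0,1}
        M[2, 3] = M[3, 2] = 1.0  # component {2,3}, no seed mass
        res = random_walk_with_restart(M, np.array([1.0, 0, 0, 0]))
        assert res.posterior[2] == 0.0 and res.posterior[3] == 0.0

    def test_max_iter_error_carries_residual(self):
        M = np.array([[0.0, 1.0], [1.0, 0.0]])
        with pytest.raises(ConvergenceError) as err:
            random_walk_with_restart(M, np.array([1.0, 0.0]), alpha=0.5,
                                     tol=1e-12, max_iter=2)
        assert err.value.residual > 0


class TestRanking:
    def test_pairs_inherit_fingerprint_posterior(self):
        table = FingerprintTable(
            keys=((0.0,), (1.0,)),
            members=((("A", "B"), ("A", "C")), (("B", "C"),)))
        ranked = score_and_rank_pairs(np.array([0.1, 0.3]), table)
        assert ranked == [(("B", "C"), 0.3), (("A", "B"), 0.1),
                          (("A", "C"), 0.1)]

    def test_ties_order_lexicographically(self):
        table = FingerprintTable(
            keys=((0.0,), (1.0,)),
            members=((("X", "Y"),), (("A", "B"),)))
        ranked = score_and_rank_pairs(np.array([0.2, 0.2]), table)
        assert [p for p, _ in ranked] == [("A", "B"), ("X", "Y")]

    def test_select_top(self):
        ranked = [(("A", "B"), 0.5), (("A", "C"), 0.4), (("B", "C"), 0.3),
                  (("B", "D"), 0.2), (("C", "D"), 0.1)]
        assert len(select_top(ranked, 0)) == 0
        assert len(select_top(ranked, 99)) == 5
        net = select_top(ranked, 3)
        assert net.pairs() == (("A", "B"), ("A", "C"), ("B", "C"))
        scores = [w for _, _, w in net.edges]
        assert scores == sorted(scores, reverse=True)
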