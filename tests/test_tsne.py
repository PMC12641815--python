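"""t-SNE building blocks against brute-force and finite-difference oracles."""

import numpy as np
import pytest

from spectraqsar import (
    TSNEConfig,
    conditional_affinities,
    fit_tsne,
    gradient,
    kl_loss,
    low_dim_affinities,
    symmetrize,
)
from spectraqsar.tsne import _entropy_bits


def realized_perplexities(P_cond):
    return [2.0 ** _entropy_bits(row[row > 0]) for row in P_cond]


class TestConditionalAffinities:
    def test_equidistant_pair_split_evenly(self):
        X = np.array([[0.0, 0.0], [1.0, 0.0], [-1.0, 0.0]])
        P, _ = conditional_affinities(X, perplexity=1.9)
        assert P[0, 1] == pytest.approx(0.5, abs=1e-6)
        assert P[0, 2] == pytest.approx(0.5, abs=1e-6)

    def test_rows_sum_to_one(self, rng):
        P, _ = conditional_affinities(rng.normal(size=(25, 6)), perplexity=8)
        assert np.abs(P.sum(axis=1) - 1).max() < 1e-9
        assert np.all(np.diag(P) == 0)

    @pytest.mark.parametrize("perplexity", [5.0, 12.0])
    def test_perplexity_calibration(self, rng, perplexity):
        X = rng.normal(size=(20, 10))
        P, _ = conditional_affinities(X, perplexity)
        realized = realized_perplexities(P)
        assert max(abs(r - perplexity) for r in realized) < 1e-3

    def test_perplexity_too_large_rejected(self, rng):
        with pytest.raises(ValueError, match="perplexity"):
            conditional_affinities(rng.normal(size=(10, 3)), perplexity=9.5)

    def test_non_finite_rejected(self):
        X = np.full((5, 2), np.nan)
        with pytest.raises(ValueError, match="finite"):
            conditional_affinities(X, perplexity=2)


class TestSymmetrize:
    def test_symmetric_input_identity_case(self):
        n = 6
        rng = np.random.default_rng(1)
        raw = rng.uniform(size=(n, n))
        raw = (raw + raw.T) / 2
        np.fill_diagonal(raw, 0)
        raw = raw / raw.sum(axis=1, keepdims=True)
        # rows of a symmetric conditional are not exactly symmetric; force it
        sym = (raw + raw.T) / 2
        model = symmetrize(sym)
        assert np.allclose(model.P, sym / n)

    def test_matches_elementwise_formula(self):
        rng = np.random.default_rng(2)
        raw = rng.uniform(size=(10, 10))
        np.fill_diagonal(raw, 0)
        raw = raw / raw.sum(axis=1, keepdims=True)
        P = symmetrize(raw).P
        n = 10
        for i in range(n):
            for j in range(n):
                expect = 0.0 if i == j else (raw[i, j] + raw[j, i]) / (2 * n)
                assert P[i, j] == pytest.approx(expect, abs=1e-15)

    def test_total_mass_one(self, rng):
        raw = rng.uniform(size=(12, 12))
        np.fill_diagonal(raw, 0)
        raw = raw / raw.sum(axis=1, keepdims=True)
        assert symmetrize(raw).P.sum() == pytest.approx(1.0, abs=1e-9)


class TestLowDimAffinities:
    def test_two_points_half_each(self):
        Q = low_dim_affinities(np.array([[0.0, 0.0], [5.0, 5.0]]))
        assert Q[0, 1] == pytest.approx(0.5)
        assert Q[1, 0] == pytest.approx(0.5)

    def test_three_equidistant_points(self):
        Y = np.array([[0, 0], [1, 0], [0.5, np.sqrt(3) / 2]])
        Q = low_dim_affinities(Y)
        off = Q[~np.eye(3, dtype=bool)]
        assert np.allclose(off, 1 / 6)

    def test_matches_brute_force(self, rng):
        Y = rng.normal(size=(8, 2))
        Q = low_dim_affinities(Y)
        n = 8
        num = np.zeros((n, n))
        for i in range(n):
            for j in range(n):
                if i != j:
                    num[i, j] = 1 / (1 + ((Y[i] - Y[j]) ** 2).sum())
        expect = num / num.sum()
        assert np.abs(Q - expect).max() < 1e-12


class TestKLLoss:
    def test_zero_when_equal(self, rng):
        Y = rng.normal(size=(6, 2))
        Q = low_dim_affinities(Y)
        assert kl_loss(Q, Q) == pytest.approx(0.0, abs=1e-12)

    def test_nonnegative(self, rng):
        P = symmetrize(_random_conditional(rng, 7)).P
        Q = low_dim_affinities(rng.normal(size=(7, 2)))
        assert kl_loss(P, Q) >= 0

    def test_matches_brute_force(self, rng):
        P = symmetrize(_random_conditional(rng, 6)).P
        Q = low_dim_affinities(rng.normal(size=(6, 2)))
        expect = sum(
            P[i, j] * np.log(P[i, j] / Q[i, j])
            for i in range(6)
            for j in range(6)
            if P[i, j] > 0
        )
        assert kl_loss(P, Q) == pytest.approx(expect, abs=1e-12)


class TestGradient:
    def test_zero_at_matching_distribution(self, rng):
        Y = rng.normal(size=(6, 2))
        Q = low_dim_affinities(Y)
        g = gradient(Q, Q, Y)
        assert np.abs(g).max() < 1e-12

    def test_rows_sum_to_zero(self, rng):
        P = symmetrize(_random_conditional(rng, 9)).P
        Y = rng.normal(size=(9, 2))
        g = gradient(P, low_dim_affinities(Y), Y)
        assert np.abs(g.sum(axis=0)).max() < 1e-10

    def test_matches_finite_differences(self, rng):
        n = 10
        X = rng.normal(size=(n, 30))
        P_cond, _ = conditional_affinities(X, perplexity=4)
        P = symmetrize(P_cond).P
        Y = rng.normal(size=(n, 2))
        g = gradient(P, low_dim_affinities(Y), Y)
        fd = np.zeros_like(Y)
        eps = 1e-5
        for i in range(n):
            for d in range(2):
                up, down = Y.copy(), Y.copy()
                up[i, d] += eps
                down[i, d] -= eps
                fd[i, d] = (
                    kl_loss(P, low_dim_affinities(up))
                    - kl_loss(P, low_dim_affinities(down))
                ) / (2 * eps)
        assert np.abs(g - fd).max() < 1e-4


class TestFit:
    def test_seeded_determinism(self, rng):
        X = rng.normal(size=(30, 10))
        cfg = TSNEConfig(perplexity=8, n_iter=50, seed=5)
        a = fit_tsne(X, cfg)
        b = fit_tsne(X, cfg)
        assert np.array_equal(a.Y, b.Y)
        assert a.loss_trace == b.loss_trace

    def test_loss_decreases(self, rng):
        X = np.vstack(
            [rng.normal(loc=c, size=(17, 10)) for c in (-4.0, 0.0, 4.0)]
        )
        res = fit_tsne(X, TSNEConfig(perplexity=10, n_iter=200, seed=2))
        assert res.final_loss < res.loss_trace[0]

    def test_affinity_mass_conserved_every_iteration(self, rng):
        X = rng.normal(size=(25, 8))
        sums = []
        fit_tsne(
            X,
            TSNEConfig(perplexity=6, n_iter=40, seed=3),
            callback=lambda t, Y, Q, loss: sums.append(Q.sum()),
        )
        assert len(sums) == 40
        assert max(abs(s - 1) for s in sums) < 1e-9

    def test_permutation_equivariance(self, rng):
        X = rng.normal(size=(20, 5))
        init = rng.normal(scale=1e-2, size=(20, 2))
        perm = rng.permutation(20)
        cfg = TSNEConfig(perplexity=6, n_iter=60, seed=0)
        base = fit_tsne(X, cfg, init=init)
        permuted = fit_tsne(X[perm], cfg, init=init[perm])
        assert np.allclose(permuted.Y, base.Y[perm], atol=1e-8)

    def test_scaffold_families_separate(self):
        from spectraqsar import GeneratorConfig, build_analytical_matrix, generate_dataset

        cfg = GeneratorConfig(
            n_compounds=60,
            seed=1,
            scaffold_mix={"pcb_like": 1 / 3, "alkane_like": 1 / 3, "methyl_ester": 1 / 3},
        )
        ds = generate_dataset(cfg)
        std = build_analytical_matrix(ds, standardize=True)
        res = fit_tsne(std.matrix, TSNEConfig(perplexity=10, n_iter=300, seed=1))
        fams = np.array(
            [ds.by_id(c).metadata["Scaffold"] for c in std.compound_ids]
        )
        within, between = _family_distances(res.Y, fams)
        assert within < between

    def test_nonfinite_loss_reports_iteration(self, rng):
        X = rng.normal(size=(15, 4))
        cfg = TSNEConfig(perplexity=5, n_iter=200, learning_rate=1e160, seed=0)
        with pytest.raises((FloatingPointError, ValueError)):
            fit_tsne(X, cfg)


def _random_conditional(rng, n):
    raw = rng.uniform(size=(n, n))
    np.fill_diagonal(raw, 0)
    return raw / raw.sum(axis=1, keepdims=True)


def _family_distances(Y, families):
    within, between = [], []
    n = len(families)
    for i in range(n):
        for j in range(i + 1, n):
            d = float(np.linalg.norm(Y[i] - Y[j]))
            (within if families[i] == families[j] else between).append(d)
    return float(np.mean(within)), float(np.mean(between))
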