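"""Admixture EM, cross-validation, replicate alignment, PCA."""

import itertools

import numpy as np
import pytest

from duckmix import ancestry, synthio
from duckmix.ancestry import (AncestryMatrix, align_replicates, cross_validate,
                              fit_admixture, merge_cluster_assignments, pca,
                              select_k)
from duckmix.genofilter import GenotypeMatrix


def matrix_from(genotypes, prefix="i"):
    n, m = genotypes.shape
    return GenotypeMatrix(genotypes.astype(np.int8),
                          [f"{prefix}{k}" for k in range(n)],
                          [f"l{j}" for j in range(m)])


def mixed_cohort(pools, qs, n_per_q, seed):
    """Individuals with known mixing proportion q toward pool A."""
    pa, pb = pools
    rng = np.random.default_rng(seed)
    rows, truth = [], []
    for q in qs:
        f = q * pa.freqs + (1 - q) * pb.freqs
        rows.append(rng.binomial(2, f, size=(n_per_q, len(f))))
        truth.extend([q] * n_per_q)
    return matrix_from(np.vstack(rows)), np.array(truth)


class TestFitAdmixture:
    def test_k1_degenerates_to_observed_frequencies(self):
        rng = np.random.default_rng(0)
        m = matrix_from(rng.integers(0, 3, (20, 50)))
        fit = fit_admixture(m, 1)
        assert (fit.Q == 1).all()
        np.testing.assert_allclose(fit.P[0], m.allele_frequencies(),
                                   atol=1e-5)

    def test_pure_pools_fixed_differences(self, fixed_difference_pools):
        pa, pb = fixed_difference_pools
        ga = synthio.sample_genotypes(pa, 15, seed=1, id_prefix="A")
        gb = synthio.sample_genotypes(pb, 15, seed=2, id_prefix="B")
        m = matrix_from(np.vstack([ga.genotypes, gb.genotypes]))
        fit = fit_admixture(m, 2, seed=3)
        own = np.maximum(fit.Q[:, 0], fit.Q[:, 1])
        assert (own >= 0.99).all()
        # the two groups load on opposite clusters
        assert fit.Q[0].argmax() != fit.Q[-1].argmax()

    def test_universal_heterozygote_is_symmetric(self, fixed_difference_pools):
        pa, pb = fixed_difference_pools
        ga = synthio.sample_genotypes(pa, 10, seed=4)
        gb = synthio.sample_genotypes(pb, 10, seed=5)
        het = np.ones((1, 200), dtype=np.int8)
        m = matrix_from(np.vstack([ga.genotypes, gb.genotypes, het]))
        fit = fit_admixture(m, 2, seed=6)
        assert fit.Q[-1] == pytest.approx([0.5, 0.5], abs=0.01)

    def test_k_larger_than_cohort_rejected(self):
        m = matrix_from(np.zeros((3, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            fit_admixture(m, 4)

    def test_mixing_proportion_recovery(self, pools_011):
        m, truth = mixed_cohort(pools_011, [0, 0.25, 0.5, 0.75, 1], 12,
                                seed=7)
        fit = fit_admixture(m, 2, seed=8)
        q_a = fit.Q[:, 0] if fit.Q[truth == 1, 0].mean() > 0.5 else fit.Q[:, 1]
        assert np.abs(q_a - truth).mean() <= 0.05


class TestCrossValidation:
    def test_argmin_contract(self):
        assert select_k({1: 0.5, 2: 0.3, 3: 0.4}) == 2

    def test_recovers_two_pools(self, pools_011):
        pa, pb = pools_011
        hits = 0
        for s in range(5):
            ga = synthio.sample_genotypes(
                synthio.AlleleFrequencyPool("A", pa.freqs[:300]), 20,
                seed=100 + s)
            gb = synthio.sample_genotypes(
                synthio.AlleleFrequencyPool("B", pb.freqs[:300]), 20,
                seed=200 + s)
            m = matrix_from(np.vstack([ga.genotypes, gb.genotypes]))
            errs = cross_validate(m, [1, 2, 3], folds=3, seed=s,
                                  max_iter=300)
            hits += select_k(errs) == 2
        assert hits >= 4

    def test_too_few_folds_rejected(self):
        m = matrix_from(np.zeros((4, 5), dtype=np.int8))
        with pytest.raises(ValueError):
            cross_validate(m, [1], folds=1)


class TestAlignment:
    def _fit_like(self, Q, ids=None):
        n, K = Q.shape
        ids = ids or [f"i{k}" for k in range(n)]
        P = np.full((K, 5), 0.5)
        return AncestryMatrix(ids, K, Q, P, 0.0)

    def test_column_swap_recovered(self):
        rng = np.random.default_rng(10)
        Q = rng.dirichlet(np.ones(3), size=12)
        runs = [self._fit_like(Q), self._fit_like(Q[:, [2, 0, 1]])]
        rep = align_replicates(runs)
        np.testing.assert_allclose(rep.consensus_Q, Q, atol=1e-9)

    def test_single_run_identity(self):
        rng = np.random.default_rng(11)
        Q = rng.dirichlet(np.ones(2), size=6)
        rep = align_replicates([self._fit_like(Q)])
        assert rep.permutations == [(0, 1)]
        np.testing.assert_allclose(rep.consensus_Q, Q)

    def test_noisy_runs_match_exhaustive_best_permutation(self):
        rng = np.random.default_rng(12)
        base = rng.dirichlet(np.ones(3), size=10)
        runs_Q = []
        for r in range(5):
            noisy = np.clip(base + rng.normal(0, 0.02, base.shape), 1e-6, 1)
            noisy /= noisy.sum(axis=1, keepdims=True)
            perm = rng.permutation(3)
            runs_Q.append((noisy[:, perm], perm))
        rep = align_replicates([self._fit_like(q) for q, _ in runs_Q])

        # brute force: best global permutation assignment maximizing total
        # pairwise similarity across all 5 runs
        best_score, best_consensus = -np.inf, None
        for perms in itertools.product(itertools.permutations(range(3)),
                                       repeat=4):
            aligned = [runs_Q[0][0]] + [q[:, p]
                                        for (q, _), p in zip(runs_Q[1:], perms)]
            score = sum((a * b).sum() for a, b in
                        itertools.combinations(aligned, 2))
            if score > best_score:
                best_score = score
                best_consensus = np.mean(aligned, axis=0)
        assert np.abs(rep.consensus_Q - best_consensus).max() < 0.01

    def test_greedy_matches_exhaustive_score_on_random_trials(self):
        rng = np.random.default_rng(13)
        agree = 0
        trials = 20
        for _ in range(trials):
            K = int(rng.integers(2, 5))
            base = rng.dirichlet(np.ones(K) * 2, size=8)
            runs = []
            for r in range(4):
                noisy = np.clip(base + rng.normal(0, 0.05, base.shape),
                                1e-6, 1)
                noisy /= noisy.sum(axis=1, keepdims=True)
                runs.append(noisy[:, rng.permutation(K)])
            rep = align_replicates([self._fit_like(q) for q in runs])
            greedy_score = sum(
                (a * b).sum() for a, b in itertools.combinations(
                    [r[:, p] for r, p in zip(runs, rep.permutations)], 2))
            best = -np.inf
            for perms in itertools.product(
                    itertools.permutations(range(K)), repeat=3):
                aligned = [runs[0]] + [q[:, p] for q, p in zip(runs[1:], perms)]
                best = max(best, sum((a * b).sum() for a, b in
                                     itertools.combinations(aligned, 2)))
            agree += greedy_score >= best - 1e-9
        assert agree >= 0.95 * trials

    def test_dimension_mismatch_rejected(self):
        rng = np.random.default_rng(14)
        q2 = rng.dirichlet(np.ones(2), size=5)
        q3 = rng.dirichlet(np.ones(3), size=5)
        with pytest.raises(ValueError):
            align_replicates([self._fit_like(q2), self._fit_like(q3)])


class TestPca:
    def test_fixed_difference_pools_separate_on_pc1(self, fixed_difference_pools):
        pa, pb = fixed_difference_pools
        ga = synthio.sample_genotypes(pa, 12, seed=20)
        gb = synthio.sample_genotypes(pb, 12, seed=21)
        m = matrix_from(np.vstack([ga.genotypes, gb.genotypes]))
        scores, _ = pca(m)
        a, b = scores[:12, 0], scores[12:, 0]
        assert max(a.min(), b.min()) > min(a.max(), b.max()) \
            or max(b.min(), a.min()) > min(b.max(), a.max())
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_duplicated_individual_identical_scores(self):
        rng = np.random.default_rng(22)
        g = rng.integers(0, 3, (10, 40)).astype(np.int8)
        g = np.vstack([g, g[0:1]])
        m = matrix_from(g)
        scores, _ = pca(m)
        np.testing.assert_allclose(scores[0], scores[-1], atol=1e-8)

    def test_explained_variance_bounded_by_total(self):
        rng = np.random.default_rng(23)
        m = matrix_from(rng.integers(0, 3, (15, 30)))
        scores, explained = pca(m)
        G = m.genotypes.astype(float)
        total = G.var(axis=0, ddof=1).sum()
        assert explained.sum() <= total + 1e-8
        assert (np.diff(explained) <= 1e-9).all()

    def test_constant_matrix_rejected(self):
        m = matrix_from(np.ones((5, 8), dtype=np.int8))
        with pytest.raises(ValueError):
            pca(m)


class TestMerge:
    def test_merge_arithmetic(self):
        Q = np.array([[0.2, 0.5, 0.3]])
        merged = merge_cluster_assignments(Q, [1, 2])
        np.testing.assert_allclose(merged, [[0.2, 0.8]])

    def test_merge_all_gives_ones(self):
        rng = np.random.default_rng(24)
        Q = rng.dirichlet(np.ones(4), size=6)
        merged = merge_cluster_assignments(Q, [0, 1, 2, 3])
        np.testing.assert_allclose(merged, np.ones((6, 1)))

    def test_empty_merge_rejected(self):
        with pytest.raises(ValueError):
            merge_cluster_assignments(np.ones((2, 2)) / 2, [])
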