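"""Admixture-proportion estimation, replicate alignment, K selection, PCA.

The model is the standard admixture likelihood for unlinked bi-allelic
SNPs: individual i's genotype at locus l is Binomial(2, f_il) with
f_il = sum_k q_ik p_kl, where q_ik are ancestry fractions (rows of Q sum
to 1) and p_kl cluster allele frequencies. (Q, P) are estimated by
expectation-maximization from random initialization; the log-likelihood is
checked to be non-decreasing at every iteration. Replicate runs are made
label-consistent by permutation alignment (cluster labels are arbitrary),
and K is selected by masked-entry cross-validation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linear_sum_assignment

from duckmix.genofilter import MISSING, GenotypeMatrix

_EPS = 1e-6


@dataclass
class AncestryMatrix:
    """Fitted ancestry model: Q (n x K), P (K x L), and the final loglik."""

    individual_ids: list[str]
    K: int
    Q: np.ndarray
    P: np.ndarray
    loglik: float
    cv_error: float | None = None
    seed: int | None = None

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        self.P = np.asarray(self.P, dtype=float)
        if self.Q.shape != (len(self.individual_ids), self.K):
            raise ValueError("Q shape mismatch")
        if self.P.shape[0] != self.K:
            raise ValueError("P shape mismatch")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-6):
            raise ValueError("Q rows must sum to 1")
        for arr in (self.Q, self.P):
            if ((arr < -1e-9) | (arr > 1 + 1e-9)).any():
                raise ValueError("Q and P must lie in [0, 1]")

    def q_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=self.individual_ids,
                            columns=[f"cluster_{k + 1}" for k in range(self.K)])


def _loglik(G: np.ndarray, obs: np.ndarray, Q: np.ndarray, P: np.ndarray) -> float:
    F = np.clip(Q @ P, _EPS, 1 - _EPS)
    Gc = np.where(obs, G, 0).astype(float)
    ll = Gc * np.log(F) + np.where(obs, 2.0 - Gc, 0.0) * np.log(1.0 - F)
    return float(ll[obs].sum())


def fit_admixture(matrix: GenotypeMatrix, K: int, seed: int = 0,
                  max_iter: int = 2000, tol: float = 1e-4,
                  supervised_labels: dict[str, int] | None = None
                  ) -> AncestryMatrix:
    """Fit the K-cluster admixture model by EM.

    Missing genotypes contribute nothing to the likelihood. Loci with no
    observed genotypes are excluded. In supervised mode the Q rows of
    labelled individuals are pinned to their cluster (up to the boundary
    clip). Convergence: log-likelihood improvement below ``tol`` or
    ``max_iter`` reached; the trajectory is asserted non-decreasing.
    """
    n, L = matrix.n_individuals, matrix.n_loci
    if K < 1:
        raise ValueError("K must be >= 1")
    if K > n:
        raise ValueError("K exceeds the number of individuals")

    G = matrix.genotypes.astype(float)
    obs = matrix.genotypes != MISSING
    keep = obs.any(axis=0)
    if not keep.all():
        G, obs = G[:, keep], obs[:, keep]
        L = keep.sum()
    Gc = np.where(obs, G, 0.0)
    G2c = np.where(obs, 2.0 - G, 0.0)

    freqs = Gc.sum(axis=0) / np.maximum(2.0 * obs.sum(axis=0), 1.0)

    if K == 1:
        Q = np.ones((n, 1))
        P = np.clip(freqs[None, :], _EPS, 1 - _EPS)
        ll = _loglik(G, obs, Q, P)
        return _expand_P(matrix, keep, Q, P, ll, K, seed)

    rng = np.random.default_rng(seed)
    Q = rng.dirichlet(np.ones(K), size=n)
    P = np.clip(freqs[None, :] + rng.normal(0, 0.05, size=(K, L)), _EPS, 1 - _EPS)

    sup_idx, sup_cluster = [], []
    if supervised_labels:
        pos = {ind: i for i, ind in enumerate(matrix.individual_ids)}
        for ind, k in supervised_labels.items():
            sup_idx.append(pos[ind])
            sup_cluster.append(k)

    def pin(Qm: np.ndarray) -> np.ndarray:
        if sup_idx:
            Qm[sup_idx, :] = _EPS / max(K - 1, 1)
            Qm[sup_idx, sup_cluster] = 1.0 - _EPS
            Qm /= Qm.sum(axis=1, keepdims=True)
        return Qm

    Q = pin(Q)
    ll_prev = -np.inf
    denom_q = 2.0 * obs.sum(axis=1, keepdims=True).astype(float)
    check_every = 5  # likelihood evaluated periodically; still monotone
    for it in range(max_iter):
        F = np.clip(Q @ P, _EPS, 1 - _EPS)
        A = Gc / F          # n x L
        B = G2c / (1.0 - F)
        # Both updates use responsibilities from the same (old) parameters,
        # which is what guarantees a non-decreasing likelihood.
        num = P * (Q.T @ A)
        den = num + (1.0 - P) * (Q.T @ B)
        P_new = np.clip(num / np.maximum(den, 1e-300), _EPS, 1 - _EPS)
        Q = Q * (A @ P.T + B @ (1.0 - P).T) / denom_q
        P = P_new
        Q = np.clip(Q, _EPS, None)
        Q /= Q.sum(axis=1, keepdims=True)
        Q = pin(Q)
        if it % check_every == check_every - 1 or it == max_iter - 1:
            ll = _loglik(G, obs, Q, P)
            if ll < ll_prev - 1e-6:
                raise AssertionError("EM log-likelihood decreased")
            if ll - ll_prev < tol:
                ll_prev = ll
                break
            ll_prev = ll
    if ll_prev == -np.inf:
        ll_prev = _loglik(G, obs, Q, P)
    return _expand_P(matrix, keep, Q, P, ll_prev, K, seed)


def _expand_P(matrix: GenotypeMatrix, keep: np.ndarray, Q: np.ndarray,
              P: np.ndarray, ll: float, K: int, seed: int) -> AncestryMatrix:
    full_P = np.full((K, matrix.n_loci), np.nan)
    full_P[:, keep] = P
    return AncestryMatrix(list(matrix.individual_ids), K, Q, full_P, ll, seed=seed)


# ---------------------------------------------------------------------------
# Cross-validation over K
# ---------------------------------------------------------------------------


def cross_validate(matrix: GenotypeMatrix, K_list: list[int], folds: int = 5,
                   seed: int = 0, replicates: int = 1, **fit_kwargs
                   ) -> dict[int, float]:
    """Masked-entry cross-validation error for each K.

    Non-missing genotype entries are partitioned into ``folds`` random
    folds; each fold is masked in turn, the model refitted, and the masked
    genotypes scored by mean squared error against their fitted expectation
    ``2 f_il``. Errors are averaged over folds (and replicate refits).
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    rng = np.random.default_rng(seed)
    obs_idx = np.argwhere(matrix.genotypes != MISSING)
    errors: dict[int, float] = {}
    for K in K_list:
        errs = []
        for rep in range(replicates):
            perm = rng.permutation(len(obs_idx))
            fold_of = np.arange(len(obs_idx)) % folds
            for f in range(folds):
                masked = obs_idx[perm[fold_of == f]]
                geno = matrix.genotypes.copy()
                geno[masked[:, 0], masked[:, 1]] = MISSING
                train = GenotypeMatrix(geno, matrix.individual_ids,
                                       matrix.locus_ids, matrix.chromosome_class)
                fit = fit_admixture(train, K, seed=int(rng.integers(2 ** 31)),
                                    **fit_kwargs)
                F = np.clip(fit.Q @ np.nan_to_num(fit.P, nan=0.5), _EPS, 1 - _EPS)
                pred = 2.0 * F[masked[:, 0], masked[:, 1]]
                truth = matrix.genotypes[masked[:, 0], masked[:, 1]].astype(float)
                errs.append(float(np.mean((pred - truth) ** 2)))
        errors[K] = float(np.mean(errs))
    return errors


def select_k(cv_errors: dict[int, float]) -> int:
    """K with the lowest averaged cross-validation error."""
    return min(cv_errors, key=cv_errors.get)


# ---------------------------------------------------------------------------
# Replicate alignment (label switching)
# ---------------------------------------------------------------------------


@dataclass
class ReplicateSet:
    runs: list[AncestryMatrix]
    permutations: list[tuple[int, ...]]
    consensus_Q: np.ndarray

    def consensus_frame(self) -> pd.DataFrame:
        ref = self.runs[0]
        return pd.DataFrame(self.consensus_Q, index=ref.individual_ids,
                            columns=[f"cluster_{k + 1}" for k in range(ref.K)])


def _similarity(Q1: np.ndarray, Q2: np.ndarray) -> float:
    """Mean per-individual dot-product similarity between two Q matrices."""
    return float((Q1 * Q2).sum(axis=1).mean())


def _best_permutation(reference: np.ndarray, Q: np.ndarray) -> tuple[int, ...]:
    K = Q.shape[1]
    if math.factorial(K) <= 40320:  # exhaustive up to K = 8
        best, best_s = None, -np.inf
        for perm in itertools.permutations(range(K)):
            s = _similarity(reference, Q[:, perm])
            if s > best_s:
                best, best_s = perm, s
        return best
    # optimal column matching via the assignment problem
    cost = -(reference.T @ Q)
    _, cols = linear_sum_assignment(cost)
    return tuple(int(c) for c in cols)


def align_replicates(runs: list[AncestryMatrix]) -> ReplicateSet:
    """Align replicate runs' cluster labels and average their Q matrices.

    The reference starts as the first run; each subsequent run is permuted
    to maximize mean per-individual dot-product similarity with the running
    mean of previously aligned runs (greedy over runs, exhaustive over
    permutations for K <= 8).
    """
    if not runs:
        raise ValueError("no runs supplied")
    ids0, K0 = runs[0].individual_ids, runs[0].K
    for r in runs[1:]:
        if r.individual_ids != ids0 or r.K != K0:
            raise ValueError("runs differ in individuals or K")

    aligned = [runs[0].Q]
    perms: list[tuple[int, ...]] = [tuple(range(K0))]
    for r in runs[1:]:
        reference = np.mean(aligned, axis=0)
        perm = _best_permutation(reference, r.Q)
        perms.append(perm)
        aligned.append(r.Q[:, perm])
    consensus = np.mean(aligned, axis=0)
    consensus /= consensus.sum(axis=1, keepdims=True)
    return ReplicateSet(list(runs), perms, consensus)


# ---------------------------------------------------------------------------
# PCA and cluster merging
# ---------------------------------------------------------------------------


def pca(matrix: GenotypeMatrix, n_components: int = 10
        ) -> tuple[np.ndarray, np.ndarray]:
    """PCA of the mean-imputed, centered genotype matrix.

    Returns (scores, explained variance per component), components ordered
    by decreasing variance. Component signs are fixed so each loading
    vector's largest-magnitude entry is positive (determinism).
    """
    G = matrix.genotypes.astype(float)
    G[matrix.genotypes == MISSING] = np.nan
    col_mean = np.nanmean(G, axis=0)
    variable = np.nanvar(G, axis=0) > 0
    if not variable.any():
        raise ValueError("all loci are constant; PCA undefined")
    G = np.where(np.isnan(G), col_mean, G)[:, variable]
    G = G - G.mean(axis=0)
    u, s, vt = np.linalg.svd(G, full_matrices=False)
    k = min(n_components, len(s))
    signs = np.sign(vt[np.arange(len(s)), np.argmax(np.abs(vt), axis=1)])
    signs[signs == 0] = 1.0
    scores = (u * s)[:, :k] * signs[:k]
    explained = (s ** 2 / (matrix.n_individuals - 1))[:k]
    return scores, explained


def merge_cluster_assignments(Q: np.ndarray, clusters_to_merge: list[int]
                              ) -> np.ndarray:
    """Sum the listed Q columns into one (appended last); rows still sum to 1.

    ``clusters_to_merge`` uses 0-based column indices.
    """
    Q = np.asarray(Q, dtype=float)
    if not clusters_to_merge:
        raise ValueError("empty merge list")
    merge = sorted(set(clusters_to_merge))
    if min(merge) < 0 or max(merge) >= Q.shape[1]:
        raise ValueError("cluster index out of range")
    others = [k for k in range(Q.shape[1]) if k not in merge]
    merged_col = Q[:, merge].sum(axis=1, keepdims=True)
    return np.hstack([Q[:, others], merged_col])
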