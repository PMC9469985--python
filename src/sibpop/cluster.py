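"""Admixture-model clustering, replicate alignment, and K-selection diagnostics.

The clusterer is a maximum-likelihood admixture model: each individual i has
mixing proportions q_i over K clusters, each cluster k has allele frequencies
p_kl. per locus l, and each observed allele copy is drawn from the mixture
sum_k q_ik p_kl.. Parameters are estimated by block-coordinate EM; the
log-likelihood is non-decreasing across iterations. This targets the same
estimand (the membership matrix Q) as Bayesian MCMC admixture programs while
being fast and reproducible; replicate variability is induced by seeded random
restarts. Replicates are label-aligned by a greedy search over column
permutations scored with the pairwise matrix-similarity statistic G, and the
Evanno delta-K statistic summarizes support across values of K.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sibpop.genio import MISSING, GenotypeTable


@dataclass
class ClusterConfig:
    """EM and replication controls.

    ``lambda_note`` records the symmetric allele-frequency prior setting of the
    Bayesian programs this model stands in for (lambda = 1); it is provenance
    only and does not enter the likelihood.
    """

    K: int = 2
    replicates: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    seed: int = 0
    alpha: float = 2.0
    lambda_note: float = 1.0

    def __post_init__(self) -> None:
        if self.K < 1:
            raise ValueError("K must be >= 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.tol <= 0:
            raise ValueError("tol must be > 0")
        if self.alpha < 1:
            raise ValueError("alpha must be >= 1 (interior MAP)")


@dataclass
class MembershipMatrix:
    """n x K cluster-membership proportions with the model log-likelihood."""

    Q: np.ndarray
    loglik: float
    individuals: list[str]
    freqs: list[np.ndarray] = field(repr=False, default_factory=list)  # per locus (K, m_l)
    allele_codes: list[np.ndarray] = field(repr=False, default_factory=list)

    def __post_init__(self) -> None:
        self.Q = np.asarray(self.Q, dtype=float)
        if self.Q.ndim != 2:
            raise ValueError("Q must be 2-D")
        if not np.allclose(self.Q.sum(axis=1), 1.0, atol=1e-8):
            raise ValueError("Q rows must sum to 1")

    @property
    def n(self) -> int:
        return self.Q.shape[0]

    @property
    def K(self) -> int:
        return self.Q.shape[1]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.Q, index=self.individuals, columns=[f"q{k + 1}" for k in range(self.K)])


def _encode(table: GenotypeTable) -> tuple[list[np.ndarray], list[np.ndarray]]:
    """Map allele codes to dense indices per locus; -1 marks missing copies."""
    idx_arrays, code_lists = [], []
    for j in range(table.n_loci):
        col = table.calls[:, j, :]
        codes = np.unique(col[col != MISSING])
        if codes.size == 0:
            raise ValueError(f"locus {table.locus_names[j]!r} has no non-missing calls")
        lookup = {c: i for i, c in enumerate(codes)}
        idx = np.full(col.shape, -1, dtype=np.int64)
        nz = col != MISSING
        idx[nz] = np.vectorize(lookup.get)(col[nz])
        idx_arrays.append(idx)
        code_lists.append(codes)
    return idx_arrays, code_lists


def fit_admixture(table: GenotypeTable, cfg: ClusterConfig) -> MembershipMatrix:
    """Fit the K-cluster admixture model by EM from one seeded random start.

    Ancestry proportions carry a weakly informative symmetric Dirichlet(alpha)
    prior (default alpha = 2, the smallest integer giving an interior MAP);
    the block-coordinate EM maximizes the resulting penalized likelihood, which
    is non-decreasing each iteration. The prior shrinks memberships toward
    uniform exactly when the genotypes carry no signal — the behavior of the
    Bayesian admixture samplers this estimator stands in for — while leaving
    strongly differentiated samples near 0/1. Missing allele copies contribute
    nothing to the likelihood. For K = 1 the model is degenerate: Q is the
    all-ones column and the cluster frequencies are the observed allele
    frequencies.
    """
    if cfg.K > table.n:
        raise ValueError(f"K={cfg.K} exceeds the number of individuals ({table.n})")
    if table.n < 2:
        raise ValueError("need at least 2 individuals")
    idx, codes = _encode(table)
    n, L, K = table.n, table.n_loci, cfg.K
    rng = np.random.default_rng(cfg.seed)

    # observed (global) allele frequencies per locus
    global_freqs = []
    for j in range(L):
        flat = idx[j][idx[j] >= 0]
        f = np.bincount(flat, minlength=len(codes[j])).astype(float)
        global_freqs.append(f / f.sum())

    if K == 1:
        Q = np.ones((n, 1))
        loglik = 0.0
        for j in range(L):
            flat = idx[j][idx[j] >= 0]
            loglik += float(np.log(global_freqs[j][flat]).sum())
        return MembershipMatrix(Q, loglik, list(table.individuals), [g[None, :] for g in global_freqs], codes)

    Q = rng.dirichlet(np.ones(K), size=n)
    P = []
    for j in range(L):
        m = len(codes[j])
        noise = rng.dirichlet(np.ones(m), size=K)
        p = 0.8 * global_freqs[j][None, :] + 0.2 * noise
        P.append(p / p.sum(axis=1, keepdims=True))

    a0 = cfg.alpha - 1.0                # Dirichlet prior pseudo-counts on Q rows
    prev = -np.inf
    loglik = 0.0
    for it in range(cfg.max_iter):
        q_num = np.zeros((n, K))
        p_num = [np.zeros_like(P[j]) for j in range(L)]
        loglik = 0.0
        for j in range(L):
            for c in (0, 1):
                a = idx[j][:, c]
                mask = a >= 0
                if not mask.any():
                    continue
                pm = P[j][:, a[mask]].T          # (nm, K)
                w = Q[mask] * pm
                tot = w.sum(axis=1)
                loglik += float(np.log(tot).sum())
                r = w / tot[:, None]
                q_num[mask] += r
                # accumulate responsibilities into allele bins
                pt = p_num[j].T                  # (m, K) view
                np.add.at(pt, a[mask], r)
        if not np.isfinite(loglik):
            raise FloatingPointError(f"non-finite likelihood at EM iteration {it}")
        penalized = loglik + a0 * float(np.log(np.clip(Q, 1e-300, None)).sum())
        # EM guarantees a monotone objective; tolerate fp rounding only
        assert penalized >= prev - 1e-8 * max(1.0, abs(prev)), "EM objective decreased"
        if penalized - prev < cfg.tol and it > 0:
            prev = penalized
            break
        prev = penalized
        Q = q_num + a0
        Q /= Q.sum(axis=1, keepdims=True)
        for j in range(L):
            s = p_num[j].sum(axis=1, keepdims=True)
            # a cluster with no responsibility mass at a locus keeps its prior shape
            P[j] = np.where(s > 0, p_num[j] / np.where(s == 0, 1, s), P[j])
    return MembershipMatrix(Q, float(loglik), list(table.individuals), P, codes)


def fit_replicates(table: GenotypeTable, cfg: ClusterConfig) -> list[MembershipMatrix]:
    """Run ``cfg.replicates`` seeded random restarts of :func:`fit_admixture`."""
    reps = []
    ss = np.random.SeedSequence(cfg.seed)
    for child in ss.spawn(cfg.replicates):
        sub = ClusterConfig(
            K=cfg.K,
            replicates=1,
            max_iter=cfg.max_iter,
            tol=cfg.tol,
            seed=int(child.generate_state(1)[0] % 2**31),
            alpha=cfg.alpha,
            lambda_note=cfg.lambda_note,
        )
        reps.append(fit_admixture(table, sub))
    return reps


# ---------------------------------------------------------------------------
# Replicate alignment (label switching)
# ---------------------------------------------------------------------------

@dataclass
class AlignmentResult:
    permutations: list[tuple[int, ...]]
    G: float
    Q_mean: MembershipMatrix


def pairwise_g(q1: np.ndarray, q2: np.ndarray) -> float:
    """Matrix-similarity statistic G in [0, 1]; 1 for identical matrices.

    G = 1 - ||Q1 - Q2||_F / sqrt(2 n): since rows sum to 1, the squared
    Frobenius distance between two membership matrices is at most 2n.
    """
    n = q1.shape[0]
    return 1.0 - float(np.linalg.norm(q1 - q2)) / math.sqrt(2.0 * n)


def align_replicates(reps: list[MembershipMatrix], repeats: int = 1000, seed: int = 0) -> AlignmentResult:
    """Permute replicate columns to undo label switching, then average.

    Greedy alignment: replicates are visited in order, each permuted to
    maximize G against the running mean of the already-aligned set; the
    procedure is repeated over ``repeats`` random visit orders and the best
    mean pairwise G wins. For small K the per-replicate search enumerates all
    K! permutations (exhaustive for K = 2).
    """
    if not reps:
        raise ValueError("no replicates")
    n, K = reps[0].Q.shape
    for r in reps:
        if r.Q.shape != (n, K):
            raise ValueError("replicate shape mismatch")
    qs = [r.Q for r in reps]
    R = len(qs)
    perms_all = list(itertools.permutations(range(K)))
    rng = np.random.default_rng(seed)
    if R == 1:
        return AlignmentResult([tuple(range(K))], 1.0, reps[0])

    def greedy(order: np.ndarray) -> tuple[list[tuple[int, ...]], float, list[np.ndarray]]:
        perm_of = [None] * R
        aligned: list[np.ndarray] = []
        ref_sum = np.zeros((n, K))
        for pos, ri in enumerate(order):
            q = qs[ri]
            if pos == 0:
                best_p, best_q = tuple(range(K)), q
            else:
                ref = ref_sum / pos
                best_p, best_score, best_q = None, -np.inf, None
                for p in perms_all:
                    qp = q[:, p]
                    s = pairwise_g(qp, ref)
                    if s > best_score:
                        best_p, best_score, best_q = p, s, qp
            perm_of[ri] = best_p
            aligned.append(best_q)
            ref_sum += best_q
        score = 0.0
        for i in range(R):
            for j in range(i + 1, R):
                score += pairwise_g(aligned[i], aligned[j])
        score /= R * (R - 1) / 2
        # recover per-original-index aligned matrices
        out = [None] * R
        for pos, ri in enumerate(order):
            out[ri] = aligned[pos]
        return perm_of, score, out

    best = greedy(np.arange(R))
    n_extra = max(0, min(repeats - 1, 200 if K <= 3 else repeats - 1))
    for _ in range(n_extra):
        cand = greedy(rng.permutation(R))
        if cand[1] > best[1]:
            best = cand
    perms, G, aligned = best
    q_mean = np.mean(aligned, axis=0)
    q_mean /= q_mean.sum(axis=1, keepdims=True)
    return AlignmentResult([tuple(p) for p in perms], float(G), MembershipMatrix(q_mean, float(np.mean([r.loglik for r in reps])), list(reps[0].individuals)))


# ---------------------------------------------------------------------------
# K-selection diagnostics
# ---------------------------------------------------------------------------

def k_diagnostics(objective_by_k: dict[int, list[float]]) -> pd.DataFrame:
    """Replicate mean/sd of the model objective per K, plus the Evanno delta-K.

    delta-K(K) = |mean L(K+1) - 2 mean L(K) + mean L(K-1)| / sd(L(K)); defined
    only for interior K with replicate sd > 0 (NaN and flagged otherwise).
    """
    ks = sorted(objective_by_k)
    means = {k: float(np.mean(objective_by_k[k])) for k in ks}
    sds = {k: float(np.std(objective_by_k[k], ddof=1)) if len(objective_by_k[k]) > 1 else float("nan") for k in ks}
    rows = []
    for k in ks:
        dk, flag = float("nan"), ""
        if k - 1 in means and k + 1 in means:
            if sds[k] > 0:
                dk = abs(means[k + 1] - 2 * means[k] + means[k - 1]) / sds[k]
            else:
                flag = "sd=0: delta-K undefined"
        rows.append({"K": k, "mean": means[k], "sd": sds[k], "delta_k": dk, "flag": flag})
    return pd.DataFrame(rows)
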