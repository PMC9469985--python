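"""Diversity, divergence, equilibrium tests, and spatial autocorrelation.

Per-group diversity follows the classic microsatellite summary: mean alleles
per locus (A), effective alleles Ae = 1/sum(p^2), alleles at >= 5% frequency
(A95), observed and expected heterozygosity (Ho, He = 1 - sum(p^2)), and the
heterozygote-deficit statistic FIS = 1 - Ho/He. Divergence between groups uses
the Weir–Cockerham (1984) variance-components estimator of FST (theta) and
Jost's D with Nei–Chesser sample-size correction. Hardy–Weinberg and gametic
(linkage) disequilibrium are tested by seeded Monte-Carlo permutation.
Spatial autocorrelation uses a multivariate Mantel correlogram on the
individual-level AMOVA (codominant squared) genetic distance, with progressive
Bonferroni correction across distance classes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln

from sibpop.genio import MISSING, GenotypeTable

# ---------------------------------------------------------------------------
# allele frequencies & diversity
# ---------------------------------------------------------------------------

def allele_freqs(table: GenotypeTable, group: list[str] | None = None) -> dict[str, pd.Series]:
    """Per-locus allele frequencies from non-missing calls.

    Returns ``{locus_name: Series(freq, index=allele code)}``; an all-missing
    locus maps to an empty Series (flagged by callers and excluded downstream).
    """
    sub = table if group is None else table.subset(group)
    out: dict[str, pd.Series] = {}
    for j, name in enumerate(sub.locus_names):
        col = sub.calls[:, j, :].ravel()
        col = col[col != MISSING]
        if col.size == 0:
            out[name] = pd.Series(dtype=float)
            continue
        codes, counts = np.unique(col, return_counts=True)
        out[name] = pd.Series(counts / counts.sum(), index=codes)
    return out


def fis(ho: float, he: float) -> float:
    """Heterozygote-deficit statistic FIS = 1 - Ho/He (undefined when He = 0)."""
    if he == 0:
        return float("nan")
    return 1.0 - ho / he


def diversity_summary(
    table: GenotypeTable,
    groups: dict[str, list[str]] | None = None,
    unbiased_he: bool = False,
) -> pd.DataFrame:
    """Per-group diversity metrics, averaged over loci with equal weights.

    Columns: n, A, Ae, A95, Ho, He, FIS. FIS is computed from the across-locus
    mean Ho and He. ``unbiased_he`` applies the 2n/(2n-1) small-sample
    correction to He (the default is the plain gene diversity 1 - sum(p^2)).
    """
    if groups is None:
        groups = {"All Samples": list(table.individuals)}
    rows = []
    for name, ids in groups.items():
        sub = table.subset(ids)
        a = ae = a95 = ho = he = 0.0
        used = 0
        for j in range(sub.n_loci):
            calls = sub.calls[:, j, :]
            ok = calls[:, 0] != MISSING
            if not ok.any():
                continue
            flat = calls[ok].ravel()
            codes, counts = np.unique(flat, return_counts=True)
            p = counts / counts.sum()
            sum_p2 = float(np.sum(p**2))
            he_l = 1.0 - sum_p2
            if unbiased_he:
                two_n = flat.size
                he_l *= two_n / (two_n - 1) if two_n > 1 else 1.0
            a += len(codes)
            ae += 1.0 / sum_p2
            a95 += int(np.sum(p >= 0.05))
            ho += float(np.mean(calls[ok, 0] != calls[ok, 1]))
            he += he_l
            used += 1
        if used == 0:
            raise ValueError(f"group {name!r} has no typed loci")
        rows.append(
            {
                "group": name,
                "n": sub.n,
                "A": a / used,
                "Ae": ae / used,
                "A95": a95 / used,
                "Ho": ho / used,
                "He": he / used,
                "FIS": fis(ho / used, he / used),
            }
        )
    return pd.DataFrame(rows).set_index("group")


# ---------------------------------------------------------------------------
# Weir–Cockerham theta and Jost's D
# ---------------------------------------------------------------------------

def _group_locus_arrays(table: GenotypeTable, groups: dict[str, list[str]], locus: int):
    """Sample sizes, allele freqs and heterozygote-carrier freqs per group."""
    stats = []
    for ids in groups.values():
        sub = table.subset(ids)
        calls = sub.calls[:, locus, :]
        ok = calls[:, 0] != MISSING
        calls = calls[ok]
        stats.append(calls)
    return stats


def theta_st(table: GenotypeTable, groups: dict[str, list[str]]) -> tuple[float, pd.Series]:
    """Weir–Cockerham (1984) theta over >= 2 groups.

    Per locus and per allele, variance components a (among groups), b (among
    individuals within groups) and c (within individuals) are computed and
    summed; the multilocus estimate is sum(a) / sum(a + b + c) over all loci
    and alleles. Small negative values are a known property of the estimator.
    Returns ``(multilocus theta, per-locus Series)``.
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    sum_a = sum_all = 0.0
    per_locus = {}
    for j, name in enumerate(table.locus_names):
        group_calls = [g for g in _group_locus_arrays(table, groups, j) if len(g) > 0]
        r = len(group_calls)
        if r < 2:
            per_locus[name] = float("nan")
            continue
        n_i = np.array([len(g) for g in group_calls], dtype=float)
        codes = np.unique(np.concatenate([g.ravel() for g in group_calls]))
        if len(codes) < 2:
            per_locus[name] = float("nan")
            continue
        n_bar = n_i.mean()
        if n_bar <= 1:
            per_locus[name] = float("nan")
            continue
        nc = (r * n_bar - np.sum(n_i**2) / (r * n_bar)) / (r - 1)
        la = lb = lc = 0.0
        for u in codes:
            p_i = np.array([np.mean(g == u) for g in group_calls])
            h_i = np.array([np.mean((g[:, 0] != g[:, 1]) & np.any(g == u, axis=1)) for g in group_calls])
            p_bar = np.sum(n_i * p_i) / (r * n_bar)
            s2 = np.sum(n_i * (p_i - p_bar) ** 2) / ((r - 1) * n_bar)
            h_bar = np.sum(n_i * h_i) / (r * n_bar)
            inner = p_bar * (1 - p_bar) - (r - 1) / r * s2
            a = (n_bar / nc) * (s2 - (inner - h_bar / 4.0) / (n_bar - 1))
            b = (n_bar / (n_bar - 1)) * (inner - (2 * n_bar - 1) / (4 * n_bar) * h_bar)
            c = h_bar / 2.0
            la += a
            lb += b
            lc += c
        tot = la + lb + lc
        per_locus[name] = la / tot if tot != 0 else float("nan")
        sum_a += la
        sum_all += tot
    if sum_all == 0:
        raise ValueError("theta undefined: no variance at any locus")
    return sum_a / sum_all, pd.Series(per_locus)


def jost_d(table: GenotypeTable, groups: dict[str, list[str]]) -> tuple[float, pd.Series]:
    """Jost's differentiation statistic D with Nei–Chesser-corrected Hs/Ht.

    Per locus, with r groups of harmonic-mean size ñ (individuals):
    Hs' = (2ñ/(2ñ-1)) Hs, Ht' = Ht + Hs'/(2 ñ r), and
    D = (Ht' - Hs')/(1 - Hs') * r/(r-1), clipped to [0, 1]. The multilocus
    value is the arithmetic mean over polymorphic loci; monomorphic loci are
    excluded (NaN per locus).
    """
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    per_locus = {}
    for j, name in enumerate(table.locus_names):
        group_calls = [g for g in _group_locus_arrays(table, groups, j) if len(g) > 0]
        r = len(group_calls)
        if r < 2:
            per_locus[name] = float("nan")
            continue
        codes = np.unique(np.concatenate([g.ravel() for g in group_calls]))
        if len(codes) < 2:
            per_locus[name] = float("nan")
            continue
        p = np.array([[np.mean(g == u) for u in codes] for g in group_calls])  # (r, m)
        n_i = np.array([len(g) for g in group_calls], dtype=float)
        n_harm = r / np.sum(1.0 / n_i)
        hs = 1.0 - float(np.mean(np.sum(p**2, axis=1)))
        ht = 1.0 - float(np.sum(p.mean(axis=0) ** 2))
        hs_est = (2 * n_harm / (2 * n_harm - 1)) * hs
        ht_est = ht + hs_est / (2 * n_harm * r)
        if hs_est >= 1.0:
            per_locus[name] = float("nan")
            continue
        d = (ht_est - hs_est) / (1.0 - hs_est) * r / (r - 1)
        per_locus[name] = float(np.clip(d, 0.0, 1.0))
    series = pd.Series(per_locus)
    valid = series.dropna()
    if valid.empty:
        raise ValueError("Jost's D undefined: all loci monomorphic")
    return float(valid.mean()), series


def divergence_matrix(table: GenotypeTable, groups: dict[str, list[str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise multilocus theta and Jost's D between groups (symmetric, 0 diagonal)."""
    names = list(groups)
    k = len(names)
    th = np.zeros((k, k))
    jd = np.zeros((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            pair = {names[i]: groups[names[i]], names[j]: groups[names[j]]}
            th[i, j] = th[j, i] = theta_st(table, pair)[0]
            jd[i, j] = jd[j, i] = jost_d(table, pair)[0]
    return (
        pd.DataFrame(th, index=names, columns=names),
        pd.DataFrame(jd, index=names, columns=names),
    )


# ---------------------------------------------------------------------------
# Hardy–Weinberg and gametic-disequilibrium tests
# ---------------------------------------------------------------------------

def _genotype_log_prob_stat(a1: np.ndarray, a2: np.ndarray, m: int) -> float:
    """Log of the ordering statistic of an exact HWP test: genotype arrays are
    ranked by their conditional probability given the allele counts. Terms that
    are invariant under allele reshuffling are dropped. ``a1``/``a2`` are dense
    allele indices in [0, m)."""
    het = int(np.sum(a1 != a2))
    key = np.minimum(a1, a2) * m + np.maximum(a1, a2)
    counts = np.bincount(key, minlength=m * m)
    counts = counts[counts > 0]
    return het * np.log(2.0) - float(np.sum(gammaln(counts + 1)))


def hwp_test(table: GenotypeTable, group: list[str] | None, locus: str, reps: int = 9999, seed: int = 0) -> float:
    """Monte-Carlo exact test for deviation from Hardy–Weinberg proportions.

    The observed allele copies are shuffled into random diploid pairings;
    genotype arrays are ordered by their conditional probability given the
    allele counts (the exact-test convention), and
    p = (#{simulated <= observed} + 1)/(reps + 1). Monomorphic loci return NaN
    (test skipped).
    """
    sub = table if group is None else table.subset(group)
    j = sub.locus_names.index(locus)
    calls = sub.calls[:, j, :]
    calls = calls[calls[:, 0] != MISSING]
    codes = np.unique(calls)
    if codes.size < 2:
        return float("nan")
    m = codes.size
    dense = np.searchsorted(codes, calls)
    rng = np.random.default_rng(seed)
    obs = _genotype_log_prob_stat(dense[:, 0], dense[:, 1], m)
    pool = dense.ravel().copy()
    hits = 0
    for _ in range(reps):
        rng.shuffle(pool)
        if _genotype_log_prob_stat(pool[0::2], pool[1::2], m) <= obs + 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


def ld_test(table: GenotypeTable, group: list[str] | None, locus_pair: tuple[str, str], reps: int = 9999, seed: int = 0) -> float:
    """Permutation test for gametic disequilibrium between two loci.

    Statistic: genotypic log-likelihood-ratio (G) of the two-locus genotype
    contingency table against independence; null distribution by permuting one
    locus's genotypes among individuals. Either locus monomorphic -> NaN.
    """
    sub = table if group is None else table.subset(group)
    j1 = sub.locus_names.index(locus_pair[0])
    j2 = sub.locus_names.index(locus_pair[1])
    c1 = np.sort(sub.calls[:, j1, :], axis=1)
    c2 = np.sort(sub.calls[:, j2, :], axis=1)
    ok = (c1[:, 0] != MISSING) & (c2[:, 0] != MISSING)
    c1, c2 = c1[ok], c2[ok]
    if len(np.unique(c1)) < 2 or len(np.unique(c2)) < 2:
        return float("nan")
    _, g1 = np.unique(c1, axis=0, return_inverse=True)
    _, g2 = np.unique(c2, axis=0, return_inverse=True)
    m1 = int(g1.max()) + 1
    m2 = int(g2.max()) + 1
    row_marg = np.bincount(g1, minlength=m1).astype(float)
    tot = float(len(g1))

    def g_stat(b: np.ndarray) -> float:
        tab = np.bincount(g1 * m2 + b, minlength=m1 * m2).astype(float).reshape(m1, m2)
        exp = np.outer(row_marg, np.bincount(b, minlength=m2)) / tot
        nz = tab > 0
        return 2.0 * float(np.sum(tab[nz] * np.log(tab[nz] / exp[nz])))

    obs = g_stat(g2)
    rng = np.random.default_rng(seed)
    hits = 0
    perm = g2.copy()
    for _ in range(reps):
        rng.shuffle(perm)
        if g_stat(perm) >= obs - 1e-12:
            hits += 1
    return (hits + 1) / (reps + 1)


def bonferroni(pvals: pd.Series | np.ndarray) -> np.ndarray:
    """Plain Bonferroni correction over the test family (NaNs not counted)."""
    p = np.asarray(pvals, dtype=float)
    m = int(np.sum(~np.isnan(p)))
    return np.minimum(1.0, p * max(m, 1))


# ---------------------------------------------------------------------------
# AMOVA (codominant squared) genetic distance
# ---------------------------------------------------------------------------

def amova_distance(table: GenotypeTable, on_no_overlap: str = "error") -> np.ndarray:
    """Pairwise individual squared genetic distance (codominant convention).

    Per locus, d2 = 0.5 * sum_a (x_a - y_a)^2 with x, y the two individuals'
    allele-dosage vectors, which yields the classic values: identical genotype
    0; heterozygotes sharing one allele 1; heterozygotes sharing none 2;
    heterozygote vs homozygote sharing one allele 1, sharing none 3; opposite
    homozygotes 4. Loci missing in either individual are skipped and the sum is
    rescaled by (total loci / shared loci). Pairs with no shared typed locus
    raise (``on_no_overlap='error'``) or get NaN (``'nan'``).
    """
    n, L = table.n, table.n_loci
    dist = np.zeros((n, n))
    shared = np.zeros((n, n))
    for j in range(L):
        calls = table.calls[:, j, :]
        ok = calls[:, 0] != MISSING
        codes = np.unique(calls[ok])
        if codes.size == 0:
            continue
        dosage = np.zeros((n, codes.size))
        for a, u in enumerate(codes):
            dosage[:, a] = np.sum(calls == u, axis=1)
        d2 = 0.5 * (
            np.sum(dosage**2, axis=1)[:, None]
            + np.sum(dosage**2, axis=1)[None, :]
            - 2 * dosage @ dosage.T
        )
        pair_ok = np.outer(ok, ok)
        dist += np.where(pair_ok, d2, 0.0)
        shared += pair_ok
    np.fill_diagonal(shared, L)
    if (shared == 0).any():
        if on_no_overlap == "error":
            bad = np.argwhere(shared == 0)[0]
            raise ValueError(
                f"no shared typed loci between {table.individuals[bad[0]]!r} and {table.individuals[bad[1]]!r}"
            )
        with np.errstate(invalid="ignore"):
            dist = np.where(shared > 0, dist * L / np.maximum(shared, 1), np.nan)
    else:
        dist = dist * L / shared
    np.fill_diagonal(dist, 0.0)
    return dist


# ---------------------------------------------------------------------------
# Mantel correlogram
# ---------------------------------------------------------------------------

@dataclass
class CorrelogramResult:
    table: pd.DataFrame
    breaks: np.ndarray


def mantel_correlog(
    geo_dist: np.ndarray,
    gen_dist: np.ndarray,
    n_classes: int = 80,
    reps: int = 999,
    seed: int = 0,
    alpha: float = 0.05,
) -> CorrelogramResult:
    """Multivariate Mantel correlogram with progressive Bonferroni correction.

    Equal-width distance classes span [0, max geographic distance]. For class
    k, the Mantel statistic is the negated Pearson correlation between the
    genetic-distance matrix and the class-k membership indicator over unordered
    pairs, so positive r means positive spatial autocorrelation (pairs in the
    class are genetically more alike than average). Significance comes from
    permuting individual labels (one-tailed in the observed direction,
    p = (hits + 1)/(reps + 1)); corrected p for class k is min(1, raw p * k).
    Classes in the upper half of the range are only tested while every
    individual still has a pair in the class (the all-points-included rule);
    classes with < 2 pairs are skipped.
    """
    geo = np.asarray(geo_dist, dtype=float)
    gen = np.asarray(gen_dist, dtype=float)
    n = geo.shape[0]
    if geo.shape != (n, n) or gen.shape != (n, n):
        raise ValueError("distance matrices must be square and same size")
    if n < 10:
        raise ValueError("need at least 10 individuals")
    if not (np.allclose(geo, geo.T) and np.allclose(gen, gen.T)):
        raise ValueError("distance matrices must be symmetric")
    iu = np.triu_indices(n, 1)
    gvec = geo[iu]
    yvec = gen[iu]
    edges = np.linspace(0.0, gvec.max(), n_classes + 1)
    cls = np.clip(np.digitize(gvec, edges[1:-1], right=True), 0, n_classes - 1)
    half = n_classes // 2

    rng = np.random.default_rng(seed)
    y_centered = yvec - yvec.mean()
    y_norm = float(np.linalg.norm(y_centered))

    rows = []
    perms = [rng.permutation(n) for _ in range(reps)]
    # permuted genetic vectors, built lazily in blocks to bound memory
    perm_vecs: np.ndarray | None = None

    for k in range(n_classes):
        sel = cls == k
        n_pairs = int(sel.sum())
        row = {
            "class": k + 1,
            "lo_km": edges[k],
            "hi_km": edges[k + 1],
            "n_pairs": n_pairs,
            "r": np.nan,
            "p_raw": np.nan,
            "p_corr": np.nan,
            "significant": False,
            "tested": False,
        }
        if n_pairs < 2:
            rows.append(row)
            continue
        ind = np.zeros((n, n))
        ind[iu[0][sel], iu[1][sel]] = 1.0
        participates = (ind + ind.T).sum(axis=1) > 0
        if k >= half and not participates.all():
            rows.append(row)
            continue
        x = sel.astype(float)
        xc = x - x.mean()
        x_norm = float(np.linalg.norm(xc))
        if x_norm == 0 or y_norm == 0:
            rows.append(row)
            continue
        r_obs = -float(xc @ y_centered) / (x_norm * y_norm)
        if perm_vecs is None:
            perm_vecs = np.empty((reps, len(yvec)), dtype=np.float32)
            for t, p in enumerate(perms):
                perm_vecs[t] = gen[np.ix_(p, p)][iu]
            perm_vecs -= perm_vecs.mean(axis=1, keepdims=True)
        r_perm = -(perm_vecs @ xc) / (x_norm * y_norm)
        if r_obs >= 0:
            hits = int(np.sum(r_perm >= r_obs - 1e-12))
        else:
            hits = int(np.sum(r_perm <= r_obs + 1e-12))
        p_raw = (hits + 1) / (reps + 1)
        tested_so_far = sum(1 for rr in rows if rr["tested"]) + 1
        p_corr = min(1.0, p_raw * tested_so_far)
        row.update(r=r_obs, p_raw=p_raw, p_corr=p_corr, significant=p_corr <= alpha, tested=True)
        rows.append(row)
    return CorrelogramResult(pd.DataFrame(rows), edges)
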