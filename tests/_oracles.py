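"""Independent from-scratch oracles for divergence estimators.

Deliberately written in plain scalar loops, directly off the published
variance-component / heterozygosity formulas, sharing no code with the
package's vectorized implementations.
"""

from __future__ import annotations

import numpy as np


def wc_theta_oracle(group_calls: list[np.ndarray]) -> float:
    """Weir & Cockerham (1984) multilocus theta from per-group (n, L, 2) calls.

    0 marks missing alleles. Multilocus estimate = ratio of summed components.
    """
    L = group_calls[0].shape[1]
    total_a = 0.0
    total_abc = 0.0
    for l in range(L):
        per_group = []
        for g in group_calls:
            calls = [tuple(pair) for pair in g[:, l, :] if pair[0] != 0]
            if calls:
                per_group.append(calls)
        r = len(per_group)
        if r < 2:
            continue
        alleles = sorted({a for grp in per_group for pair in grp for a in pair})
        if len(alleles) < 2:
            continue
        n_i = [len(grp) for grp in per_group]
        n_bar = sum(n_i) / r
        if n_bar <= 1:
            continue
        n_c = (r * n_bar - sum(n**2 for n in n_i) / (r * n_bar)) / (r - 1)
        for u in alleles:
            p_i = []
            h_i = []
            for grp in per_group:
                copies = [a for pair in grp for a in pair]
                p_i.append(copies.count(u) / len(copies))
                het = sum(1 for pair in grp if pair[0] != pair[1] and u in pair)
                h_i.append(het / len(grp))
            p_bar = sum(n * p for n, p in zip(n_i, p_i)) / (r * n_bar)
            s2 = sum(n * (p - p_bar) ** 2 for n, p in zip(n_i, p_i)) / ((r - 1) * n_bar)
            h_bar = sum(n * h for n, h in zip(n_i, h_i)) / (r * n_bar)
            a = (n_bar / n_c) * (
                s2 - (1.0 / (n_bar - 1)) * (p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - h_bar / 4.0)
            )
            b = (n_bar / (n_bar - 1)) * (
                p_bar * (1 - p_bar) - ((r - 1) / r) * s2 - ((2 * n_bar - 1) / (4 * n_bar)) * h_bar
            )
            c = h_bar / 2.0
            total_a += a
            total_abc += a + b + c
    if total_abc == 0:
        return float("nan")
    return total_a / total_abc


def jost_d_oracle(group_calls: list[np.ndarray]) -> float:
    """Jost's D (Nei–Chesser-corrected, SMOGD convention), mean over polymorphic loci."""
    L = group_calls[0].shape[1]
    values = []
    for l in range(L):
        per_group = []
        for g in group_calls:
            calls = [tuple(pair) for pair in g[:, l, :] if pair[0] != 0]
            if calls:
                per_group.append(calls)
        r = len(per_group)
        if r < 2:
            continue
        alleles = sorted({a for grp in per_group for pair in grp for a in pair})
        if len(alleles) < 2:
            continue
        n_i = [len(grp) for grp in per_group]
        n_harm = r / sum(1.0 / n for n in n_i)
        freqs = []
        for grp in per_group:
            copies = [a for pair in grp for a in pair]
            freqs.append({u: copies.count(u) / len(copies) for u in alleles})
        hs = 1.0 - sum(sum(f[u] ** 2 for u in alleles) for f in freqs) / r
        mean_p = {u: sum(f[u] for f in freqs) / r for u in alleles}
        ht = 1.0 - sum(mean_p[u] ** 2 for u in alleles)
        hs_est = (2 * n_harm / (2 * n_harm - 1)) * hs
        ht_est = ht + hs_est / (2 * n_harm * r)
        if hs_est >= 1.0:
            continue
        d = (ht_est - hs_est) / (1.0 - hs_est) * r / (r - 1)
        values.append(min(1.0, max(0.0, d)))
    if not values:
        return float("nan")
    return sum(values) / len(values)
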