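"""Synthetic spatial microsatellite data.

Two generators cover the regimes the analysis methods assume:

* :func:`simulate_hierarchical` — nested differentiation under the
  Balding–Nichols F-model: each branch of a bifurcating deme tree draws child
  allele frequencies from Dirichlet(p (1-F)/F) around its parent's, so drift
  per branch is controlled exactly. Demes are laid out spatially so genetic
  lineage matches geography (what the bifurcation method assumes), genotypes
  are Hardy–Weinberg within demes, and sampling can be clumped into "leks"
  (communal display sites) with uneven intensity.

* :func:`simulate_stepping_stone` — genuine isolation by distance: forward
  Wright–Fisher demes on a lattice with nearest-neighbor migration and
  stepwise mutation on a bounded allele ladder.

All randomness flows from ``cfg.seed``; identical configs give identical data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd

from sibpop.genio import Dataset, GenotypeTable, GeoTable


def balanced_tree(levels: int) -> Any:
    """A balanced bifurcating branching plan with 2**levels terminal demes."""
    if levels == 0:
        return "deme"
    return (balanced_tree(levels - 1), balanced_tree(levels - 1))


@dataclass
class SimConfig:
    """Parameters for both generators; unused fields are ignored per mode.

    Hierarchical mode: ``tree`` is a nested pair structure (leaves = demes),
    ``F`` the per-branch drift (scalar, or dict keyed by lineage path like
    "1", "12", "21", ... for branch-specific values). Stepping-stone mode:
    ``lattice`` demes of ``deme_size`` diploids evolve ``generations``
    generations with migration ``m`` and stepwise mutation ``mu``.
    """

    mode: str = "hierarchical"
    tree: Any = field(default_factory=lambda: balanced_tree(2))
    F: float | dict = 0.2
    loci: int = 15
    ancestral_alleles: int = 10
    samples_per_deme: int = 50
    sigma_km: float = 30.0
    root_spacing_km: float = 800.0
    leks_per_deme: int = 0            # 0 = plain Gaussian scatter (no lek clumping)
    lek_sigma_km: float = 5.0
    missing_rate: float = 0.0
    lattice: tuple[int, int] = (10, 2)
    m: float = 0.01
    mu: float = 5e-4
    generations: int = 200
    deme_size: int = 100
    allele_states: int = 20
    deme_spacing_km: float = 50.0
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.F, (int, float)) and not 0 < self.F < 1:
            raise ValueError("F must be in (0, 1)")
        if not 0 <= self.m <= 0.5:
            raise ValueError("m must be in [0, 0.5]")
        if self.loci < 1:
            raise ValueError("need at least one locus")


def _branch_f(cfg: SimConfig, path: str) -> float:
    if isinstance(cfg.F, dict):
        return float(cfg.F.get(path, cfg.F.get("default", 0.2)))
    return float(cfg.F)


def _leaves(tree: Any, path: str = "") -> list[str]:
    if not isinstance(tree, tuple):
        return [path or "0"]
    return _leaves(tree[0], path + "1") + _leaves(tree[1], path + "2")


def _tree_depth(tree: Any) -> int:
    if not isinstance(tree, tuple):
        return 0
    return 1 + max(_tree_depth(tree[0]), _tree_depth(tree[1]))


def simulate_hierarchical(cfg: SimConfig) -> Dataset:
    """Nested-drift dataset with per-individual truth labels.

    Returns a :class:`Dataset` whose ``truth`` frame has columns ``deme``
    (terminal deme index), ``path`` (branch lineage, e.g. "12"), and ``lek``.
    """
    if _tree_depth(cfg.tree) > 10:
        raise ValueError("tree depth > 10")
    rng = np.random.default_rng(cfg.seed)
    L, A = cfg.loci, cfg.ancestral_alleles
    ancestral = rng.dirichlet(np.ones(A), size=L)            # (L, A)

    deme_freqs: list[np.ndarray] = []
    deme_paths: list[str] = []
    deme_centers: list[np.ndarray] = []

    def descend(node: Any, freqs: np.ndarray, path: str, center: np.ndarray, spread: float, axis: int) -> None:
        if not isinstance(node, tuple):
            deme_freqs.append(freqs)
            deme_paths.append(path or "0")
            deme_centers.append(center.copy())
            return
        for i, child in enumerate(node):
            cpath = path + str(i + 1)
            f = _branch_f(cfg, cpath)
            child_freqs = np.empty_like(freqs)
            for l in range(L):
                alpha = freqs[l] * (1.0 - f) / f
                # Dirichlet needs strictly positive alpha; floor rare alleles
                child_freqs[l] = rng.dirichlet(np.maximum(alpha, 1e-6))
            offset = np.zeros(2)
            offset[axis % 2] = (i - 0.5) * spread
            descend(child, child_freqs, cpath, center + offset, spread / 2.0, axis + 1)

    descend(cfg.tree, ancestral, "", np.zeros(2), cfg.root_spacing_km, 0)

    ids, coords, rows, truth_rows = [], [], [], []
    for d, (freqs, path, center) in enumerate(zip(deme_freqs, deme_paths, deme_centers)):
        n = cfg.samples_per_deme
        if cfg.leks_per_deme > 0:
            lek_centers = center + rng.normal(scale=cfg.sigma_km, size=(cfg.leks_per_deme, 2))
            # uneven sampling intensity across leks
            w = rng.dirichlet(np.ones(cfg.leks_per_deme) * 0.8)
            lek_of = rng.choice(cfg.leks_per_deme, size=n, p=w)
            pts = lek_centers[lek_of] + rng.normal(scale=cfg.lek_sigma_km, size=(n, 2))
        else:
            lek_of = np.zeros(n, dtype=int)
            pts = center + rng.normal(scale=cfg.sigma_km, size=(n, 2))
        geno = np.empty((n, L, 2), dtype=np.int64)
        for l in range(L):
            geno[:, l, :] = rng.choice(np.arange(1, freqs.shape[1] + 1), size=(n, 2), p=freqs[l])
        if cfg.missing_rate > 0:
            miss = rng.random((n, L)) < cfg.missing_rate
            geno[miss] = 0
        for i in range(n):
            ind = f"d{d}_i{i}"
            ids.append(ind)
            coords.append(pts[i])
            rows.append(geno[i])
            truth_rows.append({"individual": ind, "deme": d, "path": path, "lek": f"d{d}_lek{lek_of[i]}"})

    table = GenotypeTable(ids, [f"locus{l + 1}" for l in range(L)], np.array(rows), [t["path"] for t in truth_rows])
    coords = np.array(coords)
    geo = GeoTable(ids, coords[:, 0], coords[:, 1], mode="km")
    truth = pd.DataFrame(truth_rows).set_index("individual")
    return Dataset(table, geo, truth)


def simulate_stepping_stone(cfg: SimConfig) -> Dataset:
    """Isolation-by-distance dataset from a lattice Wright–Fisher simulation.

    Demes sit on a ``cfg.lattice`` grid spaced ``deme_spacing_km`` apart; each
    generation, allele frequencies mix with nearest neighbors at rate ``m``,
    mutate stepwise (rate ``mu``, reflecting at the ladder bounds), and drift
    by multinomial resampling of 2N gene copies. Truth labels carry the deme
    index and lattice position.
    """
    rows_n, cols_n = cfg.lattice
    if rows_n * cols_n < 4:
        raise ValueError("lattice must have at least 2x2 demes")
    if cfg.generations < 1:
        raise ValueError("generations must be >= 1")
    if cfg.deme_size < 2:
        raise ValueError("deme size must be >= 2")
    rng = np.random.default_rng(cfg.seed)
    D = rows_n * cols_n
    L, A = cfg.loci, cfg.allele_states
    # common founding pool concentrated on central ladder states
    founding = np.zeros((L, A))
    lo, hi = A // 4, 3 * A // 4
    for l in range(L):
        founding[l, lo:hi] = rng.dirichlet(np.ones(hi - lo))
    freqs = np.repeat(founding[None, :, :], D, axis=0)       # (D, L, A)

    # adjacency of the lattice
    neighbors: list[list[int]] = [[] for _ in range(D)]
    for r in range(rows_n):
        for c in range(cols_n):
            d = r * cols_n + c
            for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                rr, cc = r + dr, c + dc
                if 0 <= rr < rows_n and 0 <= cc < cols_n:
                    neighbors[d].append(rr * cols_n + cc)

    two_n = 2 * cfg.deme_size
    for _ in range(cfg.generations):
        mixed = np.empty_like(freqs)
        for d in range(D):
            nb = neighbors[d]
            mixed[d] = (1 - cfg.m) * freqs[d] + (cfg.m / len(nb)) * freqs[nb].sum(axis=0)
        if cfg.mu > 0:
            up = np.roll(mixed, 1, axis=2)
            down = np.roll(mixed, -1, axis=2)
            # reflecting bounds: mass that would step off the ladder stays
            up[:, :, 0] = mixed[:, :, 0]
            down[:, :, -1] = mixed[:, :, -1]
            mixed = (1 - cfg.mu) * mixed + 0.5 * cfg.mu * (up + down)
        for d in range(D):
            for l in range(L):
                counts = rng.multinomial(two_n, mixed[d, l])
                freqs[d, l] = counts / two_n

    ids, pts, rows, truth_rows = [], [], [], []
    alleles = np.arange(1, A + 1)
    for d in range(D):
        r, c = divmod(d, cols_n)
        center = np.array([c * cfg.deme_spacing_km, r * cfg.deme_spacing_km])
        n = cfg.samples_per_deme
        loc = center + rng.normal(scale=cfg.sigma_km / 10.0, size=(n, 2))
        geno = np.empty((n, L, 2), dtype=np.int64)
        for l in range(L):
            p = freqs[d, l]
            if p.sum() <= 0:  # lost locus in this deme (cannot happen with mu>0)
                p = founding[l]
            geno[:, l, :] = rng.choice(alleles, size=(n, 2), p=p / p.sum())
        for i in range(n):
            ind = f"s{d}_i{i}"
            ids.append(ind)
            pts.append(loc[i])
            rows.append(geno[i])
            truth_rows.append({"individual": ind, "deme": d, "row": r, "col": c})
    table = GenotypeTable(ids, [f"locus{l + 1}" for l in range(L)], np.array(rows))
    pts = np.array(pts)
    geo = GeoTable(ids, pts[:, 0], pts[:, 1], mode="km")
    truth = pd.DataFrame(truth_rows).set_index("individual")
    return Dataset(table, geo, truth)
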