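"""Spatial iterative bifurcation process (SIBP).

Each round (1) splits the current sample into two admixture clusters (K = 2,
replicated and label-aligned), (2) kriges each cluster's membership
probabilities over space, and (3) retains, for each cluster, the individuals
whose own kriged membership is >= the isocline threshold (default 0.70);
everyone else is dropped from further rounds. Retained groups are re-bifurcated
recursively until no individuals reach the threshold, a group is too small, or
the recursion cap is hit. Terminal nodes are the "subpopulation centers" —
spatial cores of distinct genetic groups — and nodes are named by an
alternating binary nomenclature (1|2 then a|b: 1, 1a, 1a2, ...) recording each
center's lineage.
"""

from __future__ import annotations

import json
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from sibpop.cluster import ClusterConfig, align_replicates, fit_replicates
from sibpop.genio import Dataset
from sibpop.krige import IsoclineSelection, fit_surface, select_by_isocline

_DIGITS = ("1", "2")
_LETTERS = ("a", "b")


@dataclass
class SIBPConfig:
    threshold: float = 0.70
    replicates: int = 10
    seed: int = 0
    max_iter: int = 500
    tol: float = 1e-6
    min_group: int = 10
    max_depth: int = 8
    align_repeats: int = 200
    keep_surfaces: bool = False

    def __post_init__(self) -> None:
        if not 0.5 < self.threshold < 1:
            raise ValueError("threshold must be in (0.5, 1)")
        if self.min_group < 2:
            raise ValueError("min_group must be >= 2")


def name_children(parent_name: str) -> tuple[str, str]:
    """Next two lineage labels: root -> 1|2, then alternate a|b and 1|2."""
    _validate_name(parent_name)
    if parent_name == "" or parent_name[-1] in _LETTERS:
        suffixes = _DIGITS
    else:
        suffixes = _LETTERS
    return parent_name + suffixes[0], parent_name + suffixes[1]


def _validate_name(name: str) -> None:
    expect_digit = True
    for ch in name:
        ok = ch in _DIGITS if expect_digit else ch in _LETTERS
        if not ok:
            raise ValueError(f"malformed lineage name {name!r}")
        expect_digit = not expect_digit


def _node_seed(seed: int, name: str) -> int:
    """Deterministic per-node seed, independent of sibling execution order."""
    return int(np.random.SeedSequence([seed, zlib.crc32(name.encode() or b"root")]).generate_state(1)[0] % 2**31)


@dataclass
class BifurcationNode:
    name: str
    members_retained: list[str]
    depth: int
    children: list["BifurcationNode"] = field(default_factory=list)
    G: float | None = None
    q_mean: pd.DataFrame | None = field(default=None, repr=False)
    surfaces: tuple | None = field(default=None, repr=False)
    stop_reason: str | None = None

    @property
    def n(self) -> int:
        return len(self.members_retained)

    def walk(self):
        yield self
        for ch in self.children:
            yield from ch.walk()

    def to_dict(self, members: bool = True) -> dict:
        d = {
            "name": self.name or "root",
            "depth": self.depth,
            "n": self.n,
            "G": self.G,
            "stop_reason": self.stop_reason,
            "children": [c.to_dict(members) for c in self.children],
        }
        if members:
            d["members"] = list(self.members_retained)
        return d

    def to_json(self, members: bool = True) -> str:
        return json.dumps(self.to_dict(members), indent=2)

    def to_newick(self) -> str:
        def rec(node: BifurcationNode) -> str:
            label = node.name or "root"
            if not node.children:
                return f"{label}:{node.depth}"
            inner = ",".join(rec(c) for c in node.children)
            return f"({inner}){label}:{node.depth}"

        return rec(self) + ";"


@dataclass
class SubpopCenters:
    centers: dict[str, list[str]]
    unassigned: list[str]

    def to_frame(self) -> pd.DataFrame:
        rows = [{"individual": ind, "center": name} for name, mem in self.centers.items() for ind in mem]
        rows += [{"individual": ind, "center": ""} for ind in self.unassigned]
        return pd.DataFrame(rows)


@dataclass
class SIBPResult:
    tree: BifurcationNode
    centers: SubpopCenters
    report: pd.DataFrame

    @property
    def n_centers(self) -> int:
        return len(self.centers.centers)


def bifurcate_once(dataset: Dataset, cfg: SIBPConfig, seed: int | None = None):
    """One SIBP round: cluster at K=2, krige both memberships, select by isocline.

    Returns ``(retained_groups, diagnostics)`` where ``retained_groups`` is a
    pair of ID lists (either may be empty) and ``diagnostics`` carries the
    aligned mean membership matrix, the replicate-similarity statistic G, the
    two fitted surfaces, and the isocline selection.
    """
    if dataset.n < 2:
        raise ValueError("dataset too small to bifurcate")
    seed = cfg.seed if seed is None else seed
    ccfg = ClusterConfig(K=2, replicates=cfg.replicates, max_iter=cfg.max_iter, tol=cfg.tol, seed=seed)
    reps = fit_replicates(dataset.genotypes, ccfg)
    aligned = align_replicates(reps, repeats=cfg.align_repeats, seed=seed)
    q = aligned.Q_mean.Q
    pts = dataset.coords()
    surfaces = tuple(fit_surface(pts, q[:, c], jitter_seed=seed + c) for c in (0, 1))
    sel: IsoclineSelection = select_by_isocline(surfaces, pts, dataset.genotypes.individuals, cfg.threshold)
    diagnostics = {
        "q_mean": aligned.Q_mean.to_frame(),
        "G": aligned.G,
        "surfaces": surfaces,
        "selection": sel,
    }
    return (sel.retained[0], sel.retained[1]), diagnostics


def run_sibp(dataset: Dataset, cfg: SIBPConfig | None = None) -> SIBPResult:
    """Run the full recursive bifurcation and report centers and attrition.

    Recursion is depth-first; per-node seeds derive from ``cfg.seed`` and the
    node's lineage name, so subtrees reproduce independently of sibling order.
    A node becomes a terminal center when its bifurcation retains nobody, when
    it is too small to bifurcate (< min_group), or at max_depth. When exactly
    one side of a bifurcation retains individuals, the parent is itself
    reported as a center holding its retained members not claimed by deeper
    successful descendants.
    """
    cfg = cfg or SIBPConfig()
    if dataset.n == 0:
        raise ValueError("empty dataset")

    def recurse(sub: Dataset, name: str, depth: int) -> BifurcationNode:
        node = BifurcationNode(name, list(sub.genotypes.individuals), depth)
        if sub.n < cfg.min_group:
            node.stop_reason = "min_group"
            return node
        if depth >= cfg.max_depth:
            node.stop_reason = "max_depth"
            return node
        try:
            (g1, g2), diag = bifurcate_once(sub, cfg, seed=_node_seed(cfg.seed, name))
        except ValueError as exc:
            raise ValueError(f"bifurcation failed at node {name or 'root'!r}: {exc}") from exc
        node.G = diag["G"]
        node.q_mean = diag["q_mean"]
        if cfg.keep_surfaces:
            node.surfaces = diag["surfaces"]
        # retained groups below min_group are too small to krige or report as
        # centers; they terminate their side like an empty isocline does
        viable = [g if len(g) >= cfg.min_group else [] for g in (g1, g2)]
        if not viable[0] and not viable[1]:
            node.stop_reason = "no_isocline_members" if not (g1 or g2) else "children_below_min_group"
            return node
        if sum(len(g) for g in viable) == sub.n and not (viable[0] and viable[1]):
            # a single isocline swallowed the whole sample: no progress possible
            node.stop_reason = "no_progress"
            return node
        names = name_children(name)
        for child_ids, child_name in zip(viable, names):
            if not child_ids:
                continue
            node.children.append(recurse(sub.subset(child_ids), child_name, depth + 1))
        return node

    root = recurse(dataset, "", 0)

    centers: dict[str, list[str]] = {}

    def collect(node: BifurcationNode) -> set[str]:
        """Register centers below (and possibly at) this node; return claimed IDs."""
        if not node.children:
            centers[node.name or "root"] = list(node.members_retained)
            return set(node.members_retained)
        claimed: set[str] = set()
        for ch in node.children:
            claimed |= collect(ch)
        if len(node.children) == 1:
            # one side retained nobody: the node is itself a center for its
            # retained members not claimed deeper down
            own = [i for i in node.members_retained if i not in claimed]
            if own:
                centers[node.name or "root"] = own
                claimed |= set(own)
        return claimed

    claimed = collect(root)
    all_ids = list(dataset.genotypes.individuals)
    unassigned = [i for i in all_ids if i not in claimed]
    centers = dict(sorted(centers.items()))

    rows = []
    for node in root.walk():
        if node.children or node.stop_reason in ("no_isocline_members", "children_below_min_group", "no_progress"):
            kept = sum(ch.n for ch in node.children)
            rows.append(
                {
                    "node": node.name or "root",
                    "round": node.depth + 1,
                    "n_start": node.n,
                    "n_retained": kept,
                    "cut_pct": 100.0 * (node.n - kept) / node.n,
                    "G": node.G,
                }
            )
    report = pd.DataFrame(rows)
    return SIBPResult(root, SubpopCenters(centers, unassigned), report)
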