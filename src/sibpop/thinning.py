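"""Spatial sample thinning.

Uneven sampling intensity biases spatial genetic analyses, so sampling is
homogenized before clustering: locations are grouped by agglomerative
hierarchical clustering (Lance–Williams updates, complete linkage by default),
the tree is cut so clusters are separated by more than a threshold distance
(default 50 km), and clusters larger than a cap (default 10) are subsampled
uniformly at random.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

from sibpop.genio import Dataset, GeoTable

_LINKAGES = {"single", "complete", "average", "weighted", "centroid", "median", "ward"}


@dataclass
class ThinningConfig:
    linkage: str = "complete"
    cut_distance: float = 50.0
    max_per_cluster: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.cut_distance <= 0:
            raise ValueError("cut_distance must be > 0")
        if self.max_per_cluster < 1:
            raise ValueError("max_per_cluster must be >= 1")
        if self.linkage not in _LINKAGES:
            raise ValueError(f"unknown linkage {self.linkage!r}; choose from {sorted(_LINKAGES)}")


def cluster_locations(geo: GeoTable, cfg: ThinningConfig | None = None) -> np.ndarray:
    """Partition individuals into spatial clusters separated by > cut_distance km.

    Returns an integer label per individual (labels are arbitrary but stable:
    input order does not affect the partition, and merge-height ties resolve
    to the same connected components because the cut keeps every merge at
    height <= cut_distance).
    """
    cfg = cfg or ThinningConfig()
    geo = geo.to_km()
    pts = geo.coords()
    if len(pts) == 0:
        raise ValueError("no locations to cluster")
    if len(pts) == 1:
        return np.zeros(1, dtype=int)
    # canonical point order makes merge-height tie-breaking (and hence the
    # partition) independent of input ordering
    order = np.lexsort((np.array(geo.individuals), pts[:, 1], pts[:, 0]))
    z = linkage(pdist(pts[order]), method=cfg.linkage)
    labels_sorted = fcluster(z, t=cfg.cut_distance, criterion="distance")
    labels = np.empty(len(pts), dtype=int)
    labels[order] = labels_sorted
    return labels - 1


def thin(dataset: Dataset, cfg: ThinningConfig | None = None) -> tuple[Dataset, pd.DataFrame]:
    """Subsample each spatial cluster to at most ``max_per_cluster`` individuals.

    Clusters at or below the cap are kept whole; larger clusters are sampled
    uniformly without replacement with ``cfg.seed``. Returns the thinned
    dataset (original individual order) and a per-cluster report with kept and
    dropped counts.
    """
    cfg = cfg or ThinningConfig()
    labels = cluster_locations(dataset.geo, cfg)
    rng = np.random.default_rng(cfg.seed)
    ids = np.array(dataset.genotypes.individuals)
    keep_mask = np.zeros(len(ids), dtype=bool)
    records = []
    for lab in np.unique(labels):
        members = np.flatnonzero(labels == lab)
        if len(members) > cfg.max_per_cluster:
            chosen = rng.choice(members, size=cfg.max_per_cluster, replace=False)
        else:
            chosen = members
        keep_mask[chosen] = True
        records.append(
            {
                "cluster": int(lab),
                "size": int(len(members)),
                "kept": int(len(chosen)),
                "dropped": int(len(members) - len(chosen)),
            }
        )
    report = pd.DataFrame.from_records(records).sort_values("cluster").reset_index(drop=True)
    thinned = dataset.subset(list(ids[keep_mask]))
    return thinned, report
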