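"""Maximum-posterior group assignment and kernel-density center polygons.

Individuals are assigned to the cluster with the highest membership
probability, and each group's spatial core is summarized by utilization-
distribution contours of a bivariate normal kernel density: the v-level
contour (v in {25, 50, 75}%) encloses the smallest-area region containing
fraction v of the estimated density mass — the home-range convention, not a
density-height quantile. Bandwidth defaults to the reference ("href") rule
h = sigma * n^(-1/6) with sigma = sqrt((var x + var y)/2).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPolygon, Polygon, mapping
from shapely.ops import unary_union
from skimage import measure

from sibpop.cluster import MembershipMatrix


def assign_max_posterior(q: MembershipMatrix | np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group label per individual = argmax of its membership row.

    Ties break toward the lowest column index; the second array flags rows
    where a tie occurred. Labels are 0-based column indices.
    """
    mat = q.Q if isinstance(q, MembershipMatrix) else np.asarray(q, dtype=float)
    labels = np.argmax(mat, axis=1)
    top = mat[np.arange(len(mat)), labels]
    ties = (np.isclose(mat, top[:, None])).sum(axis=1) > 1
    return labels, ties


@dataclass
class KDEContours:
    """Per-group utilization-distribution polygons at the requested levels."""

    polygons: dict[object, dict[float, MultiPolygon]]
    bandwidth: dict[object, float]
    thresholds: dict[object, dict[float, float]]
    masses: dict[object, dict[float, float]] = field(default_factory=dict)

    def to_geojson(self) -> str:
        features = []
        for group, by_level in self.polygons.items():
            for level, poly in by_level.items():
                features.append(
                    {
                        "type": "Feature",
                        "properties": {"group": str(group), "level": level},
                        "geometry": mapping(poly),
                    }
                )
        return json.dumps({"type": "FeatureCollection", "features": features})


def _href(points: np.ndarray) -> float:
    sigma = np.sqrt(0.5 * (points[:, 0].var(ddof=1) + points[:, 1].var(ddof=1)))
    return float(sigma * len(points) ** (-1.0 / 6.0))


def kde_contours(
    points_by_group: dict[object, np.ndarray],
    levels: tuple[float, ...] = (0.25, 0.50, 0.75),
    bandwidth: float | None = None,
    grid_n: int = 200,
    margin: float = 0.10,
) -> KDEContours:
    """Kernel-density utilization contours per group.

    For each group (>= 5 points) the density is evaluated on a ``grid_n`` x
    ``grid_n`` lattice over the group's bounding box expanded by ``margin`` per
    side; the v-level region is the set of cells with density above the
    threshold at which cumulative (sorted-descending) mass reaches v, and its
    boundary is polygonized. Smaller v gives a smaller region nested inside
    larger-v regions.
    """
    polygons: dict = {}
    bands: dict = {}
    thresholds: dict = {}
    masses: dict = {}
    for group, pts in points_by_group.items():
        pts = np.asarray(pts, dtype=float)
        if len(pts) < 5:
            raise ValueError(f"group {group!r}: need >= 5 points for a KDE")
        if np.allclose(pts.var(axis=0), 0):
            raise ValueError(f"group {group!r}: all points identical; jitter the coordinates")
        h = bandwidth if bandwidth is not None else _href(pts)
        if h <= 0:
            raise ValueError(f"group {group!r}: degenerate bandwidth; jitter the coordinates")
        x0, y0 = pts.min(axis=0)
        x1, y1 = pts.max(axis=0)
        mx = margin * (x1 - x0) + 3 * h
        my = margin * (y1 - y0) + 3 * h
        gx = np.linspace(x0 - mx, x1 + mx, grid_n)
        gy = np.linspace(y0 - my, y1 + my, grid_n)
        xx, yy = np.meshgrid(gx, gy)
        dens = np.zeros_like(xx)
        inv = 1.0 / (2.0 * h * h)
        for px, py in pts:
            dens += np.exp(-((xx - px) ** 2 + (yy - py) ** 2) * inv)
        dens /= len(pts) * 2.0 * np.pi * h * h
        cell = (gx[1] - gx[0]) * (gy[1] - gy[0])
        total = dens.sum() * cell
        order = np.argsort(dens.ravel())[::-1]
        cum = np.cumsum(dens.ravel()[order]) * cell / total
        polygons[group] = {}
        thresholds[group] = {}
        masses[group] = {}
        bands[group] = h
        for v in levels:
            idx = int(np.searchsorted(cum, v))
            idx = min(idx, len(cum) - 1)
            t = float(dens.ravel()[order][idx])
            thresholds[group][v] = t
            masses[group][v] = float(dens.ravel()[order][: idx + 1].sum() * cell / total)
            polys = []
            for contour in measure.find_contours(dens, t):
                ys = np.interp(contour[:, 0], np.arange(grid_n), gy)
                xs = np.interp(contour[:, 1], np.arange(grid_n), gx)
                ring = np.column_stack([xs, ys])
                if len(ring) >= 4:
                    poly = Polygon(ring).buffer(0)  # cleanup self-touching rings
                    if not poly.is_empty:
                        polys.append(poly)
            merged = unary_union(polys) if polys else Polygon()
            if isinstance(merged, Polygon):
                merged = MultiPolygon([merged]) if not merged.is_empty else MultiPolygon()
            polygons[group][v] = merged
    return KDEContours(polygons, bands, thresholds, masses)
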