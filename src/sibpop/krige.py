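"""Spatial interpolation of cluster-membership probabilities.

Membership values observed at irregular sample locations are interpolated with
a thin-plate spline smoother: s(x) minimizes the residual sum of squares plus
lambda times the bending energy. The smoothing weight lambda is chosen by
generalized cross-validation (GCV), mirroring the default behavior of kriging
tools commonly used for this task; lambda = 0 gives exact interpolation.
Predictions for membership surfaces are clipped to [0, 1]. Individuals are
assigned to a cluster's "subpopulation center" when the cluster's surface,
evaluated at their own coordinates, reaches the isocline threshold (default
0.70).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist


def _tps_kernel(r: np.ndarray) -> np.ndarray:
    """U(r) = r^2 log r with U(0) = 0."""
    out = np.zeros_like(r)
    nz = r > 0
    out[nz] = r[nz] ** 2 * np.log(r[nz])
    return out


@dataclass
class KrigedSurface:
    """A fitted thin-plate spline surface, evaluable at arbitrary (x, y) km.

    ``grid_x``/``grid_y``/``grid_values`` give a regular lattice over the
    sample bounding box (expanded by a margin) for export and plotting;
    membership selection always uses exact evaluation at sample coordinates.
    """

    points: np.ndarray = field(repr=False)
    coeffs: np.ndarray = field(repr=False)     # spline weights c, one per point
    poly: np.ndarray = field(repr=False)       # affine part (d0, dx, dy)
    smoothing: float                           # lambda chosen by GCV (or forced)
    clip: tuple[float, float] | None = (0.0, 1.0)
    grid_n: int = 200
    margin: float = 0.05
    grid_x: np.ndarray = field(init=False, repr=False)
    grid_y: np.ndarray = field(init=False, repr=False)
    grid_values: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        x0, y0 = self.points.min(axis=0)
        x1, y1 = self.points.max(axis=0)
        mx = self.margin * max(x1 - x0, 1e-9)
        my = self.margin * max(y1 - y0, 1e-9)
        self.grid_x = np.linspace(x0 - mx, x1 + mx, self.grid_n)
        self.grid_y = np.linspace(y0 - my, y1 + my, self.grid_n)
        gx, gy = np.meshgrid(self.grid_x, self.grid_y)
        self.grid_values = self.evaluate(np.column_stack([gx.ravel(), gy.ravel()])).reshape(gy.shape)

    def evaluate(self, xy: np.ndarray, clip: bool = True) -> np.ndarray:
        """Evaluate the surface at (m, 2) planar-km coordinates."""
        xy = np.atleast_2d(np.asarray(xy, dtype=float))
        k = _tps_kernel(cdist(xy, self.points))
        vals = k @ self.coeffs + self.poly[0] + xy @ self.poly[1:]
        if clip and self.clip is not None:
            vals = np.clip(vals, *self.clip)
        return vals


def fit_surface(
    points: np.ndarray,
    values: np.ndarray,
    smoothing: float | None = None,
    clip: tuple[float, float] | None = (0.0, 1.0),
    grid_n: int = 200,
    margin: float = 0.05,
    jitter_seed: int = 0,
) -> KrigedSurface:
    """Fit a thin-plate spline to values observed at irregular points.

    ``smoothing=None`` selects lambda by minimizing the GCV function
    n * ||y - yhat||^2 / (n - tr A)^2 over a log-spaced grid; ``smoothing=0``
    forces exact interpolation. Duplicate coordinates are perturbed by a tiny
    seeded jitter (1e-6 km) so the spline system stays full-rank.
    """
    pts = np.asarray(points, dtype=float).copy()
    y = np.asarray(values, dtype=float)
    n = len(pts)
    if pts.shape != (n, 2) or y.shape != (n,):
        raise ValueError("points must be (n, 2) and values (n,)")
    if n < 3:
        raise ValueError("need at least 3 points")
    # jitter exact duplicates
    _, first = np.unique(pts, axis=0, return_index=True)
    if len(first) < n:
        rng = np.random.default_rng(jitter_seed)
        dup = np.setdiff1d(np.arange(n), first)
        pts[dup] += rng.normal(scale=1e-6, size=(len(dup), 2))
    P = np.column_stack([np.ones(n), pts])
    if np.linalg.matrix_rank(P) < 3:
        raise ValueError("points are collinear; jitter the coordinates before fitting")

    K = _tps_kernel(cdist(pts, pts))
    # null-space reduction: c = Q2 z with P^T c = 0
    q, _ = np.linalg.qr(P, mode="complete")
    Q2 = q[:, 3:]                       # (n, n-3)
    B = Q2.T @ K @ Q2
    B = (B + B.T) / 2.0
    evals, evecs = np.linalg.eigh(B)
    evals = np.maximum(evals, 0.0)      # TPS energy is PSD on the null space
    w = evecs.T @ (Q2.T @ y)            # rotated data

    def coeffs_for(lam: float) -> tuple[np.ndarray, np.ndarray]:
        z = w / (evals + n * lam) if lam > 0 else _safe_div(w, evals)
        c = Q2 @ (evecs @ z)
        # affine part from the residual projected on P
        d, *_ = np.linalg.lstsq(P, y - K @ c - n * lam * c, rcond=None)
        return c, d

    def _safe_div(num: np.ndarray, den: np.ndarray) -> np.ndarray:
        den = np.where(den < 1e-12 * max(den.max(initial=0.0), 1.0), np.inf, den)
        return num / den

    if smoothing is None:
        scale = max(float(np.mean(evals)), 1e-12)
        grid = scale * np.logspace(-8, 3, 45) / n
        best_lam, best_gcv = grid[0], np.inf
        for lam in grid:
            shrink = n * lam / (evals + n * lam)
            rss = float(np.sum((shrink * w) ** 2))
            tr_a = n - float(np.sum(shrink))
            denom = (n - tr_a) ** 2
            if denom <= 0:
                continue
            g = n * rss / denom
            if g < best_gcv - 1e-15:
                best_gcv, best_lam = g, lam
        lam = float(best_lam)
    else:
        lam = float(smoothing)
    c, d = coeffs_for(lam)
    return KrigedSurface(pts, c, d, lam, clip=clip, grid_n=grid_n, margin=margin)


@dataclass
class IsoclineSelection:
    """Individuals inside each cluster's >= threshold membership isocline."""

    threshold: float
    retained: dict[int, list[str]]
    values: np.ndarray = field(repr=False, default=None)  # (n, n_surfaces) surface values


def select_by_isocline(
    surfaces: tuple[KrigedSurface, KrigedSurface],
    points: np.ndarray,
    ids: list[str],
    threshold: float = 0.70,
) -> IsoclineSelection:
    """Retain each individual for cluster c iff surface_c at its own location
    is >= threshold (boundary values retained); everyone else is dropped.

    With threshold > 0.5 and complementary surfaces the two retained sets are
    disjoint; thresholds <= 0.5 trigger a warning.
    """
    if threshold <= 0.5:
        warnings.warn("threshold <= 0.5: retained sets may overlap", stacklevel=2)
    points = np.asarray(points, dtype=float)
    vals = np.column_stack([s.evaluate(points) for s in surfaces])
    # small tolerance so values lying exactly on the isocline survive rounding
    retained = {
        c: [ids[i] for i in np.flatnonzero(vals[:, c] >= threshold - 1e-9)]
        for c in range(len(surfaces))
    }
    if threshold > 0.5:
        overlap = set(retained[0]) & set(retained[1])
        if overlap:
            # clipping can make both surfaces hit the bound at one spot; assign
            # the contested individuals to their larger-valued cluster
            for ind in overlap:
                i = ids.index(ind)
                drop = int(np.argmin(vals[i, :2]))
                retained[drop].remove(ind)
    return IsoclineSelection(threshold, retained, vals)


def export_ascii_grid(surface: KrigedSurface) -> str:
    """Surface grid as an ESRI-style ASCII grid (text, for GIS import)."""
    nrows, ncols = surface.grid_values.shape
    dx = surface.grid_x[1] - surface.grid_x[0]
    lines = [
        f"ncols {ncols}",
        f"nrows {nrows}",
        f"xllcorner {surface.grid_x[0]}",
        f"yllcorner {surface.grid_y[0]}",
        f"cellsize {dx}",
        "NODATA_value -9999",
    ]
    for row in surface.grid_values[::-1]:
        lines.append(" ".join(f"{v:.6g}" for v in row))
    return "\n".join(lines) + "\n"
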