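"""Spatial statistics and clustering for SMLM localization tables.

Implements the linearised Ripley's K function L(r) − r (zero under complete
spatial randomness, positive under clustering), DBSCAN cluster maps with
deterministic labelling, and cluster morphometrics (convex-hull area,
density, occupancy).
"""

from __future__ import annotations

import logging
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import shapely
from scipy.spatial import ConvexHull, cKDTree
from shapely.geometry import Polygon

from smquant.io import LocalizationTable, ParameterError

logger = logging.getLogger(__name__)

#: Default DBSCAN neighbourhood radii (nm) by dye class when the table has no
#: usable precision column: far-red dyes localize to ~20 nm, green to ~30 nm.
EPS_DEFAULT_FAR_RED = 20.0
EPS_DEFAULT_GREEN = 30.0


@dataclass
class RipleyCurve:
    """Linearised Ripley's K: L(r) − r per radius (nm)."""

    radii: np.ndarray
    l_minus_r: np.ndarray
    n_points: int
    roi_area: float


@dataclass
class ClusterParams:
    """DBSCAN parameters.

    ``eps`` (nm) defaults to the mean localization precision of the table;
    ``min_pts`` counts the point itself. ``smoothing`` is recorded for
    provenance with density-contour cluster outlines but does not affect the
    hull-based areas computed here.
    """

    eps: float | None = None
    min_pts: int = 5
    smoothing: int = 7

    def validate(self) -> None:
        if self.eps is not None and self.eps <= 0:
            raise ParameterError("eps must be > 0")
        if self.min_pts < 2:
            raise ParameterError("min_pts must be >= 2")


@dataclass
class ClusterResult:
    """Per-point labels (−1 = noise) and per-cluster metrics."""

    labels: np.ndarray
    clusters: list[dict] = field(default_factory=list)
    summary: dict = field(default_factory=dict)

    @property
    def n_clusters(self) -> int:
        return len(self.clusters)


def ripley_l_minus_r(
    locs: LocalizationTable,
    roi: Polygon | None = None,
    radii: np.ndarray | None = None,
    max_radius_fraction: float = 0.25,
) -> RipleyCurve:
    """Linearised Ripley's K with guard-band edge handling.

    K(r) = A · Σ_i N_i(r) / (n_c · (n − 1)) where the centre sum runs over
    points at least max(radii) from the ROI boundary (their neighbourhoods
    are fully observed) while all n points serve as neighbours; the
    self-pair is excluded. L(r) = sqrt(K(r)/π); the curve returned is
    L(r) − r, which has expectation 0 under CSR.
    """
    roi = roi if roi is not None else locs.roi
    if roi is None:
        raise ParameterError("an ROI polygon is required")
    xy = locs.xy[locs.points_in_roi()]
    n = len(xy)
    if n < 2:
        raise ParameterError("need at least 2 points inside the ROI")
    if radii is None:
        radii = np.linspace(20.0, 500.0, 25)
    radii = np.asarray(radii, dtype=float)
    if np.any(np.diff(radii) <= 0) or radii[0] <= 0:
        raise ParameterError("radii must be positive and strictly increasing")
    rmax = radii[-1]
    # min caliper width of the ROI bounds as a cheap size proxy
    minx, miny, maxx, maxy = roi.bounds
    limit = max_radius_fraction * min(maxx - minx, maxy - miny)
    if rmax > limit:
        raise ParameterError(
            f"max radius {rmax:.1f} nm exceeds {limit:.1f} nm "
            f"({max_radius_fraction:.0%} of the ROI's smaller extent)"
        )

    edge_dist = shapely.distance(
        shapely.points(xy[:, 0], xy[:, 1]), roi.exterior
    )
    centres = edge_dist >= rmax
    if not centres.any():
        raise ParameterError("no points lie a full max-radius inside the ROI")
    tree = cKDTree(xy)
    counts = np.empty(len(radii))
    for k, r in enumerate(radii):
        nb = tree.query_ball_point(xy[centres], r, return_length=True)
        counts[k] = nb.sum() - centres.sum()   # exclude self-pairs
    area = roi.area
    k_r = area * counts / (centres.sum() * (n - 1))
    l_r = np.sqrt(k_r / np.pi)
    return RipleyCurve(radii=radii, l_minus_r=l_r - radii,
                       n_points=n, roi_area=area)


def cluster_dbscan(
    locs: LocalizationTable,
    params: ClusterParams | None = None,
) -> ClusterResult:
    """DBSCAN over (x, y) with deterministic labelling.

    Core points have ≥ min_pts neighbours within eps (counting themselves);
    clusters are the connected components of core points plus their border
    points; everything else is noise (−1). Labels are assigned in order of
    each cluster's first core point's row index, and a border point
    reachable from several clusters joins the one with the lower label.
    """
    params = params or ClusterParams()
    params.validate()
    n = len(locs)
    if n == 0:
        return ClusterResult(labels=np.empty(0, dtype=int))
    eps = params.eps
    if eps is None:
        if locs.precision.size and np.all(np.isfinite(locs.precision)):
            eps = float(np.mean(locs.precision))
        else:
            eps = EPS_DEFAULT_FAR_RED
    tree = cKDTree(locs.xy)
    neighbours = tree.query_ball_point(locs.xy, eps)
    n_nb = np.array([len(nb) for nb in neighbours])   # includes self
    core = n_nb >= params.min_pts

    labels = np.full(n, -1, dtype=int)
    next_label = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = next_label
        queue = deque([i])
        while queue:
            j = queue.popleft()
            for k in neighbours[j]:
                if labels[k] == -1:
                    labels[k] = next_label
                    if core[k]:
                        queue.append(k)
        next_label += 1
    return _build_cluster_result(labels, locs, params)


def _build_cluster_result(
    labels: np.ndarray, locs: LocalizationTable, params: ClusterParams
) -> ClusterResult:
    result = ClusterResult(labels=labels)
    for cid in range(labels.max() + 1 if len(labels) else 0):
        members = locs.xy[labels == cid]
        area = _hull_area(members)
        result.clusters.append({
            "cluster_id": cid,
            "n_members": len(members),
            "area_nm2": area,
            "density_per_nm2": len(members) / area if area > 0 else np.nan,
            "centroid_x": float(members[:, 0].mean()),
            "centroid_y": float(members[:, 1].mean()),
        })
    result.summary = cluster_metrics(result, locs)
    return result


def _hull_area(points: np.ndarray) -> float:
    """Convex hull area; 0 for < 3 points or collinear sets."""
    if len(points) < 3:
        return 0.0
    if np.linalg.matrix_rank(points - points[0], tol=1e-9) < 2:
        return 0.0
    return float(ConvexHull(points).volume)   # 2D: volume is area


def cluster_metrics(result: ClusterResult, locs: LocalizationTable) -> dict:
    """Cluster summary: % clustered, counts, mean ± SEM area and occupancy.

    Cluster area is the convex hull of member coordinates; clusters whose
    members are collinear get area 0 and are excluded from the area mean
    (their count is logged and reported).
    """
    labels = result.labels
    if len(labels) != len(locs):
        raise ParameterError("labels do not align with the localization table")
    n = len(labels)
    clustered = int((labels >= 0).sum())
    areas = np.array([c["area_nm2"] for c in result.clusters])
    members = np.array([c["n_members"] for c in result.clusters])
    valid = areas > 0
    n_degenerate = int((~valid).sum()) if len(areas) else 0
    if n_degenerate:
        logger.info("%d cluster(s) with collinear members excluded from mean area",
                    n_degenerate)

    def _mean_sem(v: np.ndarray) -> tuple[float, float]:
        if len(v) == 0:
            return np.nan, np.nan
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return float(np.mean(v)), sem

    mean_area, sem_area = _mean_sem(areas[valid])
    mean_members, sem_members = _mean_sem(members)
    mean_density, sem_density = _mean_sem(
        np.array([c["density_per_nm2"] for c in result.clusters])[valid]
    )
    return {
        "n_points": n,
        "n_clusters": len(result.clusters),
        "pct_clustered": 100.0 * clustered / n if n else 0.0,
        "mean_area_nm2": mean_area,
        "sem_area_nm2": sem_area,
        "mean_members": mean_members,
        "sem_members": sem_members,
        "mean_density_per_nm2": mean_density,
        "sem_density_per_nm2": sem_density,
        "n_degenerate_clusters": n_degenerate,
    }
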