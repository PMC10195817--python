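"""Coordinate-based degree-of-colocalization (DoC) scoring.

Each localization receives a score in [−1, 1] built from the rank
correlation of its own-channel and other-channel local density gradients
across a ladder of radii, damped by the distance to the nearest
other-channel point: 1 means perfect colocalization, −1 segregation.
Points at or above a score threshold (default 0.4) count as colocalized.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import rankdata

from smquant.cluster import ClusterResult
from smquant.io import LocalizationTable, ParameterError

DOC_THRESHOLD_DEFAULT = 0.4


@dataclass
class DoCResult:
    """Per-point DoC scores for both channels plus threshold summaries."""

    scores_a: np.ndarray
    scores_b: np.ndarray
    threshold: float = DOC_THRESHOLD_DEFAULT
    n_zero_neighbour_a: int = 0
    n_zero_neighbour_b: int = 0

    @property
    def pct_colocalized_a(self) -> float:
        return 100.0 * np.mean(self.scores_a >= self.threshold) \
            if len(self.scores_a) else 0.0

    @property
    def pct_colocalized_b(self) -> float:
        return 100.0 * np.mean(self.scores_b >= self.threshold) \
            if len(self.scores_b) else 0.0


def _rank_correlation(ga: np.ndarray, gb: np.ndarray) -> np.ndarray:
    """Row-wise Spearman correlation of two (n, k) gradient stacks.

    Rows where either series is constant (zero rank variance) get 0: such
    gradients carry no ordering information about co-variation.
    """
    ra = rankdata(ga, axis=1)
    rb = rankdata(gb, axis=1)
    ra = ra - ra.mean(axis=1, keepdims=True)
    rb = rb - rb.mean(axis=1, keepdims=True)
    denom = np.sqrt((ra ** 2).sum(axis=1) * (rb ** 2).sum(axis=1))
    num = (ra * rb).sum(axis=1)
    out = np.zeros(len(ga))
    ok = denom > 0
    out[ok] = num[ok] / denom[ok]
    return out


def _channel_scores(
    xy_self: np.ndarray,
    tree_self: cKDTree,
    tree_other: cKDTree,
    radii: np.ndarray,
    r_max: float,
) -> tuple[np.ndarray, int]:
    n = len(xy_self)
    counts_self = np.empty((n, len(radii)))
    counts_other = np.empty((n, len(radii)))
    for k, r in enumerate(radii):
        counts_self[:, k] = tree_self.query_ball_point(xy_self, r, return_length=True) - 1
        counts_other[:, k] = tree_other.query_ball_point(xy_self, r, return_length=True)
    # density gradients N(r)/r², normalized by the value at r_max
    grad_self = counts_self / radii ** 2
    grad_other = counts_other / radii ** 2
    norm_self = grad_self[:, -1]
    norm_other = grad_other[:, -1]
    zero_self = norm_self <= 0
    with np.errstate(divide="ignore", invalid="ignore"):
        grad_self = np.where(norm_self[:, None] > 0, grad_self / norm_self[:, None], 0.0)
        grad_other = np.where(norm_other[:, None] > 0, grad_other / norm_other[:, None], 0.0)
    rho = _rank_correlation(grad_self, grad_other)
    d_nearest, _ = tree_other.query(xy_self, k=1)
    scores = rho * np.exp(-d_nearest / r_max)
    scores[zero_self] = 0.0
    return scores, int(zero_self.sum())


def doc_scores(
    cha: LocalizationTable,
    chb: LocalizationTable,
    r_max: float = 500.0,
    n_radii: int = 10,
    threshold: float = DOC_THRESHOLD_DEFAULT,
) -> DoCResult:
    """Score every localization of both channels for colocalization.

    For point i of channel A, neighbour counts N_A(i, r) (self excluded) and
    N_B(i, r) are taken at ``n_radii`` linearly spaced radii up to ``r_max``
    (nm); the density gradients N(r)/r², each normalized by its value at
    r_max, are rank-correlated (Spearman) and the correlation damped by
    exp(−d_i/r_max) with d_i the nearest channel-B distance. Points with no
    own-channel neighbour at r_max score 0 and are counted.
    """
    if len(cha) == 0 or len(chb) == 0:
        raise ParameterError("both channels must be non-empty")
    if r_max <= 0:
        raise ParameterError("r_max must be > 0")
    if n_radii < 4:
        raise ParameterError("n_radii must be >= 4")
    radii = np.linspace(r_max / n_radii, r_max, n_radii)
    tree_a = cKDTree(cha.xy)
    tree_b = cKDTree(chb.xy)
    scores_a, nz_a = _channel_scores(cha.xy, tree_a, tree_b, radii, r_max)
    scores_b, nz_b = _channel_scores(chb.xy, tree_b, tree_a, radii, r_max)
    return DoCResult(scores_a=scores_a, scores_b=scores_b, threshold=threshold,
                     n_zero_neighbour_a=nz_a, n_zero_neighbour_b=nz_b)


@dataclass
class ColocClusterSummary:
    per_channel: dict = field(default_factory=dict)


def _summarize_channel(
    scores: np.ndarray,
    clusters: ClusterResult,
    threshold: float,
    min_coloc_points: int,
) -> dict:
    labels = clusters.labels
    flags = []
    for c in clusters.clusters:
        cid = c["cluster_id"]
        n_hot = int((scores[labels == cid] >= threshold).sum())
        flags.append(n_hot >= min_coloc_points)
    flags = np.array(flags, dtype=bool)
    areas = np.array([c["area_nm2"] for c in clusters.clusters])
    dens = np.array([c["density_per_nm2"] for c in clusters.clusters])

    def _mean(v):
        return float(np.nanmean(v)) if len(v) else np.nan

    mean_area_c = _mean(areas[flags])
    mean_area_nc = _mean(areas[~flags])
    record = {
        "n_clusters": len(flags),
        "n_colocalized": int(flags.sum()),
        "frac_colocalized": float(flags.mean()) if len(flags) else np.nan,
        "mean_area_coloc_nm2": mean_area_c,
        "mean_area_noncoloc_nm2": mean_area_nc,
        "mean_density_coloc": _mean(dens[flags]),
        "mean_density_noncoloc": _mean(dens[~flags]),
        "area_ratio_coloc_over_noncoloc": (
            mean_area_c / mean_area_nc
            if np.isfinite(mean_area_c) and np.isfinite(mean_area_nc)
            and mean_area_nc > 0 else np.nan
        ),
        "coloc_flags": flags,
    }
    return record


def coloc_cluster_summary(
    doc: DoCResult,
    clusters_a: ClusterResult,
    clusters_b: ClusterResult,
    min_coloc_points: int = 5,
) -> ColocClusterSummary:
    """Split each channel's clusters into colocalized vs non-colocalized.

    A cluster is colocalized iff at least ``min_coloc_points`` of its
    members score at or above the DoC threshold. Channels with zero
    clusters report NaN ratios rather than failing.
    """
    if len(doc.scores_a) != len(clusters_a.labels):
        raise ParameterError("channel A scores do not align with its clusters")
    if len(doc.scores_b) != len(clusters_b.labels):
        raise ParameterError("channel B scores do not align with its clusters")
    return ColocClusterSummary(per_channel={
        "A": _summarize_channel(doc.scores_a, clusters_a, doc.threshold,
                                min_coloc_points),
        "B": _summarize_channel(doc.scores_b, clusters_b, doc.threshold,
                                min_coloc_points),
    })
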