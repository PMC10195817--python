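"""Independent brute-force reference implementations used only by tests.

Each oracle re-derives the quantity from its definition with the simplest
possible code path (double loops, exhaustive search), deliberately sharing
no code with the package implementations it checks.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import spearmanr


def naive_dbscan(xy: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n²) DBSCAN with the same determinism contract as the package:
    labels ordered by first core point's row index; border points claimed
    by the lower label."""
    n = len(xy)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    nbr = [np.nonzero(d[i] <= eps)[0].tolist() for i in range(n)]
    core = np.array([len(nb) >= min_pts for nb in nbr])
    labels = np.full(n, -1)
    cur = 0
    for i in range(n):
        if not core[i] or labels[i] != -1:
            continue
        labels[i] = cur
        stack = [i]
        while stack:
            j = stack.pop(0)
            for k in nbr[j]:
                if labels[k] == -1:
                    labels[k] = cur
                    if core[k]:
                        stack.append(k)
        cur += 1
    return labels


def brute_ripley(xy: np.ndarray, centres_mask: np.ndarray, area: float,
                 radii: np.ndarray) -> np.ndarray:
    """L(r) − r from the definition with an explicit double loop."""
    n = len(xy)
    out = np.empty(len(radii))
    for m, r in enumerate(radii):
        total = 0
        for i in np.nonzero(centres_mask)[0]:
            for j in range(n):
                if j != i and np.hypot(*(xy[i] - xy[j])) <= r:
                    total += 1
        k = area * total / (centres_mask.sum() * (n - 1))
        out[m] = np.sqrt(k / np.pi) - r
    return out


def brute_doc_scores(xy_a: np.ndarray, xy_b: np.ndarray, r_max: float,
                     n_radii: int) -> np.ndarray:
    """Per-point DoC for channel A, straight from the formula."""
    radii = np.linspace(r_max / n_radii, r_max, n_radii)
    scores = np.empty(len(xy_a))
    for i, p in enumerate(xy_a):
        da = np.sqrt(((xy_a - p) ** 2).sum(1))
        db = np.sqrt(((xy_b - p) ** 2).sum(1))
        na = np.array([(da <= r).sum() - 1 for r in radii], dtype=float)
        nb = np.array([(db <= r).sum() for r in radii], dtype=float)
        if na[-1] <= 0:
            scores[i] = 0.0
            continue
        ga = (na / radii ** 2) / (na[-1] / r_max ** 2)
        gb = (nb / radii ** 2) / (nb[-1] / r_max ** 2) if nb[-1] > 0 \
            else np.zeros(n_radii)
        if np.ptp(ga) == 0 or np.ptp(gb) == 0:
            rho = 0.0
        else:
            rho = spearmanr(ga, gb).statistic
            if not np.isfinite(rho):
                rho = 0.0
        scores[i] = rho * np.exp(-db.min() / r_max)
    return scores


def brute_msd(track: np.ndarray, kmax: int) -> np.ndarray:
    """Time-averaged MSD with explicit double loops over pairs."""
    pos = track[:, 1:4]
    n = len(pos)
    out = np.empty(kmax)
    for k in range(1, kmax + 1):
        acc = []
        for i in range(n - k):
            acc.append(np.sum((pos[i + k] - pos[i]) ** 2))
        out[k - 1] = np.mean(acc)
    return out


def brute_threshold_mask(heights: np.ndarray, smoothed: np.ndarray,
                         k_sigma: float) -> np.ndarray:
    """Per-pixel mask straight from the definition."""
    thr = smoothed.mean() + k_sigma * smoothed.std()
    return smoothed > thr


def brute_caliper_bounds(corners: np.ndarray, step_deg: float = 0.1):
    """Min/max width of support over exhaustive rotations."""
    angles = np.deg2rad(np.arange(0.0, 180.0, step_deg))
    widths = np.empty(len(angles))
    for i, a in enumerate(angles):
        proj = corners @ np.array([np.cos(a), np.sin(a)])
        widths[i] = proj.max() - proj.min()
    return widths.min(), widths.max()
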