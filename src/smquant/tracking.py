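"""MSD analysis, anomalous-diffusion fits and mobility classification.

Per-track time-averaged MSD curves are fitted to the anomalous-diffusion
law MSD(t) = 2·dims·D·t^α on a log-log scale over the first few lags, and
tracks are classified as static (D < 0.1 µm²/s), slow moving
(0.1 ≤ D ≤ 1 µm²/s) or diffuse (D > 1 µm²/s); boundary values fall in the
slow class because the outer-class inequalities are strict.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from smquant.io import ParameterError, TrackSet

STATIC_D_MAX = 0.1    # µm²/s
DIFFUSE_D_MIN = 1.0   # µm²/s
MIN_TRACK_LENGTH = 10


@dataclass
class MSDCurve:
    lags: np.ndarray      # s
    msd: np.ndarray       # µm²
    n_pairs: np.ndarray


@dataclass
class DiffusionFit:
    D: float              # µm²/s
    alpha: float
    fit_lags: int
    r_squared: float
    mobility_class: str   # static | slow | diffuse | unclassified
    track_id: int = -1
    failed: bool = False


def track_msd(track: np.ndarray, max_lag_fraction: float = 0.5) -> MSDCurve:
    """Time-averaged MSD of one (n, 4) track of (t, x, y, z).

    MSD(k·dt) averages the squared 3D displacement over all ordered pairs
    at lag k, for k = 1..floor(max_lag_fraction·n).
    """
    track = np.asarray(track, dtype=float)
    n = len(track)
    if n < MIN_TRACK_LENGTH:
        raise ParameterError(f"track shorter than {MIN_TRACK_LENGTH} points")
    if not 0.0 < max_lag_fraction <= 0.5:
        raise ParameterError("max_lag_fraction must be in (0, 0.5]")
    dt = track[1, 0] - track[0, 0]
    kmax = int(np.floor(max_lag_fraction * n))
    pos = track[:, 1:4]
    lags = np.arange(1, kmax + 1) * dt
    msd = np.empty(kmax)
    n_pairs = np.empty(kmax, dtype=int)
    for k in range(1, kmax + 1):
        disp = pos[k:] - pos[:-k]
        msd[k - 1] = np.mean(np.sum(disp ** 2, axis=1))
        n_pairs[k - 1] = n - k
    return MSDCurve(lags=lags, msd=msd, n_pairs=n_pairs)


def fit_anomalous(
    msd: MSDCurve,
    dims: int = 3,
    max_fit_lags: int = 4,
    track_id: int = -1,
) -> DiffusionFit:
    """Fit log MSD = log(2·dims·D) + α·log t over the first lags.

    Non-positive MSD values among the fit lags are dropped; fewer than 4
    usable lags flags the fit as failed (class "unclassified").
    """
    k = min(max_fit_lags, len(msd.lags))
    t = msd.lags[:k]
    y = msd.msd[:k]
    usable = y > 0
    if usable.sum() < 4:
        return DiffusionFit(D=np.nan, alpha=np.nan, fit_lags=int(usable.sum()),
                            r_squared=np.nan, mobility_class="unclassified",
                            track_id=track_id, failed=True)
    lt, ly = np.log(t[usable]), np.log(y[usable])
    slope, intercept = np.polyfit(lt, ly, 1)
    resid = ly - (slope * lt + intercept)
    ss_tot = np.sum((ly - ly.mean()) ** 2)
    r2 = 1.0 - np.sum(resid ** 2) / ss_tot if ss_tot > 0 else 1.0
    d = np.exp(intercept) / (2.0 * dims)
    fit = DiffusionFit(D=float(d), alpha=float(slope),
                       fit_lags=int(usable.sum()), r_squared=float(r2),
                       mobility_class="", track_id=track_id)
    fit.mobility_class = classify_mobility(fit)
    return fit


def fit_linear_msd(
    msd: MSDCurve, dims: int = 3, max_fit_lags: int = 4, track_id: int = -1
) -> DiffusionFit:
    """Linear short-lag alternative: MSD = 2·dims·D·t through the origin."""
    k = min(max_fit_lags, len(msd.lags))
    t, y = msd.lags[:k], msd.msd[:k]
    d = float(np.sum(t * y) / np.sum(t * t) / (2.0 * dims))
    pred = 2.0 * dims * d * t
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 - np.sum((y - pred) ** 2) / ss_tot if ss_tot > 0 else 1.0
    fit = DiffusionFit(D=d, alpha=1.0, fit_lags=k, r_squared=float(r2),
                       mobility_class="", track_id=track_id)
    fit.mobility_class = classify_mobility(fit)
    return fit


def classify_mobility(fit: DiffusionFit) -> str:
    """Threshold classification on D; failed fits are 'unclassified'."""
    if fit.failed or not np.isfinite(fit.D) or fit.D <= 0:
        return "unclassified"
    if fit.D < STATIC_D_MAX:
        return "static"
    if fit.D > DIFFUSE_D_MIN:
        return "diffuse"
    return "slow"


def analyze_tracks(
    ts: TrackSet,
    dims: int = 3,
    max_fit_lags: int = 4,
    max_lag_fraction: float = 0.5,
    linear: bool = False,
) -> list[DiffusionFit]:
    """Per-track MSD + anomalous (or linear) fit for a whole TrackSet."""
    fitter = fit_linear_msd if linear else fit_anomalous
    fits = []
    for tid, tr in zip(ts.track_ids, ts.tracks):
        curve = track_msd(tr, max_lag_fraction)
        fits.append(fitter(curve, dims=dims, max_fit_lags=max_fit_lags,
                           track_id=tid))
    return fits


def cell_summary(
    fits: list[DiffusionFit],
    cell_ids: list | np.ndarray | None = None,
) -> dict:
    """Per-cell mean D, mean α and mobility-class percentages.

    ``cell_ids`` assigns each fit to a cell; without it all fits form one
    cell. Unclassified fits are excluded from percentages. The cohort block
    reports mean ± SEM across cells.
    """
    if cell_ids is None:
        cell_ids = np.zeros(len(fits), dtype=int)
    cell_ids = np.asarray(cell_ids)
    records = []
    for cell in np.unique(cell_ids):
        sub = [f for f, c in zip(fits, cell_ids) if c == cell and not f.failed]
        if not sub:
            continue
        classes = np.array([f.mobility_class for f in sub])
        records.append({
            "cell_id": cell,
            "n_tracks": len(sub),
            "mean_D": float(np.mean([f.D for f in sub])),
            "mean_alpha": float(np.mean([f.alpha for f in sub])),
            "pct_static": 100.0 * np.mean(classes == "static"),
            "pct_slow": 100.0 * np.mean(classes == "slow"),
            "pct_diffuse": 100.0 * np.mean(classes == "diffuse"),
        })

    def _mean_sem(key: str) -> tuple[float, float]:
        v = np.array([r[key] for r in records])
        if len(v) == 0:
            return np.nan, np.nan
        sem = float(np.std(v, ddof=1) / np.sqrt(len(v))) if len(v) > 1 else 0.0
        return float(v.mean()), sem

    cohort = {}
    for key in ("mean_D", "mean_alpha", "pct_static", "pct_slow", "pct_diffuse"):
        m, s = _mean_sem(key)
        cohort[key] = m
        cohort[f"{key}_sem"] = s
    return {"cells": records, "cohort": cohort}
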