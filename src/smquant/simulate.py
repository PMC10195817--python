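"""Synthetic-data generators with ground truth.

Every generator is a pure function of its parameters and seed, and returns
enough ground truth to score the downstream analysis (cluster membership,
shared-centre flags, mobility class, FRAP/KD parameters, DNA contour and
binding positions) without re-deriving it.

Defaults mirror the acquisition regimes of the study these analyses serve:
~20-30 nm localization precision, 32 ms frame interval and 30-frame tracks,
0.5 s FRAP sampling over 100 s with 10 pre-bleach frames, a 16-step 2-fold
MST dilution from 10 µM against a 50 nM labelled partner.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon, box

from smquant.io import HeightMap, LocalizationTable, ParameterError, TrackSet


def _square_roi(side_nm: float = 5000.0) -> Polygon:
    return box(0.0, 0.0, side_nm, side_nm)


def _uniform_in_polygon(rng: np.random.Generator, roi: Polygon, n: int) -> np.ndarray:
    """Rejection-sample n uniform points from a polygon."""
    minx, miny, maxx, maxy = roi.bounds
    out = np.empty((0, 2))
    while len(out) < n:
        m = max(32, int(1.5 * (n - len(out)) * (maxx - minx) * (maxy - miny)
                        / max(roi.area, 1e-12)))
        cand = rng.uniform((minx, miny), (maxx, maxy), size=(m, 2))
        keep = shapely.contains_xy(roi, cand[:, 0], cand[:, 1])
        out = np.vstack([out, cand[keep]])
    return out[:n]


def simulate_csr(
    roi: Polygon,
    n: int,
    precision: float = 20.0,
    seed: int = 0,
) -> LocalizationTable:
    """Complete spatial randomness: n i.i.d. uniform points over ``roi``,
    each jittered by an isotropic Gaussian of SD ``precision`` (nm)."""
    if roi.area <= 0:
        raise ParameterError("roi has zero area")
    if n < 0:
        raise ParameterError("n must be >= 0")
    rng = np.random.default_rng(seed)
    pts = _uniform_in_polygon(rng, roi, n)
    pts = pts + rng.normal(0.0, precision, size=pts.shape)
    return LocalizationTable(
        xy=pts, precision=np.full(n, float(precision)), roi=roi
    )


@dataclass
class ClusterSceneParams:
    """Two-channel Thomas-type clustered scene.

    Cluster centres are uniform over the ROI; member counts are
    Poisson(``molecules_per_cluster``); members scatter as isotropic
    Gaussians of SD ``cluster_sd`` about their centre. A
    ``background_fraction`` of each channel's molecules is uniform over the
    ROI, and a ``coloc_fraction`` of channel B's centres is copied from
    channel A, giving a controllable colocalized structure.
    """

    roi: Polygon = field(default_factory=_square_roi)
    n_clusters: int = 50
    molecules_per_cluster: float = 44.0     # nuclear-cluster occupancy scale
    cluster_sd: float = 25.0                # nm
    background_fraction: float = 0.2
    precision_mean: float = 20.0            # nm
    precision_sd: float = 5.0               # nm
    coloc_fraction: float = 0.0
    seed: int = 0

    def validate(self) -> None:
        for name in ("background_fraction", "coloc_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ParameterError(f"{name} must be in [0, 1]")
        if self.n_clusters < 0 or self.molecules_per_cluster < 0:
            raise ParameterError("counts must be >= 0")
        if self.cluster_sd <= 0:
            raise ParameterError("cluster_sd must be > 0")


@dataclass
class ClusterSceneTruth:
    centres_a: np.ndarray        # (kA, 2) nm
    centres_b: np.ndarray        # (kB, 2) nm
    shared_centre_b: np.ndarray  # (kB,) bool: B centre copied from A
    labels_a: np.ndarray         # per-point cluster id, -1 = background
    labels_b: np.ndarray


def _one_channel(
    rng: np.random.Generator,
    p: ClusterSceneParams,
    centres: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    counts = rng.poisson(p.molecules_per_cluster, size=len(centres))
    pts = []
    labels = []
    for ci, (centre, cnt) in enumerate(zip(centres, counts)):
        members = centre + rng.normal(0.0, p.cluster_sd, size=(cnt, 2))
        pts.append(members)
        labels.append(np.full(cnt, ci))
    n_cluster_pts = int(counts.sum())
    # background_fraction of the TOTAL molecules is uniform background
    n_bg = (
        0 if p.background_fraction == 0
        else rng.poisson(
            n_cluster_pts * p.background_fraction / (1 - p.background_fraction)
        ) if p.background_fraction < 1 else rng.poisson(p.molecules_per_cluster * p.n_clusters)
    )
    pts.append(_uniform_in_polygon(rng, p.roi, n_bg))
    labels.append(np.full(n_bg, -1))
    xy = np.vstack(pts) if pts else np.empty((0, 2))
    return xy, np.concatenate(labels) if labels else np.empty(0, dtype=int)


def simulate_clustered_channels(
    params: ClusterSceneParams,
) -> tuple[LocalizationTable, LocalizationTable, ClusterSceneTruth]:
    """Generate two clustered channels with a shared-centre fraction."""
    params.validate()
    rng = np.random.default_rng(params.seed)
    centres_a = _uniform_in_polygon(rng, params.roi, params.n_clusters)
    n_shared = int(round(params.coloc_fraction * params.n_clusters))
    shared_idx = rng.choice(params.n_clusters, size=n_shared, replace=False) \
        if params.n_clusters else np.empty(0, dtype=int)
    centres_b = _uniform_in_polygon(rng, params.roi, params.n_clusters)
    shared_flag = np.zeros(params.n_clusters, dtype=bool)
    if n_shared:
        centres_b[:n_shared] = centres_a[shared_idx]
        shared_flag[:n_shared] = True

    xy_a, lab_a = _one_channel(rng, params, centres_a)
    xy_b, lab_b = _one_channel(rng, params, centres_b)

    def _precisions(n: int) -> np.ndarray:
        prec = rng.normal(params.precision_mean, params.precision_sd, size=n)
        while np.any(prec <= 0):   # truncate at 0
            bad = prec <= 0
            prec[bad] = rng.normal(params.precision_mean, params.precision_sd,
                                   size=bad.sum())
        return prec

    cha = LocalizationTable(xy=xy_a, precision=_precisions(len(xy_a)),
                            channel=0, roi=params.roi)
    chb = LocalizationTable(xy=xy_b, precision=_precisions(len(xy_b)),
                            channel=1, roi=params.roi)
    truth = ClusterSceneTruth(
        centres_a=centres_a, centres_b=centres_b,
        shared_centre_b=shared_flag, labels_a=lab_a, labels_b=lab_b,
    )
    return cha, chb, truth


@dataclass
class MobilityMixture:
    """Mixture of anomalous-diffusion components for track simulation.

    Each component is (fraction, D in µm²/s, alpha); fractions must sum to 1.
    Defaults follow the nuclear mobility composition this toolkit was built
    to quantify: a dominant static pool, a slow-moving pool and a small
    freely diffusing pool.
    """

    components: list[tuple[float, float, float]] = field(
        default_factory=lambda: [(0.55, 0.05, 0.7), (0.43, 0.32, 0.7), (0.02, 3.0, 1.0)]
    )
    n_tracks: int = 200
    track_length: int = 30       # frames
    dt: float = 0.032            # s, camera-limited frame interval
    loc_noise: float = 0.0       # µm, per-coordinate localization error
    seed: int = 0

    def validate(self) -> None:
        fr = np.array([c[0] for c in self.components])
        if not np.isclose(fr.sum(), 1.0):
            raise ParameterError("component fractions must sum to 1")
        for _, d, a in self.components:
            if d <= 0:
                raise ParameterError("D must be > 0")
            if not 0.0 < a <= 2.0:
                raise ParameterError("alpha must be in (0, 2]")


def _fbm_increment_chol(n_steps: int, alpha: float, var1: float) -> np.ndarray:
    """Cholesky factor of the stationary fractional-Gaussian-noise covariance.

    Increment autocovariance at lag k:
    γ(k) = var1/2 · ((k+1)^α − 2k^α + |k−1|^α), with γ(0) = var1, so partial
    sums have variance var1·n^α — the fractional-Brownian scaling.
    """
    k = np.arange(n_steps, dtype=float)
    gamma = 0.5 * var1 * ((k + 1) ** alpha - 2 * k ** alpha
                          + np.abs(k - 1) ** alpha)
    cov = gamma[np.abs(np.subtract.outer(np.arange(n_steps),
                                         np.arange(n_steps)))]
    return np.linalg.cholesky(cov + 1e-12 * var1 * np.eye(n_steps))


def simulate_tracks(mix: MobilityMixture) -> tuple[TrackSet, np.ndarray]:
    """Simulate 3D tracks with fractional Brownian increments.

    Per axis the position is fractional Brownian motion with
    Var(x(t)) = 2·D·t^α (Hurst index α/2), sampled exactly via the Cholesky
    factor of the stationary increment covariance; the ensemble MSD obeys
    MSD(t) = 6·D·t^α and, because the increments are stationary, the
    per-track time-averaged MSD shares the same t^α scaling — which a
    non-stationary independent-increment ("scaled Brownian") construction
    would not. Returns the TrackSet and per-track component indices.
    """
    mix.validate()
    rng = np.random.default_rng(mix.seed)
    fracs = np.array([c[0] for c in mix.components])
    comp = rng.choice(len(mix.components), size=mix.n_tracks, p=fracs)
    times = np.arange(mix.track_length) * mix.dt
    chols = {
        ci: _fbm_increment_chol(mix.track_length - 1, a, 2.0 * d * mix.dt ** a)
        for ci, (_, d, a) in enumerate(mix.components)
    }
    tracks = []
    for ci in comp:
        steps = chols[ci] @ rng.normal(0.0, 1.0, size=(mix.track_length - 1, 3))
        pos = np.vstack([np.zeros(3), np.cumsum(steps, axis=0)])
        if mix.loc_noise > 0:
            pos = pos + rng.normal(0.0, mix.loc_noise, size=pos.shape)
        tracks.append(np.column_stack([times, pos]))
    ts = TrackSet(tracks=tracks, dt=mix.dt)
    return ts, comp


@dataclass
class FRAPTrace:
    """Raw FRAP time series: bleach ROI, reference ROI and background,
    in arbitrary intensity units, with ``bleach_index`` the first
    post-bleach frame."""

    t: np.ndarray
    bleach_roi: np.ndarray
    reference_roi: np.ndarray
    background: np.ndarray
    bleach_index: int

    def __post_init__(self) -> None:
        for name in ("t", "bleach_roi", "reference_roi", "background"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        if self.bleach_index < 1:
            raise ParameterError("need at least one pre-bleach frame")
        if not all(np.all(np.isfinite(getattr(self, n)))
                   for n in ("t", "bleach_roi", "reference_roi", "background")):
            raise ParameterError("intensities must be finite")


def simulate_frap(
    t_half: float = 7.5,
    mobile_fraction: float = 0.65,
    n_pre: int = 10,
    duration: float = 100.0,
    dt: float = 0.5,
    noise_sd: float = 0.02,
    seed: int = 0,
    acq_bleach_rate: float = 0.0,
    scale: float = 1000.0,
    background: float = 50.0,
) -> FRAPTrace:
    """Simulate a FRAP acquisition under the full-scale convention.

    The underlying normalized signal is 1 before the bleach and
    ``mobile_fraction·(1 − 2^(−t/t_half))`` after it (bleach floor 0).
    Gaussian noise of SD ``noise_sd`` is added on the normalized scale; the
    trace is then emitted in arbitrary units with a constant background and
    an optional exponential acquisition-bleaching decay applied to both the
    bleach and reference ROIs (rate per frame).
    """
    if t_half <= 0:
        raise ParameterError("t_half must be > 0")
    if not 0.0 <= mobile_fraction <= 1.0:
        raise ParameterError("mobile_fraction must be in [0, 1]")
    if dt <= 0:
        raise ParameterError("dt must be > 0")
    rng = np.random.default_rng(seed)
    n_post = int(round(duration / dt))
    t = np.arange(n_pre + n_post) * dt
    t_post = t[n_pre:] - t[n_pre]
    ideal = np.concatenate([
        np.ones(n_pre),
        mobile_fraction * (1.0 - 2.0 ** (-t_post / t_half)),
    ])
    noisy = ideal + rng.normal(0.0, noise_sd, size=ideal.shape)
    decay = (1.0 - acq_bleach_rate) ** np.arange(len(t))
    return FRAPTrace(
        t=t,
        bleach_roi=background + scale * noisy * decay,
        reference_roi=background + scale * decay,
        background=np.full(len(t), background),
        bleach_index=n_pre,
    )


@dataclass
class TitrationCurve:
    """Signal vs total titrant concentration at a fixed partner concentration.

    Concentrations in µM; signal in arbitrary units.
    """

    titrant_total: np.ndarray
    signal: np.ndarray
    fixed_partner: float

    def __post_init__(self) -> None:
        self.titrant_total = np.asarray(self.titrant_total, dtype=float)
        self.signal = np.asarray(self.signal, dtype=float)
        if self.titrant_total.shape != self.signal.shape:
            raise ParameterError("titrant and signal must have the same length")
        if np.any(np.diff(self.titrant_total) <= 0):
            raise ParameterError("titrant concentrations must be strictly increasing")


def mst_dilution_series(top: float = 10.0, n_steps: int = 16) -> np.ndarray:
    """A 2-fold serial dilution from ``top`` µM, ascending (n_steps points)."""
    return top / 2.0 ** np.arange(n_steps)[::-1]


def simulate_titration(
    kd: float,
    design: np.ndarray | None = None,
    fixed_partner: float = 0.05,
    f_free: float = 1.0,
    f_bound: float = 2.0,
    model: str = "eq1",
    a: float | None = None,
    b: float | None = None,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> TitrationCurve:
    """Simulate a titration under the quadratic tight-binding isotherm.

    ``model='eq1'`` gives signal = f_free + (f_bound−f_free)·[PD]/partner;
    ``'eq2'`` adds the linear term a + b·partner (requires a, b).
    """
    from smquant.binding import eq1_bound

    if kd <= 0:
        raise ParameterError("kd must be > 0")
    if design is None:
        design = mst_dilution_series()
    design = np.asarray(design, dtype=float)
    if np.any(design <= 0):
        raise ParameterError("concentrations must be > 0")
    if model == "eq2" and (a is None or b is None):
        raise ParameterError("model eq2 requires a and b")
    rng = np.random.default_rng(seed)
    bound = eq1_bound(design, fixed_partner, kd)
    signal = f_free + (f_bound - f_free) * bound / fixed_partner
    if model == "eq2":
        signal = signal + a + b * fixed_partner
    if noise_sd > 0:
        signal = signal + rng.normal(0.0, noise_sd, size=signal.shape)
    return TitrationCurve(titrant_total=design, signal=signal,
                          fixed_partner=fixed_partner)


@dataclass
class AFMSceneTruth:
    polyline: np.ndarray          # (m, 2) nm, the DNA backbone
    contour_length: float         # nm
    blob_positions: np.ndarray    # fractions along the contour
    blob_xy: np.ndarray           # (k, 2) nm


def _wlc_polyline(
    rng: np.random.Generator,
    length: float,
    persistence: float,
    step: float,
) -> np.ndarray:
    """Discrete 2D worm-like chain: tangent-angle Gaussian increments with
    variance step/persistence_length per step."""
    n_full = int(length // step)
    rem = length - n_full * step
    angles = np.cumsum(
        np.concatenate([
            [rng.uniform(0.0, 2.0 * np.pi)],
            rng.normal(0.0, np.sqrt(step / persistence), size=n_full - 1 + (rem > 0)),
        ])
    )
    steps = np.full(len(angles), step)
    if rem > 0:
        steps[-1] = rem
    seg = np.column_stack([np.cos(angles), np.sin(angles)]) * steps[:, None]
    return np.vstack([np.zeros(2), np.cumsum(seg, axis=0)])


def simulate_afm_scene(
    map_size: int = 256,
    pixel_size: float = 2.0,
    dna_length: float = 115.0,        # nm; ~339 bp at 0.34 nm/bp
    persistence_length: float = 50.0, # nm, canonical dsDNA
    dna_height: float = 2.0,          # nm
    blob_positions: np.ndarray | list[float] = (),
    blob_height: float = 4.0,
    blob_sd: float = 6.0,             # nm
    noise_sd: float = 0.1,            # nm
    seed: int = 0,
    max_retries: int = 50,
) -> tuple[HeightMap, AFMSceneTruth]:
    """Render a worm-like-chain DNA contour plus globular blobs on a flat map.

    The chain is rendered as a ridge of height ``dna_height`` about 2 px
    wide; Gaussian blobs of amplitude ``blob_height`` and SD ``blob_sd`` are
    placed at the requested contour fractions. Ground truth carries the
    backbone polyline and the blob contour positions.
    """
    if dna_length <= 0 or persistence_length <= 0:
        raise ParameterError("dna_length and persistence_length must be > 0")
    rng = np.random.default_rng(seed)
    extent = map_size * pixel_size
    margin = 4 * pixel_size + 3 * blob_sd
    step = max(pixel_size / 2.0, 0.5)
    for _ in range(max_retries):
        poly = _wlc_polyline(rng, dna_length, persistence_length, step)
        centre = np.array([extent / 2.0, extent / 2.0])
        poly = poly - poly.mean(axis=0) + centre
        if (poly.min() >= margin) and (poly.max() <= extent - margin):
            break
    else:
        raise RuntimeError(
            "DNA chain escaped the map after retries; use a larger map_size"
        )

    heights = np.zeros((map_size, map_size))
    yy, xx = np.mgrid[0:map_size, 0:map_size]
    px_centres = np.stack([(xx + 0.5) * pixel_size, (yy + 0.5) * pixel_size], axis=-1)

    # ridge: pixels within ~1 px of the densely sampled backbone
    seg_len = np.linalg.norm(np.diff(poly, axis=0), axis=1)
    arc = np.concatenate([[0.0], np.cumsum(seg_len)])
    dense_s = np.arange(0.0, arc[-1], pixel_size / 4.0)
    dense = np.column_stack([
        np.interp(dense_s, arc, poly[:, 0]),
        np.interp(dense_s, arc, poly[:, 1]),
    ])
    for pt in dense:
        dist2 = np.sum((px_centres - pt) ** 2, axis=-1)
        heights = np.maximum(heights, dna_height * (dist2 <= pixel_size ** 2))

    blob_positions = np.asarray(blob_positions, dtype=float)
    blob_xy = np.column_stack([
        np.interp(blob_positions * arc[-1], arc, poly[:, 0]),
        np.interp(blob_positions * arc[-1], arc, poly[:, 1]),
    ]) if len(blob_positions) else np.empty((0, 2))
    for bxy in blob_xy:
        dist2 = np.sum((px_centres - bxy) ** 2, axis=-1)
        heights = np.maximum(heights, blob_height * np.exp(-dist2 / (2 * blob_sd ** 2)))

    if noise_sd > 0:
        heights = heights + rng.normal(0.0, noise_sd, size=heights.shape)
    truth = AFMSceneTruth(
        polyline=poly, contour_length=float(arc[-1]),
        blob_positions=blob_positions, blob_xy=blob_xy,
    )
    return HeightMap(heights=heights, pixel_size=pixel_size), truth
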