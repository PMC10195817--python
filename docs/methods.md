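# Methods

This note documents the models and conventions behind each `smquant`
module, the defaults and why they were chosen, what the synthetic-data
generators do and do not emulate, and the numerical choices that make the
outputs deterministic.

## Units and containers

SMLM localization tables and AFM height maps are held in nanometres;
trajectories in micrometres and seconds. Readers convert at the boundary
(`units="um"` multiplies by 1000). ROI polygons are closed, in nm;
point-in-polygon uses the even–odd rule with boundary points counted
inside. Localization CSV headers are resolved through a case-insensitive
registry (`x`, `x_nm`, `x [nm]`, …) because exporter schemas vary; an
explicit dialect mapping overrides the registry.

## Ripley's K and DBSCAN

The linearised Ripley estimator is
K(r) = A · Σᵢ Nᵢ(r) / (n_c·(n−1)), with centres restricted to points at
least max(r) from the ROI boundary (guard-band edge handling) while all
points count as neighbours; L(r) − r = √(K/π) − r has expectation 0 under
complete spatial randomness. Guard-band exclusion was chosen over analytic
isotropic corrections because it stays unbiased for arbitrary (free-hand)
polygonal ROIs. The maximum radius is capped at 25% of the ROI's smaller
extent.

DBSCAN counts the point itself toward `min_pts` (default 5); ε defaults
to the mean of the table's precision column, falling back to 20 nm
(far-red dye) with a 30 nm constant provided for green dyes. Labels are
deterministic: clusters are numbered by their first core point's row
index, and a border point reachable from several clusters joins the
lowest label (the BFS claims it first). Cluster area is the convex hull
of member coordinates; a density-contour ("smoothing") outline used by
some cluster software would give systematically different areas, so the
smoothing value is carried in `ClusterParams` for provenance but unused.
Collinear clusters get area 0 and are excluded from area means (counted
in `n_degenerate_clusters`).

## DoC colocalization

For each point, own- and other-channel neighbour counts N(r) at `n_radii`
linearly spaced radii up to `r_max` (defaults 10 and 500 nm) form density
gradients N(r)/r², each normalized by its value at r_max; the per-point
score is their Spearman correlation multiplied by exp(−d/r_max), where d
is the nearest other-channel distance. Points with no own-channel
neighbour at r_max score 0 (and are counted); a constant gradient series
also yields 0 — both are deterministic conventions for degenerate local
geometry. Spearman is computed by rank transform plus row-wise Pearson,
asserted against `scipy.stats.spearmanr` in tests. The colocalization
threshold is 0.4; a cluster is colocalized when ≥ `min_coloc_points`
(default 5, matching `min_pts`) of its members reach the threshold.
Because scores depend only on each point's neighbourhoods, analysing a
dense nucleus in tiles is equivalent to a single pass as long as the full
dataset remains the neighbour source, which is what the implementation
does.

## Tracking

Per-track time-averaged MSD uses all ordered pairs at each lag up to
`max_lag_fraction` (default 0.5) of the track. The anomalous fit is
ordinary least squares of log MSD = log(2·dims·D) + α·log t over the
first `max_fit_lags` lags (default 4; short-lag fitting limits the bias
from anomalous curvature on 10–30-frame tracks). The dimensional
prefactor defaults to 3D (6D·t^α), since multi-focal acquisition yields
3D tracks; `dims=2` reanalysis and a linear fixed-α=1 fit are exposed.
Mobility classes cut at D = 0.1 and 1 µm²/s, with boundary values
assigned to "slow" because the outer-class inequalities are strict. No
localization-noise offset is subtracted by default.

### Track generator

Tracks are fractional Brownian motion per axis with Var x(t) = 2·D·t^α
(Hurst α/2), sampled exactly by Cholesky factorisation of the stationary
fractional-Gaussian-noise covariance. A non-stationary "scaled Brownian"
construction (independent increments of variance 2DΔ(t^α)) reproduces the
same ensemble MSD but not the time-averaged MSD of individual tracks —
its TA-MSD grows linearly in lag regardless of α, so per-track fits would
return α ≈ 1. Since every analysis here is per-track and time-averaged,
the fBm construction is the one consistent with the quantities being
fitted. The default mixture is 55% static (D = 0.05 µm²/s), 43% slow
(D = 0.32, roughly the geometric centre of the 0.1–1 band) and 2% diffuse
(D = 3.0), α = 0.7 for the confined pools and 1.0 for the diffuse pool,
30 frames at dt = 32 ms, no localization noise unless requested.

### Study sizes

The D/α recovery study uses 200 tracks × 30 frames (noiseless). The
composition-recovery study uses 1000 tracks × 100 frames: per-track D
estimates from very short tracks scatter across the hard 0.1 µm²/s
threshold (≈8% of the static pool at 30 frames, a property of
thresholding noisy estimators, not of the mixture), while the
acquisitions this emulates run for tens of seconds at 32 ms per frame, so
100-frame tracks are the more representative population and keep
class-leakage below ~2%.

## FRAP

Normalization follows the double + full-scale convention: background
subtraction, reference correction by ref_pre/ref(t), division by the
pre-bleach mean, then anchoring so the bleach frame is exactly 0 and the
pre-bleach plateau 1. Under this convention the fitted plateau of
M·(1 − e^(−kt)) is directly the mobile fraction (an end-value formula is
not used) and t½ = ln 2/k. Initial guesses are M = final-quartile mean
and k from the linearly interpolated half-rise time; fits outside [0, 1]
in M are clipped with a warning; non-convergence returns a failure flag
rather than raising. The simulator emits the same convention
(post-bleach signal M·(1 − 2^(−t/t½)), floor 0) wrapped in arbitrary
units with a constant background and optional exponential acquisition
bleaching on both ROIs; the default acquisition is 10 pre-bleach frames,
100 s of recovery at 0.5 s sampling.

## Binding

`eq1_bound` is the quadratic tight-binding solution; the root is
evaluated as 2·P·D/((P+D+K_d) + √disc) to avoid catastrophic cancellation
at tight binding, and is clamped to [0, min(P, D)]. The eq2 variant adds
a linear baseline on the signal scale; with the partner fixed the printed
per-partner linear term is a constant and therefore degenerate with the
offset, so the fit folds them into one parameter, while a
`linear_in="titrant"` variant (useful for non-saturating tails) fits a
genuine slope — in that case the free-signal level and the offset remain
jointly one constant, and only their sum is identifiable. Fits are
unweighted nonlinear least squares over (K_d, f_free, f_bound[, a, b])
with the K_d standard error from the covariance; a K_d outside the design
range is flagged ill-conditioned. Replicates are fitted individually
(mean ± SEM reported) and pooled. Self-association titrations reuse the
hetero-association quadratic with the fixed labelled species (50 nM by
default) in the partner role; higher-order oligomer equilibria are not
modelled. Concentrations are µM throughout.

## AFM

Masking: Gaussian smoothing of σ = 1.5 px, then threshold at
mean + k·SD of the full smoothed map (σ here is the SD of the flattened
image's height distribution); grains are 4-connected components.
Filtering order: border-touching grains, then area < 50 nm², then an
optional multiple-of-median-area window; drops are counted per rule.
Bounding sizes are caliper widths of the convex hull of the mask pixels'
physical corners (min via rotating calipers over hull edges, max as the
hull diameter); the corner convention means a w×h pixel block measures
exactly w and √(w²+h²) at 1 nm/px, and a single pixel reports
pixel_size for both bounds. KDE modes use a Gaussian kernel with
Silverman bandwidth on a 512-point grid spanning the data, ties breaking
toward the lower value, reported with the sample SD. Binding positions
project a site onto the traced backbone polyline and report arc distance
to the nearer end as a percentage of contour length (0–50%); "edge"
covers the outer 25% at each end (half the molecule), boundary values
going to "middle", and sites beyond a 20 nm capture radius are
unassigned. Compaction comparisons use shared-bin normalized histograms,
their overlap area, medians and a Mann–Whitney rank-sum test, with the
shift sign taken from the median difference.

The AFM scene generator renders a discrete 2D worm-like chain
(tangent-angle increments of variance step/persistence_length; default
persistence 50 nm, contour 115 nm ≈ 339 bp at 0.34 nm/bp) as a ~2 px
ridge, with Gaussian blobs at requested contour fractions and white
background noise. Image flattening of raw AFM data is out of scope;
inputs are assumed flattened.

## Synthetic scenes and what they do not capture

The clustered-scene generator is a Thomas process (uniform cluster
centres, Poisson occupancy, Gaussian member scatter, defaults 44
molecules/cluster, 25 nm scatter, 20% uniform background, precision
~N(20, 5) nm truncated positive), with a `coloc_fraction` of channel-B
centres copied from channel A. It emulates clustered nuclear point
patterns, not SMLM photophysics: no blinking-induced repeat
localizations, no frame structure, no drift, no detector noise. Passing
recovery tests therefore demonstrates correctness of the spatial
statistics, not robustness to over-counting artefacts — real data should
be blink-corrected upstream. Likewise the track generator has no
motion blur or tracking errors, the FRAP generator no diffusion-limited
bleach-spot geometry, and the AFM renderer no tip convolution.

## Determinism and tolerances

Every generator takes a seed and is a pure function of it. Analysis
stages contain no randomness. Oracle-equivalence tests compare against
independent brute-force implementations at 1e−10 to 1e−12 relative
tolerance (exact algorithms) or the oracle's own grid resolution
(exhaustive-rotation calipers at 0.1°). `curve_fit` failures surface as
flags, never silent NaNs, so batch summaries can report exclusion counts.
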