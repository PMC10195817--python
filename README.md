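# smquant

Quantitative analysis of single-molecule microscopy and biophysics data,
built for studies of nuclear protein organisation and dynamics — the kind
of combined campaign in which one protein is characterised by
super-resolution localization microscopy (STORM), 3D single-particle
tracking, FRAP, titration binding assays and atomic force microscopy.
`smquant` implements each quantitative stage as a tested library module,
plus synthetic-data generators with ground truth so every stage can be
validated end-to-end without raw instrument data.

## What it computes

- **SMLM cluster analysis** (`smquant.cluster`): the linearised Ripley's K
  statistic L(r) − r (0 under complete spatial randomness, > 0 under
  clustering), DBSCAN cluster maps using the mean localization precision as
  the neighbourhood radius ε with a minimum occupancy of 5 molecules, and
  per-cluster morphometrics (convex-hull area, density, % of molecules
  clustered).
- **Coordinate-based colocalization** (`smquant.coloc`): a per-localization
  degree-of-colocalization (DoC) score in [−1, 1] from the Spearman rank
  correlation of the two channels' local density gradients N(r)/r² across
  radii, damped by exp(−d/r_max) with d the nearest other-channel distance;
  clusters are split into colocalized/non-colocalized at a 0.4 score
  threshold.
- **Single-particle tracking** (`smquant.tracking`): per-track time-averaged
  MSD, anomalous-diffusion fits MSD(t) = 2·dims·D·t^α on the first lags,
  and mobility classes static (D < 0.1 µm²/s), slow (0.1 ≤ D ≤ 1) and
  diffuse (D > 1).
- **FRAP** (`smquant.frap`): double + full-scale normalization and a
  single-exponential recovery fit I(t) = M·(1 − e^(−kt)), giving
  t½ = ln 2/k and mobile fraction M.
- **Binding isotherms** (`smquant.binding`): the quadratic tight-binding
  solution [PD] = ((P+D+K_d) − √((P+D+K_d)² − 4PD))/2 with a numerically
  stable root, an optional linear-baseline variant, and nonlinear
  least-squares K_d fitting with replicate pooling.
- **AFM morphometrics** (`smquant.afm`): σ-multiplier grain masking,
  border/size/median filters, rotating-calipers min/max bounding sizes,
  KDE population modes, DNA-end binding-position preference and
  compaction statistics.
- **Synthetic data** (`smquant.simulate`): Thomas-type clustered
  two-channel scenes with a controllable colocalized fraction, fractional-
  Brownian track mixtures with MSD ∝ t^α, FRAP traces, quadratic-isotherm
  titrations and worm-like-chain DNA + protein AFM scenes — all pure
  functions of their parameters and a seed, returning ground truth.

## Worked example

```sh
python examples/cluster_analysis.py
```

```
simulated 2749 localizations in a 5x5 um nuclear ROI
max L(r)-r = 237.6 nm at r = 80 nm
  (zero means random; a positive peak means clustering at that scale)
DBSCAN: 51 clusters, 74.7% of molecules clustered
mean cluster area 5568 nm^2, 40.3 molecules per cluster
```

The Ripley curve peaking well above zero at ~80 nm says the molecules are
clustered at roughly that length scale rather than randomly scattered; the
DBSCAN summary then quantifies the clusters themselves — here the scene was
generated with 50 clusters of ~44 molecules each plus 20% background, and
the analysis recovers that structure. The other scripts in `examples/`
cover colocalization, tracking, FRAP, K_d fitting and AFM morphometrics the
same way, and a thin CLI (`smquant simulate|cluster|coloc|tracks|frap|
binding|afm`) exposes the same pipelines on CSV/TIFF files.

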