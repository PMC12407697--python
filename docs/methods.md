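# Methods

This note documents the models, parameter choices and numerical decisions
behind `lamodc`, and what the synthetic validation does and does not
establish about real laminar fMRI data.

## Forward model of a mapping run

A run is a block design: 15 s baseline, eight 30 s monocular stimulation
blocks (four per eye, pseudorandomized), 15 s baseline — 270 s at TR 3 s,
i.e. 90 volumes.  Neural drive is a boxcar per condition convolved with the
canonical double-gamma HRF (peak delay 6 s, undershoot delay 16 s, unit
dispersions, undershoot ratio 6, 32 s kernel).  Both regressors are jointly
normalized to peak 1 on a 0.1 s grid, so amplitude parameters read as peak
fractional signal changes.  An alternate CBV-like kernel (faster
time-to-peak, no undershoot) is available but off by default; it exists as a
control because the CBV response evolves differently in time than BOLD.

The signal at vertex `v`, depth fraction `d` (0 = GM/WM, 1 = pial; 11 levels
at 0.0, 0.1, …, 1.0), time `t`:

```
S = 100 · (1 + a(d) · p_d(v) · (r_L − r_R)(t) + b(d, v) · (r_L + r_R)(t)) + ε
```

- `p_d` is the columnar preference map smoothed with a depth-specific
  Gaussian point spread.  The map itself is band-pass-filtered Gaussian
  white noise (Gaussian annulus centred at 1/period, relative width 0.25,
  optional anisotropy) passed through `tanh(gain·x)`; preference is
  identically zero outside V1.  This is the standard generative model for
  irregular columnar patterns and is parameterized to the ~1 mm period of
  human ODCs.
- `a(d)` is the contrast-specific amplitude: `a0·(1 + s·d)` for BOLD-like
  contrasts (linear gain toward the pial surface, the draining-vein
  signature) and a Gaussian bump `a0·(exp(−(d−μ)²/2w²) + s·d)` for
  VASO-like CBV weighting (peak within grey matter plus a small pial trend).
- `b(d, v)` is an eye-symmetric coarse venous bias: the rectified preference
  map smoothed at 3 mm, scaled by `venous_bias_amp·d`.  Because it loads
  equally on both condition regressors it cannot carry eye information —
  the left-minus-right GLM contrast is exactly invariant to it (asserted in
  tests).
- `ε` is AR(1) Gaussian noise (coefficient 0.3) whose stationary SD
  interpolates linearly from deep to pial, reflecting higher superficial
  variability (CSF pulsatility).  The baseline is fixed at 100 a.u. so
  percent signal change is scale-free.

VASO runs produce volume pairs at an effective pair TR of 5 s (54 pairs per
270 s run), not-nulled volumes offset by half the pair TR:
`not_nulled = 100·(1+bold)`, `nulled = 100·(1+bold)·(1−cbv)`, with `cbv` the
CBV-weighted columnar response and `bold` a shared eye-unspecific
contamination term growing toward the pial surface (default 5% peak).  An
`aligned_timestamps` option samples both series at the same times; the exact
round-trip check uses it because with interleaved timestamps no common-grid
point is a sample time of both series, so division exactness is only defined
on aligned grids.

### Default acquisition parameters

| parameter | GE | SE | VASO | meaning |
|---|---|---|---|---|
| amplitude_base | 0.006 | 0.004 | 0.007 | peak fractional ocular response at depth 0 |
| pial_slope | 4.0 | 2.5 | 0.2 | linear depth gain (VASO: small pial trend) |
| mid_peak_depth / width | – | – | 0.4 / 0.22 | CBV amplitude bump |
| psf FWHM deep→pial (mm) | 0.40→0.45 | 0.30→0.40 | 0.30→0.35 | vascular point spread |
| venous_bias_amp | 0.010 | 0.005 | 0.002 | coarse depth-scaled bias |
| noise SD deep→pial (a.u.) | 6→7 | 6.5→7.5 | 8→9 | temporal noise on a 100 a.u. baseline |
| tr_s | 3 | 3 | 5 (pair) | volume / pair repetition time |

These were calibrated once, by signal-detection arithmetic, so that the
composed pipeline lands in the empirically reported regimes for this kind of
experiment — GE decoding accuracy rising from roughly 0.6 deep to 0.85+
pial without ceiling saturation, SE intermediate, VASO near 0.5–0.6 with a
peak below mid-depth when features are selected at the GM/WM surface — and
then frozen.  The magnitude of the coarse venous bias is a free parameter;
no quantitative measurement of it exists to calibrate against.  Point-spread
values describe the *additional* blur of the sampled columnar pattern, not
the full physiological PSF; with a 1 mm pattern period, FWHM values near the
period would annihilate the pattern entirely.

## Analysis stages

- **BOLD correction**: nulled and not-nulled series are linearly
  interpolated onto the grid {0, TR, 2·TR, …} spanning the run (edge volumes
  held), then divided.  Linear interpolation is exact for drifts and matches
  common practice; the grid origin is the run start.  Denominator magnitudes
  below `guard_eps` times the voxel's temporal mean flag the voxel invalid
  rather than clamping the ratio — clamping would silently bias decoding
  features.  The corrected ratio keeps the raw sign (decreases when CBV
  increases); reporting code inverts it.
- **High-pass filter**: regression against the discrete-cosine basis
  functions with periods longer than the cutoff period (order
  `⌊2·duration·cutoff⌋`), re-adding the temporal mean.  A projection, hence
  exactly idempotent.
- **GLM**: OLS with HRF-convolved left/right regressors and per-run
  constants pooled across a session's runs (fixed effects).  z is the
  contrast over its standard error (Gaussian approximation — the z-maps feed
  rank correlations, not thresholded inference); PSC_c =
  100·β_c·max(regressor_c)/β_constant.  Residual variances at machine
  precision (noiseless constructions) report z = 0.
- **Time-point selection**: volumes whose acquisition window lies inside a
  stimulation block, minus the first two volumes of each block (hemodynamic
  transients).  For the default design: 64 retained per run, 32 per eye, 576
  training samples per leave-one-run-out fold with 10 runs.
- **Layering / sampling**: equidistant is taken literally — equal Euclidean
  spacing along the straight inner→outer segment per vertex (no equivolume
  correction).  Surface sampling is trilinear in a shared mm world frame
  (0-based voxel indices, header affine); vertices outside the volume return
  NaN and are excluded by the shared field-of-view mask.
- **Decoding**: ANOVA F per vertex on training folds (own implementation:
  infinite F for zero within-class variance with distinct means, sorted
  first; ties broken by ascending vertex index for determinism), top-k
  selection (default 200, on depth-averaged training data so one vertex set
  serves all depths; at-depth and per-depth variants available),
  z-scoring per feature with training statistics, linear hinge-loss SVM with
  C = 1 and a fitted intercept.  The SVM is solved with liblinear's dual
  coordinate descent (tolerance 1e-4, 1000 iterations cap, weakly penalized
  intercept): it minimizes the identical objective as libsvm, agrees with a
  quadratic-programming oracle to weight-direction cosine > 0.9999 on toy
  problems, and is an order of magnitude faster on near-chance folds, which
  dominate permutation calibration.  Feature-count sweeps rank once per fold
  and truncate per k (equivalent for a fixed ranking).
- **Statistics**: Spearman (mid-ranks) between session z-maps at mid-depth;
  the permutation null shuffles the second map's values across one random
  10% vertex subset drawn once per analysis (spatial dependence makes
  full-map permutations anti-conservative; the subset is fixed across
  permutations).  Exceedance is two-sided (|ρ_null| ≥ |ρ_obs|).  The finite
  null size (n = 10,000) is absorbed by a binomial 3σ upper bound
  `p = (k + 3·sqrt(n·p̂(1−p̂)))/n` with p̂ = k/n; k = 0 is floored at 1/n
  because a permutation p of zero is not reportable.  Depth profiles are
  summarized per depth by the mean across participants (each entering with
  the mean of their sessions — the participant is the resampling unit), a
  percentile bootstrap 95% CI (n = 1,000), a one-sided bootstrap test
  against chance (fraction of bootstrap means ≤ chance, floored at
  1/n_boot), and Benjamini–Hochberg FDR across the 11 depths.
- **Pipeline PSC profile**: the generator drives left- and right-preferring
  vertices antisymmetrically, so a raw per-condition PSC would cancel over a
  signed columnar pattern.  The reported profile is the ocular response
  magnitude: (PSC_L − PSC_R)/2 signed by each vertex's own session contrast,
  averaged over the selected vertices.

## What the synthetic validation shows — and what it does not

Passing tests establish that the analysis machinery is correct: exact BOLD
removal on multiplicative constructions, GLM amplitude recovery to <0.1% on
noiseless runs, phase recovery after opposite-direction averaging to <1e-3
rad, no train/test leakage, chance-level behaviour under label permutations,
calibrated permutation p-values and bootstrap coverage, and qualitative
depth-profile behaviour (GE profiles rising toward the pial surface; a
sub-mid-depth VASO peak under deep-layer feature selection) *given the vein
model that produces them*.  They do not validate the vein model itself
against physiology: the generator has no explicit vessel graph, no motion or
distortion, spatially independent noise (real noise is spatially
correlated, which makes synthetic decoding easier at matched SNR), no
eye-luminance/color confound, and no retinotopic variation in column width.
Conclusions about real data require the real data.

## Problem sizes

Simulation-backed tests run on reduced problem sizes chosen to keep each
statistical property intact: 48–54-vertex-wide patches (~600 V1 vertices,
100 features) for decoding checks, 24 GE sessions of 8 runs for the
monotonicity property, 12 VASO sessions of 6 runs for the deep-selection
peak, 200 replicates for permutation calibration and 400 for bootstrap
coverage.  The acceptance script's chance-level calibration uses the full
default geometry (100×100 vertices, 2000 in V1, 10 runs, 200 features, 20
permutation repetitions).
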