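# Methods

This note documents the models, defaults and design choices behind
`phenospectra`: what the synthetic generator emulates, how each analysis
stage is specified numerically, and what the passing tests do and do not
demonstrate about real field data.

## The statistical model

A plot-level phenotype (a latent canopy trait, grain yield, or a spectral
index) is modelled with independent Gaussian random effects,

    y_ijkl = mu + G_i + E_j + (GE)_ij + rep_jk + block_jkl + eps_ijkl,

with variances σ²G, σ²E, σ²GE, σ²rep, σ²block, σ²ε. Broad-sense
heritability on an entry-mean basis over `x` environments and `r`
replications is

    H² = σ²G / (σ²G + σ²GE/x + σ²ε/(x·r)).

σ²E is a nuisance parameter: it is estimated (environment is a random term)
but does not enter H². With nonnegative component estimates H² lies in
[0, 1] without clamping.

### REML estimation

The restricted likelihood is evaluated through the low-rank structure of
V = σ²ε·I + U·D·U′, where U stacks the 0/1 indicator matrices of all random
terms and D holds their variances. Using the Woodbury identity, one
evaluation costs a single q×q Cholesky factorization (q = total number of
effect levels, typically ≲ 1000), so trials with thousands of plots fit in
seconds. The optimizer is L-BFGS-B over log-variances (bounds 1e-10 to 1e4
times the phenotypic variance, relative likelihood tolerance 1e-8, maximum
500 iterations), warm-started from the expected-mean-squares estimates when
the design is balanced, with a Nelder-Mead fallback; components below
1e-8 × var(y) are floored to zero. Non-convergence of both optimizers
raises an error carrying the traces.

Model terms absent from a design are dropped automatically: one environment
collapses G×E into error (with a warning), one replicate drops the
replicate term, and blocks identical to replicates drop the block term. In
unreplicated augmented trials the repeated checks identify σ²G; the `r`
used in H² is then a convention the caller chooses (`r=1` by default, the
conservative reading for pooled replicated/unreplicated populations — the
pipeline exposes both via `r_convention`).

The `anova_moments` method implements the classical expected-mean-squares
estimator for balanced genotype × environment × replicate layouts:
σ̂²ε = MS_err, σ̂²GE = (MS_GE − MS_err)/r, σ̂²G = (MS_G − MS_GE)/(x·r),
floored at zero. On balanced data REML and moments agree within 2% (a test
asserts this), which makes the moments estimator a useful independent
cross-check of the REML machinery; an external mixed-model fit (R lme4) is
used as a second oracle in the test suite on a small fixture.

### Adjusted entry means

Per environment, a fixed-genotype companion model with sum-to-zero
replicate and block contrasts is fitted by OLS; the genotype coefficients
are the adjusted means (BLUEs). Environments are averaged afterwards. On a
balanced design without block effects this reduces exactly to raw genotype
means.

## Calibration

`SR = DN·m + b` per band. The multi-panel fit regresses true panel
reflectance on observed DN (ordinary least squares, ≥ 2 distinct panels),
so it inverts any affine sensor transfer exactly in the noiseless limit.
The single-panel fit is a ratio through the origin (`b = 0`); a sensor
offset therefore survives as a reflectance-dependent bias — the mechanistic
reason multi-panel calibration yields cleaner data, and a property the
tests assert in closed form. The ± in the line's printed form is read as a
free-signed intercept. Calibrated reflectance is clipped to [0, 1.2]
(above 1 to tolerate specular returns) with clip counts reported.

NIR derivation uses `NIR = 2.921·Blue − 0.754·Red`, floored at zero with a
warning count. The subsequent normalization "with a coefficient of 3.07" is
implemented as division (the coefficient plays the role of the summed
quantum-efficiency weight); the operation and the coefficients are
configurable. The derivation only works on cameras whose blue/red channels
leak NIR, so the 2018-era UAS preset simulates its channels as spectral
mixtures (blue = 0.05·R450 + 0.95·R800, red = 0.95·R680 + 0.05·R800),
under which the printed coefficients approximately reconstruct the 800 nm
reflectance. With pure visible channels the derived band would be noise —
an instructive failure mode, but not how the real sensor works.

## Spectral processing

- **QC** of hyperspectral curves below 1000 nm flags: reflectance < −0.01,
  reflectance > 1.2, red-edge inversion (mean on [760, 800] nm below mean
  on [660, 690] nm), or an adjacent-sample jump > 0.3. "Abnormal" has no
  published definition, so each rule is independently switchable and these
  defaults are the package's own.
- **Broadband synthesis** averages narrowband samples in a left-closed
  half-open window `[c − w/2, c + w/2)`, default width 50 nm — the
  half-open convention partitions a sampling grid unambiguously.
- **SD normalization** divides each plot value by the sample (n−1) standard
  deviation of its trial × band group. Note that with *per-band* SDs the
  ratio-form indices are **not** invariant to the normalization; for
  TCARI/MTVI (not scale-invariant at all) index values computed from
  normalized bands lose their physical meaning and, in the emulation,
  essentially all heritability. The pipeline follows the
  normalize-then-index order by default and exposes
  `sri_from_normalized: false` for the physically interpretable variant;
  this sensitivity is a finding the package surfaces, not a bug.
- **Soil masking** thresholds NDVI at 0.3 (configurable; canopy closure
  varies by growth stage). The synthetic soil spectrum (0.13–0.28 across
  the range, NDVI ≈ 0.07) is separable from any plausible canopy by that
  single threshold.
- **Zonal extraction** uses the pixel-center-in-polygon rule — the common
  zonal-statistics default and exactly testable against brute-force
  enumeration. Plots with all pixels masked are flagged and reported
  missing rather than raised.

## The synthetic generator

The generator's purpose is to create data whose *statistical structure*
matches what the analysis assumes, with every latent quantity recorded in a
ground-truth sidecar.

**Designs.** Alpha-lattices place every entry once per complete replicate,
split into equal incomplete blocks (`r ≥ 2` enforced; block size must
divide the entry count, defaulting to the largest divisor ≤ √n).
Augmented designs replicate only checks: each of the `n_checks` checks
appears once in each of `check_reps` incomplete blocks, so the plot count
is `n_entries + n_checks·(check_reps − 1)`; the unreplicated entries are
dealt into the blocks at random.

**Genetics.** Genotype effects for the canopy trait and yield are drawn
bivariate-normal with correlation `genetic_corr_yield` (0.7 by default —
the level at which an index is a useful secondary trait); G×E, design and
residual effects are independent. A water-status proxy follows the yield
genotype effect through a logistic link (`water_coupling` = 0.8), so
higher-yielding genotypes carry wetter canopies and the water index NWI
comes out negatively associated with yield, as it should.

**Trait scale.** Study-level defaults are σ²G = 0.16, σ²GE = 0.04,
σ²ε = 0.08 with trait mean −1. Through the canopy link (below) these give a
plot NDVI spread of SD ≈ 0.06 and range ≈ 0.3–0.7 — typical of a diverse
winter-wheat trial at anthesis. Wider latent variances produce NDVI ranges
no real trial shows and make the observation-noise processes irrelevant by
comparison, which would trivialize every platform contrast.

**Canopy spectra.** A soil endmember and a vegetation endmember are mixed
by a canopy fraction c = sigmoid((latent + 2)/0.8). The vegetation
endmember has a chlorophyll green peak (550 nm), deep red absorption
(680 nm), a logistic red edge rising to a 0.50 NIR plateau, and water
absorption dips at 970/1200/1450/1940 nm whose depth scales with the water
proxy. By construction NDVI is strictly increasing in the latent trait,
R970 is decreasing in water status, the red edge rises monotonically, and a
degenerate canopy collapses to the soil curve (NDVI < 0.3) — all asserted
as tests. Any curve family with these monotonicities would serve; this one
was chosen for closed-form testability, not radiative-transfer realism
(PROSAIL-class modelling is out of scope).

**Observation channels.** Three sensor presets share band centers
450/550/680/700/800/970 nm (50 nm widths): a UAS camera emitting digital
numbers (gain 1000, offset 80, DN noise SD 4, four-hour window of solar
noon), a broadband radiometer emitting reflectance (noise SD 0.004,
six-hour window), and a full-range hyperspectral sensor (noise SD 0.003,
six-hour window). Broadband values are band-window means of the true
spectrum times the illumination factor, through the DN transfer, plus
noise.

**Illumination model.** Illumination error is 1 at solar noon and grows
with |t| hours from noon, in two parts:

- *deterministic drift*: intensity `1 − a·|t|` (a = 0.05/h) times a
  spectral tilt `1 + s·|t|·clip((λ−800)/400, −1, 1)` (s = 0.05/h),
  modelling the reddening of incident light with growing air mass;
- *stochastic walk*: each observation carries a multiplicative intensity
  error (SD 0.05·√|t|), a spectral-tilt error (SD 0.10·√|t|) and a smooth
  chromatic error (SD 0.05·√|t|, correlation length 120 nm), modelling
  haze/cloud variation accrued since the last white-panel calibration.

The decomposition matters: a factor common to all bands cancels exactly in
ratio indices (NDVI/NDRE/NWI), so only the spectrally structured components
— above all the chromatic term, which decorrelates the red and NIR
calibration errors — propagate into index noise. This is the mechanism by
which a six-hour handheld sweep loses index heritability relative to a
20-minute UAS capture, and the collection-window experiment
(`collection_window_experiment`) demonstrates it as a direction, not a
number: with identical genetics, mean NDVI H² over 20 seeds is lower for
the long window (≈ 0.73 vs ≈ 0.78 under the defaults). The magnitudes were
chosen to put diurnal NDVI variation at ≈ 0.04–0.05 over ±3 h, mid-range
of reported clear-sky diurnal reflectance variation for row crops.

**Orthomosaics.** Plots are 1.5 × 3.5 m footprints on a regular grid with
0.3/0.6 m alleys, rendered at 0.1 m ground sampling (0.25 m is the
enforced ceiling so a plot spans at least 6 × 14 pixels) on an axis-aligned
north-up grid; plot polygons are inset 0.2 m from the sown edges to avoid
border pixels. Pixels inside a footprint carry that plot's band values;
everything else carries the flat soil spectrum. GeoTIFFs carry the
georeference in ModelPixelScale/ModelTiepoint tags; polygons travel as
GeoJSON with a `plot_id` property.

## Pipeline

`RunConfig` holds an era preset plus design, genetics, sensor and seed
settings; the two presets reproduce the two processing regimes (single
panel + derived NIR + broadband radiometer vs five panels + native NIR +
hyperspectral handheld). Stages (`simulate → calibrate → process → indices
→ h2 → association`) communicate only through files in the run directory,
so any stage can be re-run in isolation and identical config + seed gives
byte-identical CSVs; a manifest records the config hash, seed and per-stage
row/QC counts. Handheld plots are scheduled sequentially across the
collection window in field order (which confounds drift with replicate
order, exactly as a real sweep does); the UAS offsets fall inside its
20-minute capture.

## Problem sizes and what the tests show

The default test and acceptance runs use trials of 25–300 entries, 1–3
replicates and 1–2 environments, and 20-seed batches for the stochastic
properties — sizes at which variance-component recovery is informative
(±15% on means over 20 seeds) while the whole suite stays fast. Passing
tests demonstrate internal consistency (formulas against independent
oracles, exact round trips, parameter recovery under the generator's own
assumptions, the direction of the window effect). They do not demonstrate
that real canopies follow the spectral model, that real illumination drift
matches the assumed magnitudes, or that real trials are free of the spatial
trends this model omits (no spatial field-trend correction is attempted).

## Known limitations

- Gaussian effects throughout; no skewed or heavy-tailed plot errors.
- No radiative-transfer realism, BRDF/vignetting correction, GPS error, or
  image-stitching artefacts; orthomosaics are rendered, not stitched.
- The REML fit assumes independent random effects (no marker kinship, no
  spatial correlation) and a single trait at a time.
- PCA is listwise-complete while correlations are pairwise-complete — the
  conventions of the common statistical routines each mirrors — so their
  effective samples can differ on data with missingness.
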