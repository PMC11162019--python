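# Methods

This note documents the models behind `canopylink`: the synthetic scene
generator, the point-cloud processing chain, the metric definitions, the
regression machinery, and the design choices made where the design was
genuinely open. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## The synthetic scene

The generator emulates a seasonally dry open woodland (Miombo-like)
inventory campaign. Its components, with defaults and rationale:

**Terrain.** Gaussian white noise smoothed with a kernel of standard
deviation equal to the correlation length (default 300 m) and rescaled so
the deviation from the base elevation never exceeds the relief amplitude
(default 8 m — gentle lateritic relief). Amplitude 0 yields a plane.

**Fertility field.** A second smooth random field, scaled to
`1 ± fertility_strength` (default 0.6), modulates local stem density (by
thinning a parent Poisson process at twice the target density, so the
realized mean density equals the nominal one) and shifts the diameter
distribution upward on rich sites. This is what creates the spatial AGB
gradient an area-based inventory needs; without it every 20 m cell would
be statistically identical.

**Trees.** Stem density defaults to 550 stems/ha (DBH ≥ 5 cm). Diameters
follow a Weibull distribution (shape 1.3, scale 11 cm) left-truncated at
5 cm — the reverse-J size structure typical of uneven-aged dry woodland.
Heights follow a saturating curve `h = 1.3 + (h_max − 1.3)·d/(d + d_half)`
(h_max 22 m, d_half 16 cm) with 1 m Gaussian scatter, floored at 1.5 m.
Crown radius is `0.8 + 0.09·DBH` m (capped at 6 m), giving landscape canopy
cover near 0.5 at the default density — open-woodland levels; an earlier,
sparser parameterization left mid height percentiles zero-inflated, which
is both unrealistic and hostile to linear modelling. Tree biomass is the
power law `AGB = a·(D²H)^b` kg (defaults a = 0.0613, b = 0.976), the
standard pan-tropical form; coefficients are configurable because
site-specific allometries vary.

**Plot AGB observation error.** Field AGB is an allometric estimate, not
truth: the generator multiplies each plot's AGB by a lognormal factor with
CV 0.15 (mean 1), consistent with propagated allometric-plus-measurement
uncertainty reported for small tropical plots. Cell-level truth AGB remains
exact, so estimator bias can be measured against it.

**Lidar.** Pulses arrive as a uniform Poisson process (default
300 pulses/m², the density class of current UAS laser scanners). Crowns
are vertical-axis spheroids (depth 0.45·height) hung below the tree top; a
pulse covered by one or more crowns returns first from the highest crown
envelope, and with probability `canopy_penetration` (default 0.35) also
returns from the ground (return number 2). Uncovered pulses return once
from the ground. All elevations carry Gaussian noise (default SD 0.05 m).
Because first returns hit a crown exactly when the pulse falls inside a
crown footprint, the first-return crown fraction is an unbiased estimator
of true vertical-projection canopy cover — a property the tests exploit.

**Reflectance.** Per-cell endmember fractions are a deterministic function
of true canopy cover (GV = 0.8·cover + 0.02, Shade = 0.15·cover, the
remainder split 45/55 between NPV and soil; non-negative, summing to one
exactly), mixed linearly through a four-endmember spectral library over
bands B2–B12 and perturbed with Gaussian band noise (default SD 0.01
reflectance), clipped to [0, 1]. The default library is a generic
green-vegetation / dry-vegetation / soil / shade set with a red-edge ramp,
NIR plateau and SWIR contrast; its condition number is checked before
unmixing.

**Layout.** Rectangular grid-aligned flight blocks (default ten of
30–50 ha) are placed without overlap; plot centres coincide with 20 m
cell centres, lie at least 50 m inside the block and pairwise at least
`plot_spacing` apart. Note a geometric fact: with a strict 250 m minimum
spacing and a 50 m buffer, a 30–50 ha block holds at most ~9 plots, so the
nominal 10–12 plots per block cannot all be placed; `generate_scene` fills
each block to packing capacity (with a warning), while direct calls to
`layout_blocks_and_plots` treat an unreachable target as an error unless
`allow_fewer_plots=True`.

**What the generator does not emulate.** Radiative transfer (reflectance
is a linear mixture driven by cover alone — no BRDF, phenology, soil
moisture or species spectra), GPS error, ranging artefacts other than
Gaussian noise, multiple scattering or waveform effects, spatial clumping
beyond the fertility field, and topographic illumination. Passing tests
therefore demonstrate the correctness and internal consistency of the
estimation chain under a known generative model — not field performance.

## Point-cloud processing

Order is enforced: denoise → ground classification → DTM → normalize;
metric extraction refuses clouds without normalized heights.

* **Outlier removal** is the classical statistical filter: a point whose
  mean distance to its k = 10 nearest neighbours exceeds the global mean by
  more than 3 SD is labelled noise. On any finite clean cloud this flags
  the thin right tail (≲1%) — exact zero flagging holds only in
  idealization, and the tests assert the ≤1% bound.
* **Ground classification** is progressive TIN densification in its basic
  published form: the lowest point per 20 m cell seeds a Delaunay TIN
  (ties broken by point index), and points are accepted iteratively when
  their vertical distance to the containing facet is ≤ 0.5 m and the
  maximal angle to the facet vertices ≤ 8°, to a fixpoint (≤ 30
  iterations). Four virtual corner vertices, carrying the elevation of the
  nearest seed, keep the TIN covering the footprint so border points can
  be classified. Deterministic; no randomness anywhere.
* **DTM** by inverse-distance weighting (power 2, 12 neighbours, 1 m
  default resolution); a node coincident with a ground point returns that
  elevation exactly; nodes beyond 50 m of any ground point are nodata.
* **Normalization** subtracts a bilinear DTM lookup; negative heights are
  clamped to zero, with heights below −0.2 m counted and warned about
  (they indicate DTM error). Points outside DTM coverage are excluded and
  counted.

## Canopy metrics

Per 20 m cell (minimum 10 returns, else the cell is listed as
underpopulated): 15 percentile heights of first returns; D1–D9 as the
proportion of all returns above the nine equal-height slice boundaries of
[min, max] (all zero when the range is degenerate — the "proportion above
the distribution's own quantiles" reading is tautologically 1−q);
moment statistics of all returns (sample SD, non-excess kurtosis, median
absolute deviation about the median); Hmean over first returns;
Hcv = Hstd/Hmean; Hmax as the maximum over returns above the 2 m canopy
threshold (a point filter, configurable — consequently H99 ≤ Hmax is
guaranteed only in cells whose tallest return exceeds 2 m); CC as the
share of first returns above 2 m; GF as the share of all returns at or
below 2 m; CRR = (mean−min)/(max−min) over all returns;
LAI = −ln(GF)/k with Beer–Lambert extinction k = 0.5 and GF floored at
1/(n+1) inside the logarithm. All return-filters are configurable.

## Satellite metrics

Vegetation indices follow their standard normalized-difference and
soil-adjusted forms (SAVI soil factor L = 0.5 by default). Endmember
fractions come from fully constrained least squares: non-negative least
squares on the sum-to-one-augmented system (weight 10³) followed by exact
renormalization, so fractions are ≥ 0 and sum to one even for out-of-hull
spectra; the residual norm is reported per cell. NDFI uses the
shade-normalized GV fraction GV/(1+Shade) against NPV+Soil; only GV is
shade-normalized, as the index is defined. Biophysical variables default
to **proxy mode** — monotone transforms of NDVI/GNDVI computed from the
(noisy) bands — because an image-derived retrieval must inherit the
image's noise; a synthetic **truth mode** (scene truth plus Gaussian
noise) exists but injects a cover signal cleaner than the bands
themselves, which is unrealistic for real retrievals.

## Regression and selection

OLS with intercept throughout; R², adjusted R², RMSE = √(SSE/n);
PRESS from leverages, pred-R² = 1 − PRESS/SST; Cp = SSE/MSE_full − n
+ 2(p+1); with k = p+2 estimated quantities,
AICc = n·ln(SSE/n) + 2k + 2k(k+1)/(n−k−1) and BIC = n·ln(SSE/n) + k·ln(n)
(defined up to additive constants; only rankings are meaningful, and a
perfect fit maps to −∞ so noiseless data select the smallest exact subset).
Best subsets enumerates all subsets up to size 10 (guarded at 25
candidates) on the centred Gram matrix, retains the best-R² subset per
size, and selects the lowest AICc. The Pearson pre-filter drops one member
of every pair with |r| > 0.85 (the member less correlated with the
response; ties keep the alphabetically first name), after removing
zero-variance columns; an exact-rank screen then removes any remaining
exact linear dependences (e.g. four fractions summing to one). k-fold
cross-validation (default k = 10, seeded shuffle, fold sizes within one)
pools out-of-fold predictions; with k = n it reproduces the analytic
leave-one-out residuals.

Two pipeline-level guards are our own additions, documented because they
change selection behaviour: (i) an **applicability-domain screen** drops
candidate predictors whose training-sample SD is less than 0.35 of their
SD over the full prediction table — a predictor nearly constant at the
plots but variable across cells acquires an enormous coefficient and,
after exponentiation, produces astronomically wrong cell predictions;
(ii) responses below 0.5 Mg/ha are excluded from ln fits; (iii) every
phase model carries a **response ceiling** of 1.5x its largest training
response, applied to all back-transformed predictions (including
out-of-fold CV predictions) — truncation to the calibration range, the
usual safeguard against a leave-one-out refit or map extrapolation
exponentiating into physically absurd biomass. Back-transform of ln models
is naive exponentiation by default, with an optional smearing factor (off
by default).

## Two-phase orchestration

Phase 1 and phase 2 use the ln response; the direct model fits the identity
response. A provenance tag on every AGB series enforces the information
firewall (phase 2 accepts only lidar predictions; the direct model only
field AGB). Margin cells — grid cells not fully covered by a block — are
removed before prediction. The reference sample (default 700, capped at
the pool with a warning) is uniform without replacement. Reports carry
training R²/adj-R² on the model scale and cross-validated RMSE/rRMSE/bias
(and pred-R²) on the Mg/ha scale; in synthetic mode an additional report
scores predictions against the scene's true cell AGB, labelled separately.

## Problem sizes and the replicate experiment

All shipped configurations are scaled-down study twins chosen so the full
chain runs on a single CPU in minutes: the demo scene uses two 16 ha
blocks, 20 plots at 100 m spacing and 2 pulses/m²; the replicate
experiment (`ordering_experiment_config`) uses eight 6.25 ha blocks, nine
plots each at 60 m spacing, 1 pulse/m², known-terrain normalization (the
full denoise/PTD/IDW chain is benchmarked separately on its own scene),
and satellite noise dominating the lidar chain (band noise SD 0.025,
proxy-mode biophysicals). The noise levels were calibrated so the three
models operate near the fit quality reported for comparable two-phase
campaigns (plot–lidar R² ≈ 0.85–0.9, satellite models ≈ 0.5–0.75); under
these conditions the two-phase model's adjusted R² exceeds the direct
model's in the large majority of replicates, which the acceptance suite
quantifies over 50 seeds.

## Numerical and degenerate-input conventions

Seeded determinism everywhere (`numpy.random.default_rng`; scene
sub-streams via `SeedSequence.spawn`). Degenerate height ranges give
D1–D9 = 0 and CRR = 0; Hcv is missing when Hmean ≤ 0; zero index
denominators give missing values, counted per cell. Unmixing falls back to
uniform fractions only for an all-zero NNLS solution (dark pixels).
Fold assignment uses a seeded permutation and `array_split`. The AGB map
is float32 with nodata −9999, georeferenced by an ESRI world file.

## Known limitations

Model-based inference only — no design-based variance for the two-phase
estimator, no uncertainty maps. The 314 m² circular plot is paired with
its 400 m² cell without area correction (the footprint mismatch acts as
response noise; both areas are configurable so the effect can be studied).
Reflectance carries no information beyond canopy cover, so satellite
models in the synthetic world cannot resolve height-driven AGB variation;
real imagery may do somewhat better (texture, phenology) or worse
(atmosphere, saturation).
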