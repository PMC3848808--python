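# Methods

## Shape model

Each LV surface (endocardium, epicardium) is a radial function λ(u, v) of a
circumferential coordinate u ∈ [0, 1) and an apex-to-base coordinate
v ∈ [0, 1], expressed in a prolate spheroidal frame: θ = 2πu, μ = v·μ_max
(default μ_max = 120°), and

    x₁ = f·cosh λ·cos μ,  x₂ = f·sinh λ·sin μ·cos θ,  x₃ = f·sinh λ·sin μ·sin θ,

followed by a rigid frame rotation/translation.  λ(u, v) is a tensor-product
cubic B-spline over an Nc×Nl nodal grid (default 8×8 per surface, 256
parameters per frame over both surfaces), periodic in u and clamped in v, so
the surface is C¹ and each nodal value acts as a local shape parameter.
This basis is the package's own design: it retains the essential structure
required by the correction method — locally supported control values as the
statistical unit, a radial surface C¹ in two angular coordinates — while
being fully specified in code.  Classical cardiac finite-element
parameterizations differ in element layout and parameter count; the
per-parameter correction is agnostic to that choice.

Cavity volume closes the sampled surface with a planar polygonal cap at the
basal boundary (v = 1) and integrates the divergence theorem over the
triangulation (second-order accurate in grid spacing; the analytic
half-ellipsoid is reproduced to 0.2% at resolution 64).  LV mass is the
epi−endo shell volume × 1.05 g/ml, evaluated at ED.  AHA 17-segment labels
are assigned parametrically: the apical cap is the apex-most 1/8 of the v
range; the remaining range splits into three equal rings with 6/6/4 sectors
anchored to a configurable septal reference angle.

## Protocol bias correction

For each shape parameter the mean and SD over the paired training
populations are estimated by maximum likelihood (divide-by-n SD; an unbiased
option exists, and the corrected spread ratio σ_SSFP/σ_GRE is nearly
invariant to the choice).  The z-score transform maps each GRE value through
its population z-score onto the SSFP distribution, matching first and second
moments of every parameter exactly on the training set.  Transforms are
learned per cardiac frame (ED, ES), since the bias field is frame-dependent;
pooling is available.  Parameters with zero GRE spread raise a fitting error
naming the parameter (an intercept-only fallback is available behind a
flag).  Six comparison families — per-parameter OLS variants, blockwise
multivariate least squares (blocks of 4 consecutive parameters standing in
for nodal groups), and a global pseudo-inverse map (under-determined when
parameters outnumber cases; included for comparison) — share the same
estimator interface.

Gaussianity of the parameter marginals is screened with the composite
Anderson–Darling normality test (scipy's size-adjusted critical values; the
empirical rejection rate for Gaussian samples of n = 46 is within 1% of the
nominal 5%).

## Synthetic cohort generator

No subject data ship with the package; all validation runs on synthetic
cohorts built to satisfy exactly the assumptions the correction makes.  Per
frame and parameter k:

    z_k ~ N(mean_k, σ_k²)            latent anatomy
    GRE_k  = z_k + ε,                ε ~ N(0, τ_k²)
    SSFP_k = s_k·(z_k − mean_k) + mean_k + δ_k + ε′

so the protocol effect is an additive regional offset δ plus a
multiplicative spread factor s, and the z-score family contains the true
optimal correction — parameter recovery is therefore a meaningful oracle
(fitted σ-ratio → s, fitted mean difference → δ, verified at n = 2000).

The default calibration (frozen constants in `_calibration.py`, derived by
`scripts/calibrate_population.py`) sets:

- mean shapes such that the mean GRE model yields EDV 126.2 ml, ESV
  52.8 ml, LVM 145.2 g (myocardial shell volume held equal at ED and ES);
- δ fields concentrated on the apical endocardium and the basal ring (with
  a mild circumferential modulation standing in for papillary/trabecular
  flow disruption), calibrated so the *population expectations* of the
  paired differences are SSFP−GRE EDV +7.9 ml, ESV 0.0 ml and GRE−SSFP LVM
  +14.1 g.  Calibration solves the mean-shape volume offsets by bracketed
  root-finding, applies a second-order variance correction for the
  nonlinearity of the volume functional under the spread factor, and
  finishes with two Newton rounds against a 12,000-case common-random-number
  cohort (residuals < 0.01 ml);
- per-parameter population SD 0.03 and measurement noise SD 0.004 (λ units),
  spread factors up to 1.06 apically / 1.025 basally.

Draws violating the epicardium-encloses-endocardium invariant are rejected
and redrawn (counts logged in cohort provenance; ~1% of cases at default
settings).

What the generator does *not* emulate: the latent covariance is diagonal,
so there is no global "heart size" mode; consequently the per-case spread
of volumes (and of paired volume differences) is far smaller than in real
populations, even though all population-mean quantities match.  Passing
validation bounds here demonstrates correctness of the estimator and of the
pipeline under the model's own assumptions, not performance on real scans,
where per-case variance terms would dominate confidence intervals.  LGE
grades are a deterministic labelling derived from the applied remodeling
effect magnitude per segment — a convenience for exercising the group
statistics, not a model of gadolinium enhancement; all disease cases of a
cohort share the same grade table.

## Validation

Leave-one-out: the transform is fitted on n−1 cases and applied to the
held-out GRE shape; volume/mass errors are signed estimated−measured SSFP.
Surface bias is a population-level quantity: the per-point mean over cases
of the 3-D displacement between corrected and measured surfaces, aggregated
as the RMS over the registered 1,089-point samplings of both surfaces.  It
deliberately excludes per-case variance — the method corrects statistical
bias, not individual error.  Pre-correction bias uses the raw GRE surfaces.

The training-size curve draws, per replicate, a fixed held-out evaluation
set of n − max(sizes) cases and fits on nested subsets of the remainder.
Holding the evaluation set fixed across sizes isolates the
transform-estimation error (the quantity of interest) from the noise of the
held-out mean, making the curve non-increasing in expectation; evaluating
on the complement of each training size would confound the two.

The seven-way family comparison runs LOO for every family.  A caveat
discovered during development: under LOO pooling *every* family that fits
an additive mean is nearly unbiased in parameter space (training residuals
cancel), so on cohorts whose spread factors are close to 1 the bias-RMS
ranking between the mean-correcting families is decided by estimation
noise.  The family comparison is therefore run on a cohort with a
pronounced spread mismatch (`spread_mismatch_model`: s up to 1.5 apically,
population SD 0.06, noise 0.02) — the regime in which variance matching
matters and the z-score family's advantage is structural: families that
shrink (OLS attenuation) or ignore (intercept/identity forms) the spread
produce a second-order surface bias ∝ Σ_k ∂²x/∂λ_k²·(Var[ŷ_k] − Var[y_k]),
which only the moment-matching transform drives to zero.

## Group statistics

Pointwise cohort comparison uses the unequal-variance Hotelling statistic
T² = d′(S₁/n₁ + S₂/n₂)⁻¹d on the 3-D coordinates at each registered lattice
point, with Yao's F-approximation (Satterthwaite-style degrees of freedom)
as the default null reference; a large-sample χ²(3) option exists and
nearly coincides at n₁ = 300, n₂ = 105 (empirical type-I error 5.2% at
α = 5% over 10,000 null replicates).  In 1-D the statistic and p-value
reduce exactly to the squared Welch t test.

Because registered samples of the spline model vary across cases only along
the radial coordinate line, per-point 3-D covariances can be exactly rank
deficient (co-planar or, on symmetry axes, co-linear samples).  The
statistic is therefore computed on the support of the pooled covariance: an
eigendecomposition discards directions below 1e−8 of the leading
eigenvalue and the reference distribution uses the effective dimension.
This is rotation-invariant (verified to 1e−9 under rigid motion of both
cohorts) and reduces to the ordinary statistic for full-rank data.

Segment-level LGE statistics select patient segments by a minimum
transmural grade (both thresholds in use, ≥2 and ≥3, are reachable),
sample a deterministic 200-point lattice per qualifying segment, and test
qualifying patients against the full control cohort point by point, before
and after correcting the controls; summaries are the quartiles and mean of
log₁₀ p.  No multiple-testing correction is applied by default (maps are
descriptive); Benjamini–Hochberg thresholding can be applied downstream.

## Numerical and design choices

- Volumes in ml, lengths in mm, mass in g; u half-open, v closed.
- Volume integration resolution 33 (matching the 33×33 sampling) for
  validation; 64+ for analytic accuracy checks.
- The 1,089-point sampling is a parametrically uniform 33×33 grid.
- Train/test splits and all generators draw from named, seed-derived
  substreams (`_utils.derive_seed`); identical seeds give bit-identical
  cohorts, reports and CSV outputs.
- Self-intersection of sampled meshes is flagged when opposite-signed
  sub-volumes exceed 1% of the total (warning, not an error).
- Wall-thickness violations after applying a transform are flagged and
  logged, never silently clipped.

## Problem sizes

Default experiment sizes — 46-case paired cohorts, 10-split training-size
curves at size 39, 500-case calibration checks, 10,000-replicate
statistical calibrations — were chosen so the full validation suite
completes in minutes on a single CPU while keeping Monte-Carlo error well
inside every asserted tolerance.

## Known limitations

- The diagonal latent covariance understates population volume SDs (no
  size mode); see above.
- The spline basis is structurally, not numerically, equivalent to
  classical cardiac FEM parameterizations; parameter counts differ.
- The planar basal cap is a simple, reproducible truncation rule; real
  basal anatomy is not planar.
- Inter-observer robustness requires a second human analysis and is out of
  scope for a synthetic pipeline.
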