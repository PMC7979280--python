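# Methods

## Contour model

A lower-facial contour is an ordered point list from one earlobe top,
around the chin, to the other earlobe top, recorded in arbitrary device
coordinates with a physical-scale annotation (mm per coordinate unit) and
the two earlobe anchors flagged. Normalization is a fixed sequence:

1. multiply by the scale annotation (coordinates now in mm);
2. rotate about the centroid so the earlobe-to-earlobe chord is
   horizontal, flipping 180° if the contour body ends up above the chord
   (the chin must point down);
3. translate so the midpoint of the two anchor x-coordinates is at
   x = 0, and the chin apex at y = 0.

The vertical anchor in step 3 is the vertex offset *c* of an auxiliary
least-squares fit y = a x² + c, not the lowest *sampled* point. The two
differ by a·(Δx/2)² when the sampling grid straddles the vertex (any
even point count), and anchoring on a sampled point would bias the final
coefficient by about 5/(3(N−1)²) relative — enough to break exact
round-trip recovery. The vertex is the contour's true lowermost point, so
this is the faithful reading of the convention; for degenerate designs
(all x equal after rotation) the code falls back to the lowest sampled
point. Normalization is idempotent and preserves point order.

The shape summary is the through-origin parabola y = a x² with the
closed-form least-squares coefficient a = Σx²y / Σx⁴ (units mm⁻¹).
No linear or constant term is fitted: the normalization already pins the
vertex to the origin, and the single-coefficient model is the point of
the method. Fit quality is R² = 1 − SS_res/SS_tot with SS_tot taken
about the mean of y. R² for a constrained model is convention-dependent;
the about-the-mean form is the one under which the R² > 0.95 gate is a
meaningful bar (the zero-mean form would be trivially high for any
upward-curving contour). A zero-variance y (flat contour) is reported as
R² = 1 with a = 0 rather than 0/0. Contours failing the gate are flagged
and excluded from association and training input when gating is enabled.

An optional quantization (`--quantize 1.0`) snaps normalized coordinates
to a 1 mm grid, emulating manual digitisation on grid-overlaid 35 × 45 mm
photo cards; it is off by default.

## Synthetic cohort generator

The generator emulates the statistical structure of a 106-subject adult
cohort (the default `n_subjects`); no public paired contour/body-fat
dataset exists. A single latent adiposity factor z ~ Uniform(0, 1) drives
everything:

* contour coefficient: true_a = 0.127 − 0.064·z + ε_a, spanning the
  observed 0.063–0.127 range from leanest to most adipose;
* each parameter j: P_j = L_j + (U_j − L_j)·z + ε_j with observed ranges
  weight 40.2–87.5 kg, BMI 17–32.7 kg/m², WHR 0.75–1.03, PBF 14.1–44.3 %,
  VFA 24.7–148.7 cm². The BFM range 5–40 kg is an assumption (it is not
  reported); it puts the mean near 21 kg, consistent with the reported
  deviation statistics.

All ε are independent Gaussians. Writing ρ_a for the fraction of variance
of a explained by z (fixed at 0.90, which must be ≥ the largest target)
and ρ_j = R²_target,j / ρ_a, the population squared correlation
corr²(a, P_j) = ρ_a·ρ_j equals the target exactly when

    σ_j = (U_j − L_j) · √(1/12) · √((1 − ρ_j)/ρ_j),

1/12 being the variance of Uniform(0,1); σ_a analogously with span 0.064.
The resulting defaults are σ_a ≈ 0.00616 and (weight, BMI, WHR, PBF, BFM,
VFA) ≈ (11.15, 1.862, 0.0572, 4.359, 7.324, 22.20) in each parameter's
units. A one-factor model is the simplest structure consistent with all
six pairwise targets; it does **not** calibrate the correlations among
the parameters themselves (none are targeted), and only the
weight/height/BMI identity is enforced physiologically — height is
derived as 100·√(weight/BMI) so BMI = weight/(height/100)² holds exactly.

Noise is unclipped, so simulated values can stray slightly outside the
stated ranges; clipping would bias the correlations the calibration
fixes. The one exception: a subject whose weight (or BMI, or true_a)
would come out non-positive — probability ~1e-5 per subject, but reachable
over many replicates — has that noise draw redrawn, since a non-positive
weight has no physical meaning and would make the derived height
undefined.

Contours are sampled per subject: N ~ Uniform{30..65} equally spaced x
over ±x_max, x_max ~ Uniform(13, 16) mm (chosen so the contour height
a·x_max² stays within a 45 mm card for every a in range), y = true_a·x²
plus Gaussian noise of SD 0.25 mm applied to y only — y-noise keeps the
through-origin estimator unbiased, whereas x-jitter would add
errors-in-variables attenuation that the calibration does not model. The
points then receive a random similarity transform (rotation ±5°, scale
50–120 units/mm, translation ±50 units) with the inverse scale recorded
as the annotation, and the two x = ±x_max points flagged as the earlobe
anchors.

What passing tests show, and what they do not: the generator reproduces
the ranges, the pairwise correlation targets, and the digitisation noise
level, so green pipeline tests demonstrate that the estimator and
analysis recover a known structure of this kind. Real faces add
asymmetry, non-parabolic chin/jowl detail, landmarking error correlated
along the contour, demographic strata and parameter-parameter
correlations, none of which are emulated; results on real cohorts can
differ accordingly.

## Association analysis

Pearson correlation of each parameter against a (scipy), OLS line
(y = parameter on x = a), and the zero-slope t-test computed from the
correlation, t = r√(n−2)/√(1−r²) with two-sided p from t(n−2) at
α = 0.05. Two-sidedness is a choice; the screening threshold R² > 0.5
marks "practically significant" associations. No multiple-testing
correction is applied across the six parameters, matching the original
single-look analysis; with six tests at p < 0.001 throughout this is
immaterial here, but users adding parameters should correct.

Residual trimming: "deviation from the best fit line" is read as the
absolute vertical residual in the parameter-vs-a regression. The
floor(f·n) largest are removed (ties broken by original row order, for
determinism), the line is refit and R² recomputed on the survivors. By
construction this cannot lower R² in practice and the trimmed values here
always rise; trimmed R² values from other residual distributions (e.g.
the original measured cohort) are not comparable and are not targeted.

At n = 106 the standard t formula gives t ≈ 18.7 for R² = 0.77; published
t values near 9.65 for the same R² imply a much smaller effective n and
cannot be reconciled with the formula — the package reports the standard
computation.

## Prediction

The predictor regresses each parameter on a over gate-passing training
rows (the inverse-regression direction: the parameter is the target), and
stores the regression standard error √(SS_res/(n−2)) per parameter plus
the training range of a. A query returns point estimates, a homoscedastic
Normal 95% band (±1.96·SE), the BMI category of the predicted BMI
(boundaries 18.5/25/30 assigned upward, WHO convention), and an
extrapolation flag for a outside the training range. Training is pooled
across the cohort; no category balancing or per-stratum model is
attempted, as no stratum information is targeted by the generator.

## Numerical and interface choices

* All randomness flows from a single integer seed through one
  `numpy.random.Generator`; identical configs give byte-identical output
  files (floats are written with shortest round-trip `repr`, and JSON
  keys are sorted).
* Replicated experiments derive per-replicate seeds from one meta-seed
  (integers below 2³¹).
* The calibration-recovery experiment uses 200 replicate cohorts of
  n = 106 — enough to pin each mean R² to ±0.01 (SE ≈ σ/√200 ≈ 0.004) —
  and runs in seconds.
* Degenerate inputs fail loudly with `ValueError` (coincident endpoints,
  all-x-zero fits, < 3 points, zero-variance correlations, non-positive
  anthropometrics); batch operations skip and log bad rows instead of
  aborting the run. CLI validation errors exit with status 2.
* Boundary BMI values go to the higher category so the categories
  partition (0, ∞).

## Known limitations

* The latent-factor generator reproduces pairwise structure only;
  inter-parameter correlations, demographic strata, and the empirical BMI
  distribution (category counts) are not modeled.
* The parabola is fitted with a fixed vertex at the origin; contours of
  strongly asymmetric faces are only approximately captured, and the
  symmetry axis is operationalized as the endpoint midline rather than an
  area bisection.
* Printed WHR ranges of the source cohort differ between sections
  (0.75–1.03 vs 0.75–1); the wider range is used.
* Prediction bands assume homoscedastic Normal residuals; they are
  calibrated for the synthetic conditions, not validated on real faces.
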