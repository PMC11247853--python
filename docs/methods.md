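# Methods

`blastotrace` analyses blastocyst collapse from time-lapse microscopy area
measurements and relates collapse behaviour to embryo ploidy.  Because
clinical time-lapse videos and PGT-A calls are confidential, the package
ships a first-class synthetic generator whose defaults encode the study
conditions, so every downstream stage is testable against known ground
truth.  This note records the models, the parameters that matter, and the
design choices made where the underlying procedure was open.

## Collapse model and detection

A collapse is an uninterrupted reduction of the blastocoel-cavity area
followed by possible re-expansion.  On the 10-minute frame grid
(`frame_interval_min = 10`, the standard acquisition interval of clinical
time-lapse incubators) an event is a **maximal non-increasing run** of
cavity area containing at least one strict decrease.  A rise of any size
terminates the run — two falls separated by a rise are two events — while a
flat plateau does not.  The run's start is the last frame at the reference
level before the first strict fall; its minimum is the first frame
attaining the smallest area.

* **Trigger** (`min_drop`, default 0.10): the total relative drop from the
  reference needed to call an event.  The default mirrors the widely used
  criterion of an embryo:zona area ratio ≤ 90%; it is configurable, and the
  noiseless closure experiments use 0.01 (see below).
* **Shrinkage**: fraction of the reference area lost at the minimum,
  1 − A_min/A_ref.  Before full blastocyst formation (tB) A_ref is the
  cavity area at the event start; after tB it is the area inside the zona
  pellucida (ZP) at the time of the minimum, since the expanded blastocyst
  fills the zona and the zona interior is the stable yardstick.  The raw
  remaining-area ratio is kept alongside (`area_ratio`); whether
  "shrinkage" names the ratio or its complement is ambiguous in the
  literature, and a mean shrinkage of ~25% is only physically coherent as
  area lost, so the complement is reported under that name.
* **Recovery duration** (`recovery_frac`, default 0.90): hours from the
  minimum-area frame to the first frame whose cavity area regains 90% of
  the pre-collapse cavity area.  "Recovery" has no standard quantitative
  definition; 0.90 requires a near-baseline return while tolerating a few
  percent of segmentation noise.  Durations are censored (missing, flagged)
  when the trace ends first, and quantised to the frame interval, which
  biases measured durations upward by about half a frame (+0.08 h on
  average) — visible in the closure experiments.
* **Phase**: events are assigned before/after tB by their start frame
  (events straddling tB count as before-tB).  The search window opens at
  blastulation onset (tSB); earlier area fluctuations are never events.
* Embryos are summarised into four categories — no collapse, before-tB
  only, after-tB only, both — plus the post-tB count and the
  multiple-collapse flag (≥ 2 post-tB events), the model's exposure of
  interest.

## Segmentation

The per-frame measurement is a classical pipeline, not a learned one: the
synthetic frames are designed to be segmentable by thresholding.  The ZP is
found as the largest bright connected component; filling it bounds the
embryo, and the ZP-interior area and effective thickness come from the
filled/interior pixel counts.  The cavity is the largest dark component
inside the interior (Otsu threshold on interior intensities).  A
near-uniform interior is either all trophectoderm (no cavity) or all cavity
(fully expanded blastocyst); it is disambiguated by comparing its median
intensity with the background/ZP anchors, and an Otsu split whose classes
are not separated by at least 3 within-class standard deviations is treated
as uniform (this is what makes the measurement robust to frame noise).
Frames with no usable contrast are flagged `off_frame`, frames without a
locatable ZP `low_contrast`; flagged frames carry missing areas — never
zeros — and a trace with more than 20% flagged frames is unanalyzable (the
threshold is our choice; clinical practice excludes embryos that drift out
of view without a numeric rule).  tB, when not annotated, is inferred as
the last frame before a sustained ZP thinning (≥ 3 consecutive decreasing
thickness frames).

On rendered synthetic suites the event-level error of the full
render → segment → detect chain is required to stay within the published
manual-validation bounds (≤ 4.48% of single-collapse embryos with no
detected event; ≤ 6.28% of multi-collapse embryos undercounted).

## Synthetic generator

**Geometry/trace level.**  The cavity baseline is zero before tSB, a
normalised logistic ramp of the ZP-interior area over (tSB, tB)
(`expansion_steepness` 10 spans the ramp; the functional form is a modelling
choice — smooth, monotone, saturating), and equal to the ZP-interior area
from tB on (fully expanded blastocyst).  The zona thins after tB by linear
inner-radius growth (0.4 px/h, outer radius fixed), which also encodes the
"last frame before the zona starts to thin" definition of tB.  Collapses
are piecewise-linear dips: one frame interval down to the programmed
minimum, then a linear ramp that crosses the 90% recovery criterion exactly
`recovery_duration_h` after the minimum and rejoins the baseline two frames
later.  The 10-minute grid cannot resolve finer dip shape, so the simplest
consistent shape is used.  Collapse windows may not overlap (rejected with
the offending pair named).  Default geometry: ZP inner/outer radii 75/85 px
in 200 px frames.

**Calibration of programmed collapses** (`FirstCollapseLaws`): start times
normal 106.6 ± 8.2 hpi (before tB) / 121.3 ± 11.1 hpi (after tB) truncated
to the phase span; shrinkage normal 23.9 ± 4.5% / 25.0 ± 15.2% truncated
*symmetrically about the mean* within (0, 1) — symmetric truncation keeps
the truncated law's mean at the printed value, which is what a calibration
to a printed mean ± SD should preserve; recovery durations log-normal with
the printed means (0.9 h / 1.0 h) and σ_log = 0.8.  A right-skewed law is
the only way a sub-hour-scale mean can coexist with occasional hours-long
collapses; the printed SD of 5.8 h is not imposed because it implies a tail
that is almost entirely censored by trace ends of realistic length, making
the mean the usable calibration target.

**Cohort level** (`simulate_cohort`): cycles carry 1 + Poisson embryos
(mean 2.38/cycle, matching ~1072 embryos in ~450 cycles), patient and cycle
covariates at realistic clinic ranges (age 32 ± 4.6 y, AMH log-normal mean
3.5 IU, …), morphokinetic times built from non-negative increments so the
ordering t2 ≤ t3 ≤ … ≤ tB always holds, and collapse categories drawn at
the published prevalences (71.9/5.6/19.4/3.1%).  The post-tB count
distribution given ≥ 1 collapse (0.673, 0.20, 0.075, 0.030, 0.015, 0.007
for counts 1–6) is a free calibration knob constrained only by the group
sizes (about one third of post-tB collapsers collapse more than once).
Aneuploidy follows a logistic model on centred covariates with a cycle
random intercept (SD 0.5):

    logit P(aneuploid) = −baseline_euploid_logit
                         + log(1.100)·1[count = 1] + log(2.597)·1[count ≥ 2]
                         + covariate terms + b_cycle

with covariate coefficients set to the published adjusted odds ratios.
Post-tB collapses also delay tB (+0.8 h per event) and stretch s3, and
shift trophectoderm grades toward C, so the confounding structure the
adjusted model must handle is present.  Exclusion flags (amplification
failure 1.3%, mosaic 12.8%, imaging abnormalities, off-frame drift) default
to the published cohort rates.  One master seed drives everything;
per-embryo substreams are derived by counter so embryo k is reproducible in
isolation.

What the generator does **not** emulate: real trophectoderm texture,
multi-focal imaging, debris beyond simple bright blobs, partial (sectorial)
collapses, zona breach after biopsy, or correlations between collapse
behaviour and covariates beyond those listed.  Passing closure tests
therefore demonstrates internal consistency of the measurement chain and
correct implementation of the statistics — not performance on clinical
videos.

## Ploidy thresholds

Segment calls use the PGT-A thresholds: aneuploid above 70% aberrant
fraction (strictly), euploid strictly below the chromosome-specific lower
limit (30% for 13/16/18/21, 50% for 19, 40% otherwise — sex chromosomes use
the general limit), mosaic in the closed band between.  The boundary
convention at exactly 70% / the lower limit is unstated in the source
protocols; strict inequalities are used as printed.  Embryo-level:
aneuploid if any segment is aneuploid, else mosaic if any mosaic, else
euploid; subtypes monosomy/trisomy (whole-chromosome events, taking
precedence) and fragment deletion/duplication (segmental only).  Embryos
with whole-chromosome losses *and* gains take the first-listed event's
subtype and are flagged `complex_aneuploidy` so they stay auditable.
Mosaic and no-result embryos are excluded from ploidy associations in the
stats layer, not here.

## Statistics

* **Rates**: euploidy per group (four-way category; post-tB count 0/1/2/3/≥4
  for descriptives; 0/1/>1 binary contrast), with missing — not zero —
  rates for empty groups and exact count conservation.
* **Partitioned χ²**: overall Pearson test on the R×2 table plus all
  pairwise 2×2 partitions at α = 0.008 (0.05 Bonferroni-corrected over the
  six pairs of four groups — the partition scheme itself is a design
  choice).  Expected counts below 5 produce warnings; zero-margin rows are
  excluded with a diagnostic.
* **Trend**: Mantel–Haenszel linear-by-linear association,
  M² = (N−1)r² on 1 df with integer row scores; the signed root is
  reported so reversing the row order flips the sign but not the magnitude.
* **Outcome rates**: per-group rates among transferred euploid embryos with
  Fisher's exact test against the no-collapse reference.
* **Univariate screen**: Mann–Whitney U for continuous variables (chosen
  over ANOVA as the two-group default; no normality switching), χ²/Fisher
  for categorical.
* **Mixed model**: two-level random-intercept logistic regression (embryo
  within cycle), marginal likelihood integrated by adaptive Gauss–Hermite
  quadrature — per cluster the integrand's mode and curvature are found by
  Newton's method (the conditional posterior is concave) and the Hermite
  nodes recentred there.  15 nodes by default; doubling to 31 moves
  coefficients by < 1e-4 on the test fixture.  Covariates are standardised
  internally for optimisation and mapped back.  L-BFGS-B maximisation is
  followed by a damped Newton polish on the numerically differentiated
  objective; non-convergence raises with the gradient norm, and a
  standardised coefficient beyond 5 log-odds per predictor SD triggers a
  separation warning.  Wald 95% CIs from the numerically
  differentiated observed information (profile-likelihood intervals are not
  implemented).  With the random-effect SD pinned at 0 the fit reproduces
  the ordinary logistic MLE to 1e-6.  Complete-case analysis only; no
  imputation.  Predictor encoding for the adjusted model: post-tB collapse
  count 0 (reference)/1/≥2, biopsy day 6 vs 5, ICM B vs A, TE B and C vs A,
  and continuous t8, tSB, tB, ECC3, s3, infertility duration and AMH/100
  (the AMH rescaling matches the reporting convention).

## Calibration experiments and problem sizes

The closure and recovery experiments (`blastotrace.experiments`, rerun by
`scripts/acceptance.py`) use: 1000 single-post-tB-collapse embryos for the
shrinkage and duration closures (each pinning the other axis at its mean,
one factor at a time); 3000 embryos for category-prevalence recovery; and
20 replicate cohorts of ~1072 embryos in ~450 cycles for odds-ratio
recovery, matching the multivariate analysis size.  Closure experiments run
on noiseless traces with a permissive 0.01 trigger — every programmed dip
is genuine, including sub-10% ones from the wide shrinkage law, and the
question is measurement fidelity; detection under the default 0.10 trigger
with noise is exercised by the error-bound suite instead.  The type-I-error
study uses 200 null cohorts of ~600 embryos with the reduced predictor set
and 9 quadrature nodes, keeping the Monte-Carlo study cheap while leaving
the test statistic unchanged in structure.

## Known limitations

* The segmentation is tuned to the schematic rendering contract (bright
  zona, darker cavity); it is a stand-in pipeline for testing the event
  logic, not a clinical image-analysis tool.
* Recovery durations are right-censored by trace end and quantised to the
  frame grid; no sub-frame timing is attempted, and hatching is not
  modelled.
* The mixed model supports a single Gaussian random intercept (no crossed
  or nested factors beyond cycle, no random slopes).
* Odds-ratio recovery at the study's size has substantial replicate
  variance (log-OR SD ≈ 0.30 per cohort, driven by the ~7% prevalence of
  the ≥ 2-collapse exposure); the 20-replicate median inherits some of it.
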