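# Methods

## The measurement

Planar bone scintigraphy (Tc-99m MDP, gamma camera) images skeletal
radiotracer uptake.  Visual reading of joint uptake is subjective; the
quantitative alternative implemented here scores each joint by a
**joint-to-bone uptake ratio**: the mean counts/pixel inside a square region
of interest (ROI) over the joint, divided by the mean counts/pixel inside a
square ROI over a reference bone imaged on the same view.  The ratio cancels
administered activity, physical decay, acquisition time and camera
sensitivity, all of which multiply every pixel of a view equally (the scale
invariance is tested on phantoms).

The inventory is fixed: 64 joints in 14 areas per patient, spread over four
planar views, each view with one reference bone — anterior whole body
(skull; shoulder, sternoclavicular, elbow, knee), posterior pelvis spot
(sacrum; sacroiliac), bilateral feet spot (distal tibia; ankle, tarsal, MTP,
toe IP), bilateral hands spot (distal radius; wrist, thumb IP, MCP, hand
PIP, hand DIP).  The ROI mean averages *all* pixels in the closed square
window — no thresholding, no background subtraction — so the estimator is a
plain arithmetic mean and its Poisson behaviour is analysable.  Joints with
arthroplasty are excluded and propagate as missing values, never zeros.

Ordering of joints (area order, right before left, digits ascending) and
the `joint_id` naming are repository conventions chosen so every exported
table is byte-stable; they carry no clinical meaning.

## Statistics battery

* **Weighted Cohen's kappa** for the two readers' ordinal 1–3 grades, with
  agreement weights `w_ij = 1 − |i−j|/(k−1)` (linear, the default) or
  `1 − ((i−j)/(k−1))²` (quadratic).  The weight scheme materially changes
  the value, so it is an explicit argument.  The confidence interval uses
  the Fleiss–Cohen–Everitt large-sample variance.  Exact percent agreement
  is reported alongside.
* **Lin's concordance correlation coefficient** for the two readers' paired
  continuous ratio measurements, with biased (1/n) moment estimators and a
  Fisher-z interval using Lin's variance.
* **ROC/AUC** by the Mann–Whitney identity (wins + half-ties over all
  positive–negative pairs, computed via midranks), confidence intervals
  from the DeLong placement-value variance, and the **DeLong paired test**
  for comparing the correlated AUCs of two scorers of the same joints.
  When several AUC comparisons are made per joint area, the per-test
  threshold is Bonferroni-corrected (`alpha/k`; 0.05/3 → 0.017).
* **Cutoff analysis**: the operating cutoff maximises Youden's
  J = sensitivity + specificity − 1 over observed score values under the
  fixed positivity rule "score > cutoff ⇒ positive"; J-ties break to the
  lowest cutoff.  Sensitivity, specificity, PPV, NPV and accuracy each get
  an exact Clopper–Pearson binomial interval on their own numerator and
  denominator; a metric with an empty denominator is *undefined*, not 0.
  The same exact-interval method is applied to PPV/NPV/accuracy for
  uniformity, although predictive-value intervals conditioned on the
  observed margins are a known approximation.
* **Group comparison** by Welch's t-test or Mann–Whitney (exact enumeration
  when both groups are ≤ 20 and tie-free, tie-corrected normal
  approximation otherwise), delegated to scipy.
* `counts_from_summary` inverts one-decimal rounding: it enumerates every
  integer confusion table consistent with printed sensitivity/specificity
  and group sizes, which lets published summary rows be checked for
  internal consistency without the raw data.

All percentages round half-away-from-zero to one decimal; ratios print with
2 decimals, AUC and p with 3.

## Synthetic data

### Phantom images

`render_phantom` draws each view as: flat soft-tissue background
(default 20 counts/px), one flat reference-bone square (default
400 counts/px), and one Gaussian-profile hotspot per joint (sigma 3 px),
*truncated to the joint's own ROI window*, with amplitude solved so that the
noise-free ROI mean equals `target_ratio × bone_level` exactly.  Truncation
means disjoint ROI windows guarantee zero cross-talk, so noise-free recovery
is exact to floating precision — the renderer is validated against the
quantifier, not the other way round.  With Poisson noise on, every pixel is
an independent Poisson draw with the noise-free value as its mean; the
recovered ratio is then unbiased with SD ∝ counts^(−1/2) (checked as a
log–log slope of −0.5 over bone levels 100/400/1600 with 300 seeds each).
A requested ratio so low that the hotspot would need negative pixels
(below ~0.04 at the defaults) raises an error rather than clipping.

Image geometry (anterior 1024×256, spots 256×256, 11×11 px ROIs for large
joints, 5×5 px for digits, pixel spacing 2.4 mm) is schematic: the clinical
acquisition's matrix and ROI sizes are not public, so these are repository
defaults, explicit in the ROI table, and every downstream computation is
invariant to them except through counting statistics.

### Cohorts

`simulate_cohort` draws, per patient and joint: an affected flag
(Bernoulli with the area's prevalence), a true uptake ratio from the
group's **log-normal** (positive support and right skew; parameters solved
in closed form from the target mean and SD), two readers' grades from a
latent-threshold model (true ratio + per-reader Gaussian noise and bias,
binned at t1 = 1.2 < t2 = 2.0), two readers' re-measured ratios
(true ratio + N(0, 0.08), floored at 0), an erosion covariate on a random
39.6% X-rayed subset (P(erosion) 0.30 affected / 0.04 nonaffected), and rare
exclusions (rate 11/5952).  Default per-area prevalences and group moments
are the observed study conditions (overall: affected 1.79 ± 0.95,
nonaffected 1.06 ± 0.64, prevalence 12.3%, 93 patients);
`CohortSpec.uniform()` applies the pooled moments to every area.

Reader-model constants are repository choices: grade noise SDs 0.35/0.45
and bias 0/0.05 give moderate inter-reader kappa and visual AUCs below the
ratio AUC, qualitatively matching reported reader behaviour; the ratio
re-measurement noise 0.08 puts the inter-reader CCC near the reported ~0.99
level.  They are not calibrated to reproduce any published per-grade
percentage, and the simulated kappa (~0.50) is not expected to equal the
reported 0.597.

For two log-normal groups the AUC of the true-ratio scorer has the closed
form Φ((μ₁−μ₂)/√(σ₁²+σ₂²)) (log-ratio of a positive–negative pair is
normal); simulation is checked against it, and it against numerical
integration.  With the pooled moments this gives ≈ 0.771 — close to, but
deliberately not identified with, the clinically reported 0.789, which
depends on the real measurement process.

What passing these tests shows: the estimator, the statistics and the
bookkeeping are correct under Poisson counting noise and the stated
distributional structure.  What they do not show: robustness to anatomy,
scatter/attenuation, patient motion, overlapping joints, reader ROI
placement variability — none of which the phantom models.

## Pipeline and sizes

`run_pipeline` chains simulate → render (one Poisson-noisy study per
patient; sub-seed = base seed + patient index) → quantify → evaluate, and
writes three CSV tables (group comparison; AUC comparison of the quantified
ratio against each reader's grading; Youden-cutoff diagnostic performance)
plus a manifest with seeds, versions and row counts.  True ratios below the
renderable floor (0.05) are rendered at the floor.  Degenerate areas
(single class) yield NA cells, not failures.  A full 93-patient run takes a
few seconds; the test and acceptance workloads use 93-patient cohorts,
300-seed noise sweeps and 8 replicate cohorts for AUC pooling — sizes
chosen to keep Monte-Carlo error well inside the asserted tolerances.

## Known limitations

* The phantom is radically schematic; it validates software, not clinical
  performance.
* Large-sample intervals (kappa, CCC, DeLong) are asymptotic; at very small
  n the DeLong p is only loosely comparable to a permutation null (tested
  with a wide band at n = 12).
* PPV/NPV intervals treat the observed test-positive/negative margins as
  fixed binomial denominators.
* Only two readers; no generalized multi-reader kappa, no covariate-adjusted
  ROC, no attenuation/scatter physics.
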