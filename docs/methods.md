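# Methods

This note documents the statistical model behind `uromet`, the defaults
and why they were chosen, what the synthetic-data generator does and does
not emulate, and the numerical conventions that make runs reproducible.

## Data model and preprocessing

A study is a collection of 1D ¹H urine NMR spectra from two groups
(`control`, `study`) sampled at one or more weeks.  Spectra are referenced
by shifting the ppm axis so the intensity argmax inside a search window
(default 0.3 to −0.3 ppm) — the TSP singlet — lands at exactly 0.0 ppm.
Bucketing integrates intensity over configured `[left, right)` ppm
intervals (descending-ppm convention, matching NMR display order) by the
trapezoid rule on the native grid, with the interval boundaries entering as
linearly interpolated points.  That choice makes integration exactly
additive under splitting a bucket, needs no resampling, and is the
simplest rule consistent with vendor bucketing tools.  Negative integrals
(baseline artifacts) are clipped to 0 with a warning because the bucket
matrix is defined non-negative.

The shipped example exclusion regions — water 5.00–4.50, urea 6.20–5.40,
TSP 0.20 to −0.20 ppm — are standard urine-NMR practice.

Each sample row is then divided by its own total so rows sum to 1.  Any
positive normalization constant is equivalent for every downstream
statistic used here (all are location/scale-based within a bucket); 1 is
the cleanest invariant and is asserted to 1e-9.  Normalization is
idempotent and invariant to per-sample dilution factors, which is its
purpose; the cost is compositional coupling (a genuine rise in some
buckets induces a small apparent fall elsewhere), which is inherent to
total-intensity normalization and visible in the synthetic calibration.

## Univariate screen

Per bucket, a two-sided Welch t-test (unequal variances,
Welch–Satterthwaite df) compares groups; a rank-sum alternative sits
behind `method="ranksum"`.  Welch was chosen as the default because
normalized bucket intensities routinely have unequal group variances and
the test is standard in this literature.  Degenerate buckets (zero
variance in both groups) get p = 1 when the means agree and p = 0
otherwise.  Family-wise error across the K buckets is controlled by
Bonferroni: a bucket is significant iff `p < α_total/K` (default
α_total = 0.05; K = 114 gives 4.39·10⁻⁴).  Alongside, the Mann–Whitney
AUC — the probability that a random study sample exceeds a random control
sample, ties ½ — is reported with a two-tailed flag at threshold 0.75
(AUC ≥ 0.75 or ≤ 0.25); the threshold is a package default, exposed as a
flag, since AUC cut-offs are conventionally qualitative.  Log₂ fold
changes are computed on group means of normalized intensities; they feed
the trend matrix.

## PLS-DA

Class membership is encoded y = +1 (study) / −1 (control) and PLS1 is fit
by NIPALS, which for a single response is closed-form per component
(weights `w_a ∝ Xᵀy`, scores `t_a = Xw_a`, loadings
`p_a = Xᵀt_a/t_aᵀt_a`, y-loading `c_a = yᵀt_a/t_aᵀt_a`, then deflation of
X and y).  Defaults: unit-variance scaling (centering plus division by the
n−1 SD) and A = 2 components, because the separation test operates on
two-dimensional score plots; `none` and `pareto` scaling are available.
R²Y per component is `c_a²·t_aᵀt_a / SS_y`; the cumulative value is their
sum (scores are mutually orthogonal).  VIP for bucket k is
`sqrt(K · Σ_a SS_a (w_ak/‖w_a‖)² / Σ_a SS_a)` with `SS_a = c_a² t_aᵀt_a`;
the mean of squared VIPs is exactly 1, which is asserted.

Q²(cum) = 1 − PRESS/SS is estimated by 7-fold cross-validation
(withholding 1/7 of the samples per round).  Folds are assigned by
deterministic interleaving within each class (venetian blinds), which
keeps classes balanced, needs no random seed, and matches common
chemometrics defaults.  Centering and scaling are re-estimated on each
training split so the held-out samples leak no information.  A class with
fewer samples than folds simply appears in fewer held-out sets; a
singleton class is an error.

Numerical conventions: each component's sign is fixed so its
largest-magnitude weight entry is positive, making fits bit-for-bit
reproducible; requesting more components than the matrix rank raises an
error (detected by the deflated `‖Xᵀy‖` falling below 1e-10 of its initial
value).

## Cluster-separation test

The separation of the two score-plot clouds is quantified by the
Mahalanobis distance between centroids with the pooled within-group
covariance, `D² = (m₁−m₂)ᵀ S⁻¹ (m₁−m₂)`,
`S = ((n₁−1)S₁+(n₂−1)S₂)/(n₁+n₂−2)`.  The pooled (not per-group) form is
required for the Hotelling identity below.  D converts to
`T² = (n₁n₂/(n₁+n₂))·D²` and `F = ((n₁+n₂−p−1)/(p(n₁+n₂−2)))·T²` with
p the score dimensionality (2 by default).  This two-sample Hotelling
conversion reproduces the published worked examples this package uses as
regression anchors: D = 6.735 with n₁ = n₂ = 14 gives F = 152.65, and
D = 4.46 with n₁ = n₂ = 19 gives F = 91.86 (91.7 to the precision allowed
by the three-significant-figure D).

Critical values are upper-tail F quantiles.  Two df conventions are
supported.  The default `paper` convention (df₁ = n₁−1, df₂ = n₂−1)
follows the applied literature this package mirrors and reproduces its
printed critical values (2.217 at n₁ = n₂ = 19, 2.577 at n₁ = n₂ = 14);
Monte-Carlo calibration shows it is **anti-conservative** (null rejection
≈ 11% at n = 15/group rather than 5%).  The `hotelling` convention
(df₁ = p, df₂ = n₁+n₂−p−1) is the exact null of the statistic for
multivariate normal clouds and rejects at the nominal rate; users wanting
a calibrated test should select it.  Note also that applying the test to
scores of a PLS-DA model fitted on the same samples inflates separation
under the null (the projection is supervised); the calibration claim
applies to the test itself on given clouds.

## Longitudinal summary

A metabolite is significant in a week when any of its annotated buckets
is (the aggregation is deliberately permissive; bucket-level detail
remains available).  The trend matrix entry for (metabolite, week) is the
log₂ fold change of its largest-magnitude significant bucket, or 0 when no
bucket passed the screen; metabolites are ordered by peak |log₂FC|.  The
matrix is antisymmetric under swapping the group labels.  The heat map's
color scale is the package's own (diverging around 0); masked-to-zero
cells read as "no significant change".

## Enrichment

Over-representation of significant metabolites in user-supplied sets uses
the upper-tail hypergeometric probability `P(X ≥ k)` with
X ~ Hypergeom(N, K_set, n_sig) on the annotated-metabolite universe, Holm
adjusted across sets.  Holm was preferred to Bonferroni across pathways
because set counts are small and Holm is uniformly more powerful.
Topology/impact-weighted pathway scoring is out of scope: it requires
curated pathway graphs, while ORA captures the ranking use-case.

## Synthetic cohorts

The generator emulates the statistical structure the analysis assumes:

* two groups at weeks 1/3/5/7, default n = 15 per group per week;
* 114 buckets: 46 centered on the resonance lines of a 30-metabolite
  library (an editable TSV; shift positions are rounded values from public
  NMR references) and 68 "unassigned resonance" filler buckets placed
  deterministically outside the exclusion regions;
* per-metabolite log-normal concentrations.  Baseline log-SDs
  (0.12; creatinine 0.10, dominant resonance at log-mean ln 3; affected
  metabolites at log-mean ln 0.5) were calibrated once so that the
  generator reproduces the detection regime of the study design it
  emulates — a weak week-1 effect flagging a minority of buckets while
  cluster separation is already significant, and a mid-study effect
  flagging tens of buckets with Q² near 0.9;
* a multiplicative effect on the 8 affected metabolites in the study
  group with default trajectory 1.2/1.6/1.5/1.1 over weeks 1/3/5/7 — the
  rise-then-attenuate pattern of early tumor growth followed by
  senescence;
* Lorentzian lines of FWHM 0.0017 ppm (≈ 1 Hz at 600 MHz), per-sample
  chemical-shift jitter (SD 0.002 ppm), and additive Gaussian noise at 1%
  of the median signal.

Cohort tables are produced from the analytic Lorentzian mass inside each
bucket (the exact limit of integrating a rendered spectrum), which makes
Monte-Carlo calibration cheap; `generate_spectrum` renders full 2¹⁵-point
traces for exercising the spectrum-level path, and the two routes agree
linearly in concentration by construction (asserted at R² > 0.999).  One
master seed determines every draw.

What the generator does **not** emulate: J-coupling multiplets,
pH-dependent shift drift, baseline distortions, correlated metabolite
physiology, and repeated measures of the same animal across weeks
(samples are independent between weeks).  Passing calibration tests
therefore demonstrates correctness of the statistics under the assumed
structure, not robustness to every feature of real urine spectra.

## Calibration results asserted by the test suite

With the defaults above, the test suite asserts: family-wise error of the
Bonferroni screen ≤ 0.05 + 3·SE over 500 null cohorts; null rejection of
the hotelling-convention separation test within 3·SE of 5% over 1000
replicates; mean per-metabolite power ≥ 0.99 at fold 3.0 with
n = 15/group (200 replicates); and the designed mid-study trend peak
recovered for ≥ 90% of affected metabolites across 10 replicate cohorts.
Replicate counts were sized so the suite runs in seconds; the estimates'
Monte-Carlo errors are accounted for in the assertions.

## Known limitations

* The `paper` df convention is reproduced for fidelity but is not a
  calibrated test; use `hotelling` for inference.
* Log₂ fold changes on normalized data inherit compositional coupling;
  strong multi-metabolite effects depress apparent levels of unaffected
  metabolites.
* The bucket-table reader expects one row per sample; transposed layouts
  must be pivoted before ingestion.
* Only two-group designs are supported (no multi-class PLS2, no OPLS-DA,
  no MANOVA-style >2-group separation tests).
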