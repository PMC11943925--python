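# uromet

Longitudinal urine ¹H-NMR metabolic profiling for two-group animal
studies — typically a sham-surgery **control** group against an orthotopic
tumor **study** group sampled at several weeks — implemented as a tested,
reusable Python pipeline.  It is aimed at NMR metabolomics practitioners
who have binned (bucketed) spectra, or raw two-column traces, and want the
complete statistical workflow without spreadsheet- or GUI-bound steps:

1. **Bucketing and normalization** — trapezoidal integration of spectra
   over a configurable bucket scheme (with water/urea/TSP exclusion
   regions), then total-intensity normalization so each spectrum's buckets
   sum to 1.
2. **Univariate screening** — per-bucket two-sided Welch tests (rank-sum
   optional) with Bonferroni family-wise control, `α_b = 0.05/K` for `K`
   buckets; Mann–Whitney AUC (`P(x_study > x_control)`, ties ½) and log₂
   fold changes.
3. **PLS-DA** — from-scratch NIPALS PLS1 with class labels encoded ±1:
   per component `w = Xᵀy/‖Xᵀy‖`, `t = Xw`, `p = Xᵀt/tᵀt`,
   `c = yᵀt/tᵀt`, then deflation.  Reports cumulative R²Y, cross-validated
   Q²(cum) = 1 − PRESS/SS with deterministic venetian-blind folds
   (withholding 1/7 of the samples at a time), and VIP scores
   (mean of VIP² = 1).
4. **Cluster-separation significance** — Mahalanobis distance `D` between
   the two score-plot centroids (pooled covariance), converted to
   Hotelling's `T² = (n₁n₂/(n₁+n₂))·D²` and
   `F = ((n₁+n₂−p−1)/(p(n₁+n₂−2)))·T²`, compared with a critical F.  Two
   degrees-of-freedom conventions are available: `paper`
   (df₁ = n₁−1, df₂ = n₂−1, as used in the NMR profiling literature this
   package follows) and `hotelling` (df₁ = p, df₂ = n₁+n₂−p−1, the
   calibrated textbook null).
5. **Longitudinal trend matrix** — per metabolite per week, the signed
   log₂ fold change masked to 0 when not Bonferroni-significant; rendered
   as a heat map.
6. **Enrichment** — hypergeometric over-representation of significant
   metabolites against a user-supplied metabolite-set library, Holm
   adjusted.
7. **Synthetic cohorts** — a generator with known ground truth (log-normal
   concentrations, Lorentzian lines, shift jitter, an effect trajectory
   that peaks mid-study) for type-I-error, power and recovery analysis.

## Worked example

Generate a synthetic cohort (two groups of 15 at weeks 1/3/5/7, 114
buckets, effect folds 1.2/1.6/1.5/1.1 on 8 affected metabolites) and run
the full per-week analysis:

```bash
uromet simulate --out cohort --seed 42
uromet report --tables cohort/week1.csv --tables cohort/week3.csv \
    --tables cohort/week5.csv --tables cohort/week7.csv \
    --annotation cohort/annotation.tsv --out report
```

prints

```
week 1: 3 significant buckets, R2Y=0.955, Q2=0.544, F=284.61 (F_crit=2.484)
week 3: 22 significant buckets, R2Y=0.993, Q2=0.939, F=1869.72 (F_crit=2.484)
week 5: 20 significant buckets, R2Y=0.983, Q2=0.893, F=801.76 (F_crit=2.484)
week 7: 0 significant buckets, R2Y=0.970, Q2=0.388, F=436.66 (F_crit=2.484)
```

Reading: at week 1 the group effect (fold 1.2) is barely detectable by the
Bonferroni screen (3 of 114 buckets at `α_b = 0.05/114 ≈ 4.4·10⁻⁴`) though
the PLS-DA clusters already separate (F ≫ F_crit); the effect peaks at
weeks 3–5 (20+ significant buckets, Q² ≈ 0.9) and attenuates at week 7
(fold 1.1, no bucket survives the screen, Q² drops to 0.39).
`report/trend_matrix.tsv` holds the metabolites × weeks masked log₂ fold
changes behind `report/trend_heatmap.png`, e.g.

```
metabolite      1       3       5       7
cis-aconitate   0       0.618   0.481   0
succinate       0       0.591   0.323   0
acetate         0.332   0.556   0.399   0
```

— the designed rise-then-return trajectory, recovered from the data alone.

Deposited bucket tables whose metadata columns are named differently are
ingested with remapping flags
(`--sample-col/--group-col/--week-col/--group-map sham=control,orthotopic=study`);
`scripts/validate_deposit.py` wraps this for a whole deposit and prints the
per-week counts, R²Y/Q², D, F and F-critical for side-by-side comparison.

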