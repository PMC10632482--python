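# Methods

This note documents the models, conventions and numerical choices behind
`immunomet`, in the spirit of the methods documentation mature statistical
packages ship with their code. Nothing here states an empirical result that
the test suite or `scripts/acceptance.py` does not itself compute.

## SCENITH parameters

SCENITH treats puromycin incorporation as a per-cell proxy for protein
synthesis, and the drop in the median puromycin MFI under a pathway
inhibitor — relative to the full-suppression anchor (2DG + oligomycin,
"DGO") — as the share of translation that pathway funds. The percent
parameters are ratios of MFI differences; they are computed from
**population medians** (median MFI per condition), not per cell, because a
per-cell ratio of noisy log-normal intensities is far less stable than the
ratio of medians. A per-cell view of metabolic state is provided instead by
the oligomycin quantile binning below.

Conventions:

* **Denominator guard.** C − DGO is the assay's dynamic range. C ≤ DGO is a
  hard error ("no translation dynamic range"); a suppressible fraction
  (C − DGO)/C below `min_dynamic_range` (default 0.2, a QC invention of
  this package, configurable) flags the profile rather than failing it.
* **Clamping.** Measurement noise can produce raw dependencies outside
  [0, 100] (e.g. a 2DG median above control). Reported values are clamped
  to [0, 100] with `clamped_low`/`clamped_high` flags; the capacities are
  recomputed from the clamped dependencies so the complement identities
  (glucose + FAAO = 100, mitochondrial + glycolytic = 100) hold exactly.
  Raw values are always retained, and `clamp=False` exports the unclamped
  convention, since either might be wanted for group comparisons.
* **Harringtonine** arrests elongation outright; it appears in the
  condition vocabulary as a QC anchor only (its MFI should sit at or below
  every other condition's, warned otherwise) and enters no formula.
* **No background subtraction** of unstained controls is applied by
  default; MFIs are analyzed as provided.
* SCENITH fluorescence MFIs are analyzed untransformed; the arcsinh
  transform (cofactor 5) exists for mass-cytometry-style channels and is
  applied only on request. Because the binning is rank-based, transforming
  puromycin does not change bin membership.

## Oligomycin quantile binning

Oligomycin-condition cells are cut at the empirical 25/50/75 percentiles
(linear interpolation) of the pooled puromycin distribution. Bin 4 (highest
residual translation) is glycolytic, bin 1 mitochondrial-dependent.
Boundary ties go to the lower bin — deterministic and order-independent;
the fully degenerate case (all intensities equal) lands everything in bin 1
with a warning. The pooling scope defaults to **cohort** because occupancy
comparisons across clinical groups only make sense against shared
boundaries; a per-sample scope is available for sensitivity analysis (the
right choice when samples were acquired on very different intensity
scales). Per-bin marker contrasts against a reference group use the routed
two-group test (below) with Holm adjustment within each marker;
insufficient cells or zero variance yield an explicit "not-computable" row,
never a silent drop.

## Seahorse indices

Traces are segmented at the injection times (a measurement at exactly an
injection time belongs to the following segment; an empty segment is an
error naming the injection). Segment summaries default to: pre-oligomycin
→ mean (stable basal plateau), post-FCCP → maximum (the uncoupled peak),
post-oligomycin and post-rotenone/antimycin A → minimum (the suppressed
floors). These mirror common instrument-report conventions; all four are
configurable, and the configuration actually used is recorded in the output
metadata because index values near segment edges depend on it. Negative
indices are reported with a QC warning, never clipped — a negative spare
capacity is a visible well failure, not a value to hide. Replicate wells
(triplicates in the underlying assay design) are averaged at the index
level; with linear (mean) aggregators this commutes with averaging the
wells first. The exogenous-FAO contrast is control minus
palmitate+etomoxir post-FCCP OCR, with the pairing always explicit in
config — the sign convention (positive when blocking β-oxidation lowers
the FCCP response) is this package's documented choice. Index scaling for
display uses sample-SD z-scores (ddof = 1, the R `scale()` convention) or
min–max.

## Supernatant flux and ELISPOT

Interval fluxes difference consecutive observations; a media change inside
an interval resets the starting concentrations to the fresh-medium values
(the observation opening the interval is read before the change — the
day-3 protocol event). A change without a specified fresh glucose
concentration is an error rather than a guess. The glucose→lactate
conversion fraction uses the standard glycolytic yield of 2 lactate per
glucose; since that stoichiometric convention is not universal, the raw
lactate/glucose ratio is exported alongside it. Fractions above 1 are
flagged (exogenous lactate source or measurement error), not clipped.
Meter-unit helpers convert clinical mg/dL to mM (glucose ÷ 18.016,
lactate ÷ 9.008).

ELISPOT positivity: after subtracting the AdVLacZ background (floored at 0
— background subtraction cannot create negative responses), a response is
positive when the post net count exceeds 10 spots/well and is at least
twofold over baseline. The baseline is floored at 1 net spot so the fold
criterion is defined for zero baselines.

## Survival statistics

Kaplan–Meier, the log-rank test, maxstat cutpoints, univariate Cox and the
Holm/BH adjustments are implemented in this package and validated against
brute-force oracles (exhaustive scans, grid likelihood maximization,
hand product-limit computation) and against `lifelines` in the test suite;
classical kernels (Shapiro–Wilk, t/rank tests, Spearman, ANOVA, Tukey HSD)
are delegated to scipy/statsmodels.

* **Cox ties:** Efron's approximation, the default of mainstream survival
  software. The single-covariate Newton iteration is run on a standardized
  covariate with step damping (±2 per step); a standardized coefficient
  walking past |β| > 15 indicates a monotone partial likelihood (complete
  separation) and the fit is flagged non-estimable instead of reporting an
  astronomically large finite hazard ratio.
* **maxstat:** candidates are observed covariate values with quantile rank
  strictly inside (0.1, 0.9); each is scored by the absolute standardized
  log-rank statistic |O − E|/√V of its dichotomy; ties take the smaller
  cutpoint. The log-rank p at the winner ignores the selection and is
  labeled `p_uncorrected`; a permutation p (covariate permuted, full
  selection re-run, seeded) is offered because the selection inflates the
  type-I error — a property the test suite demonstrates on null data
  rather than hides. No closed-form corrected-p approximation is
  implemented.
* **Two-group routing:** Shapiro–Wilk per group at α = 0.05; both groups
  must pass for Student's t, otherwise the Wilcoxon **rank-sum** test for
  unpaired designs (the signed-rank variant is reserved for explicitly
  paired data — applying a signed-rank test to unpaired groups would be a
  design error, so the unpaired default is deliberate). The test actually
  used is recorded in every result row.
* **Differential markers:** per-marker linear model of log2 per-sample
  medians on the group indicator; the coefficient is the log2 fold change;
  BH across markers.

## Synthetic-cohort generator

The generator is first-class, tested code; its defaults are the study
conditions the analysis was built around: 13 good-outcome and 17
bad-outcome patients (survival records for all 30), mitochondrial
dependence truth 84.4% (good) vs 76.4% (bad), glutaminolysis ~7 points
lower in the bad group, a 25 mM-glucose medium with a day-3 media change,
and the full C/2DG/O/Eto/Tele/DGO/H inhibitor panel.

* **Inhibitor model.** Expected condition median is
  `C · (1 − d_i (1 − b))` with `d_DGO = 1` and background fraction
  `b = 0.05` — the simplest model consistent with the SCENITH formulas
  (exact recovery in the zero-noise limit), a modeling convenience and not
  a claim about inhibitor pharmacology.
* **Noise.** Per-cell puromycin is log-normal (σ = 0.35) around the
  condition median: positive, right-skewed, like fluorescence intensities.
  Between-sample truth jitter (σ = 0.02 on the dependence fractions) gives
  cohorts realistic spread; recovery tests that need an exact truth set it
  to 0.
* **Latent coupling.** Each cell carries a latent glycolytic score
  z ~ N(0, 1) that shifts its log-intensity under oligomycin
  (median-preserving) and shifts marker log-means by per-marker coupling
  coefficients — so marker medians rise (or fall, for anti-coupled
  markers) monotonically across the oligomycin bins, the structure the
  binning analysis assumes.
* **Seahorse / supernatant / survival.** Plateau segments at configured
  group means plus Gaussian noise (SD 5 on OCR); linear glucose decline and
  lactate rise at group rates with the day-3 reset; exponential
  proportional-hazards event times with the hazard multiplied by
  `hr_high_mito` (default 0.45, protective) above the 80% mitochondrial-
  dependence threshold, and independent exponential censoring tuned to the
  target rate (default 20%).
* **Determinism.** One master seed is split through named `SeedSequence`
  sub-streams (cells / traces / flux / survival, keyed further by sample),
  so outputs are pure functions of (config, seed) and adding a generator
  never shifts an existing stream.

What the generator does **not** emulate: spectral spillover/compensation,
doublets, debarcoding artifacts, batch and acquisition drift, non-log-normal
population mixtures, or informative censoring. Passing the closed-loop
tests therefore shows the analysis code is correct under the stated model,
not that real instruments satisfy that model.

## Problem sizes and tolerances

Closed-loop recovery uses 5 000 cells/condition (recovery within ±3
percentage points across 20 seeds); Cox recovery uses n = 500 with true
HR 2.0 and 20% censoring (95% CI coverage ≥ 17/20 seeds); oracle-equality
checks run on n ≈ 40 survival datasets and 5 000-cell binning tables; the
end-to-end determinism smoke uses a 12-patient, 200-cell cohort. These
sizes were chosen so the whole validation cycle runs in seconds while
keeping Monte-Carlo margins comfortable. Identity assertions (complements,
Seahorse index algebra) are exact to 1e−9 or better; parameter-recovery
tolerances are stated with each check.

## Known limitations

Single-covariate Cox only (no multivariable adjustment, time-varying
covariates or competing risks); rectangular threshold gating only (no
auto-gating — thresholds must be explicit); FCS support covers the
list-mode float subset modern instruments export, not integer/ASCII data
types or multi-dataset files; the maxstat permutation p is the only
selection-corrected inference offered.
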