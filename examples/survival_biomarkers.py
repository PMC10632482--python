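"""Metabolic-biomarker survival association on a synthetic patient cohort.

Generates a 30-patient cohort whose hazard depends on mitochondrial
dependence, selects the biomarker cutpoint by maximally selected rank
statistics, and reports the univariate Cox hazard ratio, log-rank test and
Kaplan-Meier summary for the high/low split.
"""

import numpy as np

from immunomet.simulate import SyntheticCohortConfig, generate_survival_cohort
from immunomet.stats import cox_univariate, km_estimate, logrank_test, maxstat_cutpoint

config = SyntheticCohortConfig(seed=5, hr_high_mito=0.4, censoring_rate=0.2)
cohort = generate_survival_cohort(config)
print(f"cohort: {len(cohort)} patients, {cohort['os_event'].sum()} deaths observed")

x = cohort["mitochondrial_dependence"].to_numpy()
cut = maxstat_cutpoint(x, cohort["os_months"], cohort["os_event"],
                       covariate="mitochondrial_dependence", permutations=200, seed=5)
print(
    f"\nmaxstat cutpoint: {cut.cutpoint:.1f}% "
    f"(standardized statistic {cut.statistic:.2f}; "
    f"{cut.n_high} high / {cut.n_low} low)\n"
    f"  uncorrected log-rank p: {cut.p_uncorrected:.4f} "
    f"(selection-inflated); permutation p: {cut.p_permutation:.3f}"
)

high = (x > cut.cutpoint).astype(int)
cox = cox_univariate(cohort["os_months"], cohort["os_event"], high)
lr = logrank_test(cohort["os_months"], cohort["os_event"], high)
print(
    f"\nCox (high vs low): HR {cox.hazard_ratio:.2f} "
    f"[{cox.ci_low:.2f}, {cox.ci_high:.2f}], Wald p {cox.p_value:.4f}; "
    f"log-rank p {lr.p_value:.4f}"
)
for label, mask in (("high", high == 1), ("low", high == 0)):
    km = km_estimate(cohort.loc[mask, "os_months"], cohort.loc[mask, "os_event"])
    t = 24.0
    print(f"  KM S(24 mo) {label}-mitochondrial group: {km.survival_at(t)[0]:.2f}")
print(
    "\nAn HR below 1 for the high group reproduces the protective direction "
    "the generator was configured with: higher mitochondrial dependence, "
    "longer overall survival."
)
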