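"""Cohort characterization: expressor bins, subgroup association and
survival stratified by expression.

Simulates a 300-patient cohort where high expressors carry a planted
hazard ratio of 0.63 for overall survival (records are censored at
transplantation when applicable), then bins expression, tests association
with FAB subgroups, and fits Kaplan-Meier / Cox models.
"""

import math

from lincscout.cohort import (
    bin_expressors,
    group_association,
    km_logrank,
    median_split,
    ph_multivariable,
)
from lincscout.simulate import SimConfig, generate_cohort_metadata

cfg = SimConfig(seed=42)
meta, records, _, truth = generate_cohort_metadata(cfg)

labels, bins = bin_expressors(meta["expression"])
print("expressor bins (log2(CPM+1): 0 / (0,0.5] / (0.5,2] / (2,inf)):")
print(bins.to_string())

h, p, dunn = group_association(meta["expression"], meta["FAB"])
print(f"\nKruskal-Wallis across FAB groups: H={h:.2f}, p={p:.3g}")

strata = median_split(meta["expression"])
curves, chi2, p_lr = km_logrank(records, strata)
print(f"log-rank high vs low expressors: chi2={chi2:.2f}, p={p_lr:.4f}")

ph = ph_multivariable(records, ["high_expressor", "NPM1", "FLT3_ITD",
                                "age_scaled"])
print("\nmultivariable proportional-hazards fit:")
print(ph.round(3).to_string())
print(f"\nplanted hazard ratio for high expressors: "
      f"{math.exp(truth.survival_beta):.2f}")

# High expressors show better survival: the fitted HR for high_expressor
# estimates the planted 0.63 (within sampling noise at n=300), while the
# nuisance covariates stay near HR = 1.
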