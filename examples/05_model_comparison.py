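"""Model comparisons: random-intercept deviance test and model complexity.

First compares the full additive model against a reduced model without the
patient random intercept (analysis of deviance): once the past-mean smooth
is in the model it absorbs most patient-level variation, so the random
intercept adds little.  Then compares the plain spec against a richer one
with gender-specific past-mean smooths on a ~100-patient subset: the richer
model can win on AIC yet lose on held-out error — the overfitting pattern
that argues for the simpler model in practice.
"""

import dataclasses

from hbmon import (
    ModelSpec,
    PipelineConfig,
    SyntheticConfig,
    compare_models,
    fit_additive_model,
    run_subset_comparison,
)
from hbmon.preprocess import build_model_rows, deduplicate_same_day, holdout_split
from hbmon.syncohort import generate_cohort

cohort, _ = deduplicate_same_day(generate_cohort(SyntheticConfig(n_patients=150, seed=5)))
split = holdout_split(build_model_rows(cohort))

spec = ModelSpec()
full = fit_additive_model(split.train, spec)
reduced = fit_additive_model(split.train, dataclasses.replace(spec, random_intercept=False))
rep = compare_models(full, reduced, split.train)
print("analysis of deviance (full vs no-random-intercept):")
print(f"  residual deviance {rep.deviance_full:.1f} vs {rep.deviance_reduced:.1f}")
print(f"  F = {rep.f_statistic:.4f}, p = {rep.p_value:.3f}")
print(f"  random-intercept edf: {full.edf_by_term['random(patient_id)']:.3f}")

config = PipelineConfig(synthetic=SyntheticConfig(n_patients=150), seed=5)
cmp = run_subset_comparison(config, n_patients=100)
print(f"\nsubset of {cmp.n_patients} patients, simple vs by-gender-smooths model:")
print(f"  AIC:  {cmp.aic_simple:.1f} vs {cmp.aic_sophisticated:.1f}")
print(f"  MSPE: {cmp.mspe_simple:.4f} vs {cmp.mspe_sophisticated:.4f} mmol^2/L^2")
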