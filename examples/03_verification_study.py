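"""Nested case-control verification of one flagged outcome.

Simulates a two-drug new-user cohort in which the outcome's hazard is 1.5x
during current use of the target drug and unaffected by the active
comparator. Incident cases are matched to up to 10 risk-set controls (same
sex, provider, age within a year, still at risk at the case's time in
cohort), exposure is classified at the index day, and a conditional
logistic model estimates the odds ratio for current target vs current
single comparator use — which should recover the injected 1.5.
"""

from pvborda import (
    HealthOutcome,
    build_exposure_windows,
    classify_index_exposure,
    clr_fit,
    identify_cases,
    risk_set_match,
    simulate_cohort,
    verification_fixture,
)
from pvborda.simulate import COMPARATOR_ATC, TARGET_ATC

config = verification_fixture(n_patients=30_000, conditional_or=1.5, seed=2)
tables, _ = simulate_cohort(config)
outcome = HealthOutcome("flagged outcome", ["Y570"])

cases = identify_cases(tables, outcome, washout_days=365)
matched = risk_set_match(cases, tables.persons, tables.diagnoses, outcome, m_max=10, seed=3)
n_controls = (matched["role"] == "control").sum()
print(f"{len(cases)} incident cases, {n_controls} sampled controls "
      f"({n_controls / len(cases):.1f} per case)")

windows = {
    "target": build_exposure_windows(tables.dispensations, TARGET_ATC, config.grace_days),
    "comparator": build_exposure_windows(tables.dispensations, COMPARATOR_ATC, config.grace_days),
}
categories = classify_index_exposure(matched, windows)
print("exposure at index day:", categories.value_counts().to_dict())

for contrast in ("target_vs_comparator", "target_vs_none"):
    fit = clr_fit(matched, categories, contrast=contrast)["crude"]
    print(
        f"{contrast}: OR = {fit.or_:.2f} "
        f"(95% CI {fit.ci95[0]:.2f}-{fit.ci95[1]:.2f}), "
        f"{fit.n_sets_informative} informative sets"
    )
print(
    "\nBoth contrasts estimate the injected hazard ratio of 1.5; the "
    "confidence interval for the active-comparator contrast is wider "
    "because fewer subjects are on the comparator at their index day."
)
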