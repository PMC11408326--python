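"""Four-detector ensemble on a small synthetic claims cohort.

Simulates a tiny new-user cohort with known ground truth (codes whose rate
triples during target-drug exposure, bystander codes tied to a co-prescribed
drug, indication-confounded codes, and pure-noise codes), scores every code
with BCPNN, the longitudinal gamma-Poisson shrinker, an L1-penalized
logistic screen and a shadow-corrected random forest, and aggregates the
four rankings by Borda count.
"""

from pvborda import (
    EligibilityRules,
    StrataConfig,
    apply_eligibility,
    bcpnn_scores,
    borda_aggregate,
    build_analysis_matrix,
    build_exposure_windows,
    build_pair_counts,
    build_person_time,
    default_fixture,
    fit_gps_prior,
    gps_scores,
    kendall_tau_matrix,
    lasso_scores,
    lgps_expected,
    rf_scores,
    scores_to_ranking,
    simulate_cohort,
)
from pvborda.simulate import TARGET_ATC

config = default_fixture("tiny", seed=1)
tables, truth = simulate_cohort(config)
print(f"{tables.n_patients} patients, {len(tables.diagnoses)} diagnosis rows")

rules = EligibilityRules(
    target_atc=TARGET_ATC, washout_atc_prefixes=("B01AF", "B01AA"), require_target_use=False
)
eligible = apply_eligibility(tables, rules).eligible_ids
matrix = build_analysis_matrix(tables, eligible, TARGET_ATC, min_count=3)
print(f"analysis matrix: {len(matrix.data)} patients x {len(matrix.adr_codes)} codes, "
      f"{int(matrix.y.sum())} exposed")

bc = bcpnn_scores(build_pair_counts(matrix))
windows = build_exposure_windows(tables.dispensations, TARGET_ATC, config.grace_days)
pt = build_person_time(tables, windows, StrataConfig(), eligible_ids=eligible,
                       codes=matrix.adr_codes)
oe = lgps_expected(pt)
prior = fit_gps_prior(oe["O"].to_numpy(), oe["E"].to_numpy(), seed=1)
gs = gps_scores(oe["O"].to_numpy(), oe["E"].to_numpy(), prior, codes=oe.index)
lf = lasso_scores(matrix, cv_folds=3, n_lambda=8, seed=1)
rf = rf_scores(matrix, n_trees=200, repeats=1, seed=1)

rankings = [
    scores_to_ranking(bc["ic025"], "bcpnn"),
    scores_to_ranking(gs["eb05"], "lgps"),
    scores_to_ranking(lf.scores["score"], "lasso"),
    scores_to_ranking(rf.scores["score"], "rf"),
]
result = borda_aggregate(rankings)
top = result.table.head(6).join(truth.set_index("icd")["class"])
print("\ntop of the Borda ranking (smaller count = stronger signal):")
print(top)
print("\nKendall tau-b agreement between the four method rankings:")
print(kendall_tau_matrix(rankings).round(2))
print(
    "\nCodes whose event rate truly rises during exposure ('true') should "
    "dominate the top ranks; 'null' codes should drift to the bottom."
)
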