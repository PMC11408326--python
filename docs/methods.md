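# Methods

This note documents the statistical models implemented in `pvborda`, the
conventions adopted where several were defensible, the synthetic-data
generator used as the test substrate, and the limits of what the package's
tests demonstrate.

## Data model and conventions

The substrate is three longitudinal claims-style tables: persons (sex,
birth year, cohort entry/exit, provider), dispensations (ATC code, date,
days of supply) and diagnoses (ICD-10 code, date, inpatient flag). All date
intervals are closed; person-time is counted in years of 365.25 days; ICD
codes are normalized to dotless upper case ("K92.2" → "K922"). Validation
raises on schema violations and drops (with counts) rows that are
internally inconsistent or refer to unknown patients.

A *current-use window* for a drug is
[dispense date, dispense date + supply days + grace − 1] with a default
grace of 14 days, merged per patient when windows overlap or abut. The
14-day grace is the usual claims convention for imperfect adherence and
stockpiling; the same value is used in detection (person-time attribution)
and verification (index-day exposure), so exposure is classified one way
throughout.

New-user eligibility follows three rules applied in order, each logged in
an attrition table: (1) at least 12 months of continuous enrollment,
(2) for exposed membership, a first target dispensation at least 90 days
after cohort entry, (3) no dispensation of the washout drug class (the
target's anticoagulant class by default) in the 365 days before entry. The
binary-outcome detectors need unexposed rows, so the detection cohort keeps
patients satisfying (1) and (3) as the unexposed pool, with (2) defining
exposure; `EligibilityRules.require_target_use` restores a strict
users-only filter.

The event indicator aⱼ for code j is evaluated in an *at-risk window*:
first exposure onward for exposed patients, and from a pseudo-index at
entry + 90 days (mirroring the exposure run-in) for unexposed ones, so that
both groups have comparable observation opportunity. Codes with fewer than
`min_count` = 5 positive patients are dropped and listed; the threshold
prevents degenerate detector fits on near-empty columns.

The cohort can be split into disjoint detection and verification halves
(seeded permutation) so that the ranking and the confirmatory study do not
reuse the same observations.

## Detectors

**BCPNN.** The implemented variant is the simplified information component
with ½-shrinkage terms, IC = log₂((n₁₁+½)/(E₁₁+½)), E₁₁ = n₁·n·₁/n, and
IC025 = log₂ of the 2.5% quantile of a Gamma(n₁₁+½, rate E₁₁+½) posterior —
not the original Dirichlet network formulation. This is the variant in
routine modern use; it is finite for every input including n₁₁ = 0 and
converges to the crude log₂ observed/expected ratio as counts grow (a
property the tests check at ×10 and ×100 scalings). Ranking uses IC025
(conservative).

**LGPS.** Expected exposed counts are indirectly standardized from
stratified person-time, E = Σₛ PTₑₓₚ,ₛ · Oᵤₙₑₓₚ,ₛ/PTᵤₙₑₓₚ,ₛ, with strata
sex × 10-year age band at entry (configurable). Strata with zero unexposed
person-time are dropped with a warning rather than patched with a
continuity correction — fabricating an unexposed rate there has no basis.
The follow-up of each patient is partitioned into exposed/unexposed by the
merged current-use windows; the first occurrence of each code per patient
is attributed to the state at its event date. Age is fixed at its
entry-date band for the whole follow-up, a deliberate simplification (age
bands are wide relative to the ≤3-year follow-up of the packaged cohorts).

The shrinkage model is DuMouchel's two-component gamma mixture prior on the
relative rate λ: w·Gamma(α₁,β₁) + (1−w)·Gamma(α₂,β₂). The marginal of O
given E under a Gamma(α,β) component is negative binomial with size α and
success probability β/(β+E); the prior is fitted by maximizing the mixture
marginal log-likelihood over (log α₁, log β₁, log α₂, log β₂, logit w)
with Nelder–Mead restarted from DuMouchel's classic values
(0.2, 0.1, 2, 4, ⅓) plus nine seeded perturbations (the likelihood is
multimodal). The search is boxed at ±12 on the log scale: outside that box
the negative-binomial pmf overflows and the apparent likelihood is
numerical garbage (candidate optima with positive discrete log-likelihood
are rejected for the same reason). With a single (O, E) pair the fit is
hopeless and the fixed DuMouchel prior is returned with a warning.

The posterior of λ is again a two-gamma mixture with components
(αₖ+O, βₖ+E) and weight q from the component marginals. EBGM = exp E[ln λ]
uses the digamma closed form per component; EB05 solves mixture-CDF = 0.05
by bracketed Brent root-finding (bracket grown geometrically, 1e-12
tolerances). Ranking uses EB05 by default; EBGM is available.

**LASSO.** A single L1-penalized logistic regression of the exposure
indicator on *all* retained event indicators plus covariates (age at
entry, sex). This direction — exposure as outcome — yields one joint model
in which each code's coefficient is adjusted for all others; a
per-code-outcome regression is the natural alternative but does not give a
single joint screen for one drug. Predictors are standardized internally;
the intercept and covariates are unpenalized (per-coefficient penalty
weights in the statsmodels L1 solver). The penalty is selected on a
log-spaced grid from just above λ_max (the KKT bound at the null model)
down to λ_max/1000 by K-fold cross-validated deviance at its *minimum*;
the 1-SE rule would collapse more coefficients into the tie at zero and
blunt the ranking. Scores are |β| at the selected penalty; codes dropped
by the penalty tie at 0.

**Random forest.** A classification forest for the exposure indicator on
event indicators plus covariates. Raw impurity importance is biased, so the
corrected version is computed by pseudo-variables: the design is augmented
with an independently permuted copy (shadow) of every event column, the
forest is fitted on the augmented design, and
importanceⱼ = impurity(xⱼ) − impurity(shadowⱼ), averaged over `repeats`
seeded repetitions. A shadow preserves its column's marginal distribution
but is independent of the outcome, so it estimates exactly the bias its
original would receive under the null; corrected importances of null
features center at zero and may legitimately be negative. This
pseudo-variable construction is statistically equivalent in target to the
streaming corrected-impurity implementations in specialized forest
libraries but runs on any backend. Defaults: 500 trees, mtry = ⌊√p⌋,
3 repeats.

## Borda aggregation and triage

Scores become ranks with rank 1 = strongest signal. Ties are handled
tournament-style as competition ranking (1-2-2-4): tied items share the
best position of their block and the next block skips by the block size,
which keeps Borda counts integral under unit weights; midranks
(1-2.5-2.5-4) are available behind a flag. Missing scores (a method failed
on a code) rank last — absence of evidence is treated as no signal, and
logged. The Borda count is the weighted sum of per-method ranks (unit
weights by default; scaling all weights by a constant cannot change the
final ranking). Final ranks re-apply competition ranking to the counts;
within tied counts the display order is alphabetical, which never affects
a rank. Relative rank (rank−1)/(P−1) ∈ [0,1] (defined as 0 when P = 1) is
the triage axis: 0 = strongest signal, 1 = none. Method agreement is
summarized by Kendall τ-b, the tie-corrected variant, since competition
rankings contain ties by construction; a constant ranking yields an
undefined (reported missing, never 0) correlation. Health outcomes are
named code sets; triage reports each member's relative rank plus min and
median per outcome.

## Verification study

Incident cases of an outcome are patients whose first member-code
diagnosis falls at or after entry + 365 days, with no member code during
the washout window (the 365-day default stands in for an unspecified
incidence washout; configurable). Risk-set sampling on the time-in-cohort
axis selects, for each case at time t since entry, up to 10 controls
uniformly without replacement from patients who: are still under follow-up
at their own entry + t (their control index day), match the case's sex and
provider, are within ±1 year of the case's age at index (ages are integer
years from birth year — the schema carries no birth date), have no outcome
diagnosis on or before their control index day, are not hospitalized
(inpatient-flagged diagnosis) on that day, and are not the case. Future
cases are eligible before their own index and a person may serve as
control repeatedly — the properties that make the conditional-logistic
odds ratio estimate the incidence-rate ratio. Sampling is seeded per case
over a canonically sorted candidate list, so matched sets are reproducible.
Cases with zero eligible controls are retained and flagged; they carry no
likelihood information but belong in the audit trail. An independent
validator (`audit_matched_sets`, deliberately sharing no code with the
sampler) re-checks every emitted control.

Exposure at the index day is one of {target only, comparator only, both,
none} from window coverage. For the active-comparator contrast, subjects
in {both, none} are excluded set-wise (sets losing their case or all
controls are dropped and counted); the vs-none contrast excludes
comparator users analogously. The conditional likelihood
Π exp(x_case β)/Σ_j exp(x_j β) is maximized by Newton's method
(statsmodels `ConditionalLogit`); on 1:1 binary designs this equals the
discordant-pair ratio, which the tests verify to 1e-8. Wald 95% CIs are
reported. Sets without exposure variation are uninformative; if none are
informative the fit raises, and one-sided discordance (an infinite MLE) is
reported as non-estimable rather than as a large number.

## Synthetic-cohort generator

The generator emulates the structures that make claims-based screening
hard: a new-user cohort with age/sex structure; a latent indication whose
probability rises with age and which drives exposure odds (logit P(target)
= −2.2 + 0.3·(age−65)/10 − 0.1·female + 1.5·indication, ≈15–20% exposed at
the default age distribution of 70 ± 10); a bystander drug co-prescribed
with the target (probability 0.6, sharing the target's episode timing) and
present at a background rate 0.15 otherwise; and an active comparator
taken up preferentially by indicated non-users of the target and mutually
exclusive with it at initiation, mirroring a new-user active-comparator
design. Treatment episodes start 90–180 days after entry, last
exponential-mean-400-days, and are dispensed in 30-day supplies.

Event codes follow per-patient, per-code piecewise-constant-rate Poisson
processes: a `true` code's baseline rate is multiplied during target
current use (including grace), a `bystander` code's during bystander use,
an `indication` code's whenever the indication is present, and `null`
codes stay at baseline. Every event is emitted as a diagnosis row
(recurrences allowed), so indicator and person-time reductions are both
meaningful. The indication itself is recorded as a diagnosis at entry.
Everything derives from one seeded generator; identical configs produce
byte-identical CSV output.

Packaged fixtures: `tiny` (600 patients, 15 codes over all four classes,
inflated rates) exercises the full pipeline in seconds; `small` (20,000
patients, 12 true + 208 null codes, baseline rates 0.005–0.04/year,
multiplier 3) is the signal-recovery condition — its signal content is
true + null codes because the recovery question is separating real effects
from noise, while bystander/indication confounding is studied with
dedicated configs (confounded codes are *statistically* real associations
and belong in the ranking's top, not among the nulls);
`verification_fixture` builds the two-drug cohort (default 50,000
patients, outcome baseline 0.03/year, injected conditional OR applied
during target current use only) used for coverage checks.

What the generator does not emulate: coding-practice artifacts (rule-out
and upcoding), protopathic bias, seasonal or calendar trends, dose
titration, age advancing during follow-up, or margins calibrated to any
real database. Passing recovery tests therefore demonstrates internal
statistical correctness of the pipeline under its own assumptions, not
performance on real claims data.

## Problem sizes used by the test suite

Test and example runs are scaled to the packaged study conditions: the
ensemble-recovery check runs the small fixture over 3 seeds with 3-fold
CV over 8 penalty values for the LASSO and a 200-tree single-repeat
forest; the coverage check uses 20 seeded 50,000-patient replicates; the
sampling oracles use 10⁶ posterior draws; the Borda brute-force
equivalence uses 1,000 random instances. Detector defaults (5-fold CV,
500 trees × 3 repeats) are the recommended analysis settings.

## Known limitations

- The detection analysis contrasts patients (indicator reduction) for
  BCPNN/LASSO/RF and person-time for LGPS; a person-time variant of the
  2×2 reduction is not provided.
- Matching is strict on provider; very small provider strata can leave
  cases with few or zero controls (flagged, never silently dropped).
- Confounder adjustment in the verification stage takes user-supplied code
  lists (history indicators evaluated at each subject's index day); no
  propensity scores or weighting.
- The LGPS prior fit assumes enough pairs (≥ 10 recommended) to identify a
  two-component mixture; below that it warns, and with one pair it falls
  back to the fixed DuMouchel prior.
- No multi-drug exposure matrices beyond target + comparator + bystander,
  and no ICD-9/ICD-11 mapping.
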