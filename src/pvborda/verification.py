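"""Signal verification: nested case-control study with risk-set sampling.

Cases are incident diagnoses of an expert-defined health outcome. Each case
is matched with up to ``m_max`` controls drawn by risk-set sampling on the
time-in-cohort axis: a control must still be under follow-up at the case's
time since entry, match on sex, provider (statutory health insurance) and age
at index day within one year, must not yet have had the outcome at their own
index day, and must not be hospitalized on that day. Future cases are
eligible as controls before their own index, and one person may serve as
control for several cases — the sampling scheme under which the conditional
logistic odds ratio estimates the incidence-rate ratio.

Exposure is classified at the index day from current-use windows for the
target and the active comparator, and effects are estimated by conditional
logistic regression on the matched sets (crude and confounder-adjusted).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .borda import HealthOutcome
from .cohort import CohortTables

logger = logging.getLogger(__name__)

_DAY_KEY = 1 << 20  # packs (person ordinal, day) into one int64


def identify_cases(
    tables: CohortTables, outcome: HealthOutcome, washout_days: int = 365
) -> pd.DataFrame:
    """Incident cases: first member-code diagnosis after the washout period.

    A patient qualifies if the first occurrence of any member code inside
    follow-up falls at or after entry + ``washout_days`` and no member code
    occurs in the washout window [entry, entry + washout). Returns one row
    per case with index_day and t_index (days since entry).
    """
    persons = tables.persons[["patient_id", "cohort_entry", "cohort_exit"]]
    d = tables.diagnoses[tables.diagnoses["icd"].isin(outcome.codes)]
    d = d.merge(persons, on="patient_id")
    washout_end = d["cohort_entry"] + pd.to_timedelta(washout_days, unit="D")
    in_washout = (d["event_date"] >= d["cohort_entry"]) & (d["event_date"] < washout_end)
    qualifying = (d["event_date"] >= washout_end) & (d["event_date"] <= d["cohort_exit"])

    disq = set(d.loc[in_washout, "patient_id"])
    q = d[qualifying & ~d["patient_id"].isin(disq)]
    if q.empty:
        return pd.DataFrame(columns=["patient_id", "outcome", "index_day", "t_index"])
    first = q.groupby("patient_id").agg(
        index_day=("event_date", "min"), cohort_entry=("cohort_entry", "first")
    )
    out = first.reset_index()
    out["outcome"] = outcome.name
    out["t_index"] = (out["index_day"] - out["cohort_entry"]).dt.days
    return out[["patient_id", "outcome", "index_day", "t_index"]].sort_values(
        "patient_id"
    ).reset_index(drop=True)


def risk_set_match(
    cases: pd.DataFrame,
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    outcome: HealthOutcome,
    m_max: int = 10,
    seed: int = 0,
    age_tolerance: int = 1,
    exclude_hospitalized: bool = True,
) -> pd.DataFrame:
    """Sample risk-set controls for each case.

    Returns a long frame with one row per subject: set_id, role
    ('case'/'control'), patient_id, index_day, t_index, and per-set control
    count m. Cases with zero eligible controls are retained (flagged m=0);
    they carry no information in the conditional likelihood but belong in
    the audit trail.
    """
    if m_max < 1:
        raise ValueError("m_max must be >= 1")
    pers = persons.sort_values("patient_id").reset_index(drop=True)
    pid = pers["patient_id"].to_numpy()
    origin = pers["cohort_entry"].min().normalize()
    entry = (pers["cohort_entry"] - origin).dt.days.to_numpy()
    exit_ = (pers["cohort_exit"] - origin).dt.days.to_numpy()
    birth_year = pers["birth_year"].to_numpy()
    pos = pd.Series(np.arange(len(pers)), index=pid)

    max_day = int(exit_.max()) + 2
    day_to_year = (origin + pd.to_timedelta(np.arange(max_day), unit="D")).year.to_numpy()

    # first outcome date (any time) per person, +inf if never
    d = diagnoses[diagnoses["icd"].isin(outcome.codes)]
    first_outcome = np.full(len(pers), np.iinfo(np.int64).max, dtype=np.int64)
    if not d.empty:
        fo = (d["event_date"] - origin).dt.days.groupby(d["patient_id"]).min()
        first_outcome[pos.reindex(fo.index).to_numpy()] = fo.to_numpy()

    # inpatient diagnosis (person, day) keys for the hospitalization exclusion
    hosp_keys = np.array([], dtype=np.int64)
    if exclude_hospitalized:
        h = diagnoses[diagnoses["inpatient"].astype(bool)]
        if not h.empty:
            hk = pos.reindex(h["patient_id"]).to_numpy() * _DAY_KEY + (
                (h["event_date"] - origin).dt.days.to_numpy()
            )
            hosp_keys = np.unique(hk)

    groups: dict[tuple, np.ndarray] = {
        k: np.asarray(v, dtype=np.int64)
        for k, v in pers.groupby(["sex", "provider_id"]).indices.items()
    }

    case_order = cases.sort_values("patient_id").reset_index(drop=True)
    rows = []
    for i, case in case_order.iterrows():
        ci = int(pos[case["patient_id"]])
        t_index = int(case["t_index"])
        case_index_day = entry[ci] + t_index
        case_age = day_to_year[case_index_day] - birth_year[ci]
        cand = groups.get((pers["sex"].iat[ci], pers["provider_id"].iat[ci]))
        cand = cand if cand is not None else np.array([], dtype=np.int64)
        idx_day = entry[cand] + t_index
        ok = (
            (exit_[cand] >= idx_day)
            & (np.abs(day_to_year[np.minimum(idx_day, max_day - 1)] - birth_year[cand] - case_age) <= age_tolerance)
            & (first_outcome[cand] > idx_day)
            & (cand != ci)
        )
        if exclude_hospitalized and hosp_keys.size:
            keys = cand * _DAY_KEY + idx_day
            ok &= ~np.isin(keys, hosp_keys, assume_unique=False)
        eligible = cand[ok]
        elig_days = idx_day[ok]
        rng = np.random.default_rng([seed, i])
        if eligible.size > m_max:
            take = rng.choice(eligible.size, size=m_max, replace=False)
            take.sort()
        else:
            take = np.arange(eligible.size)
        rows.append(
            {
                "set_id": i,
                "role": "case",
                "patient_id": case["patient_id"],
                "index_day": origin + pd.Timedelta(days=int(case_index_day)),
                "t_index": t_index,
                "m": int(take.size),
            }
        )
        for j in take:
            rows.append(
                {
                    "set_id": i,
                    "role": "control",
                    "patient_id": pid[eligible[j]],
                    "index_day": origin + pd.Timedelta(days=int(elig_days[j])),
                    "t_index": t_index,
                    "m": int(take.size),
                }
            )
    matched = pd.DataFrame(
        rows, columns=["set_id", "role", "patient_id", "index_day", "t_index", "m"]
    )
    n_empty = int(((matched["role"] == "case") & (matched["m"] == 0)).sum())
    if n_empty:
        logger.warning("risk_set_match: %d case(s) with zero eligible controls", n_empty)
    return matched


def classify_index_exposure(
    subjects: pd.DataFrame, windows_by_drug: dict[str, pd.DataFrame]
) -> pd.Series:
    """Exposure category at each subject's index day.

    ``subjects`` needs patient_id and index_day; ``windows_by_drug`` maps the
    labels 'target' and 'comparator' to merged current-use window frames. A
    drug is in current use iff some window covers the index day. Returns a
    category Series aligned to ``subjects``:
    {target_only, comparator_only, both, none}.
    """
    flags = {}
    sub = subjects.reset_index(drop=True)
    for label, windows in windows_by_drug.items():
        if windows is None or windows.empty:
            flags[label] = np.zeros(len(sub), dtype=bool)
            continue
        m = sub[["patient_id", "index_day"]].reset_index().merge(
            windows, on="patient_id", how="left"
        )
        cover = (m["index_day"] >= m["start"]) & (m["index_day"] <= m["end"])
        flags[label] = (
            cover.groupby(m["index"]).any().reindex(range(len(sub)), fill_value=False).to_numpy()
        )
    t = flags.get("target", np.zeros(len(sub), dtype=bool))
    c = flags.get("comparator", np.zeros(len(sub), dtype=bool))
    cat = np.where(t & c, "both", np.where(t, "target_only", np.where(c, "comparator_only", "none")))
    return pd.Series(cat, index=subjects.index, name="category")


@dataclass
class ClrFit:
    """Conditional-logistic estimate for one exposure contrast."""

    contrast: str
    model: str  # 'crude' or 'adjusted'
    beta: float
    se: float
    or_: float
    ci95: tuple[float, float]
    n_sets_informative: int
    n_cases: int
    n_controls: int
    estimable: bool = True


_CONTRASTS = {
    "target_vs_comparator": ("target_only", "comparator_only"),
    "target_vs_none": ("target_only", "none"),
}


def clr_fit(
    matched: pd.DataFrame,
    categories: pd.Series,
    contrast: str = "target_vs_comparator",
    confounders: pd.DataFrame | None = None,
) -> dict[str, ClrFit]:
    """Crude (and, if confounders are given, adjusted) conditional-logistic ORs.

    Subjects outside the contrast's two exposure categories are excluded
    set-wise; sets that lose their case or every control are dropped and
    counted. ``confounders``, if given, must be row-aligned with ``matched``
    (same index) since a person's covariate history is evaluated at each
    index day separately. The conditional likelihood is maximized by
    Newton-Raphson; matched sets without exposure variation contribute
    nothing, and a fit where the informative sets are discordant in only one
    direction is reported as non-estimable rather than as a finite number.
    """
    if contrast not in _CONTRASTS:
        raise ValueError(f"unknown contrast {contrast!r}")
    exposed_cat, reference_cat = _CONTRASTS[contrast]
    df = matched.copy()
    df["category"] = categories.to_numpy()
    df = df[df["category"].isin([exposed_cat, reference_cat])]
    has_case = df[df["role"] == "case"].groupby("set_id").size()
    has_ctrl = df[df["role"] == "control"].groupby("set_id").size()
    good = has_case.index.intersection(has_ctrl.index)
    n_dropped = matched["set_id"].nunique() - len(good)
    if n_dropped:
        logger.info("clr_fit(%s): %d sets dropped after exposure exclusions", contrast, n_dropped)
    df = df[df["set_id"].isin(good)]
    if df.empty:
        raise ValueError(f"no informative matched sets for contrast {contrast!r}")
    df["x"] = (df["category"] == exposed_cat).astype(float)

    informative = df.groupby("set_id")["x"].nunique() > 1
    n_informative = int(informative.sum())
    if n_informative == 0:
        raise ValueError(f"no informative matched sets for contrast {contrast!r}")

    n_cases = int((df["role"] == "case").sum())
    n_controls = int((df["role"] == "control").sum())
    y = (df["role"] == "case").astype(int).to_numpy()

    results = {}
    designs = {"crude": df[["x"]]}
    if confounders is not None:
        conf = confounders.loc[df.index]
        adj = pd.concat([df[["x"]], conf], axis=1)
        designs["adjusted"] = adj
    for model_name, X in designs.items():
        fit = _fit_conditional(
            y, np.asarray(X, dtype=float), df["set_id"].to_numpy(), X.columns.tolist()
        )
        beta, se, ok = fit
        if ok:
            ci = (float(np.exp(beta - 1.96 * se)), float(np.exp(beta + 1.96 * se)))
            results[model_name] = ClrFit(
                contrast, model_name, float(beta), float(se), float(np.exp(beta)), ci,
                n_informative, n_cases, n_controls,
            )
        else:
            results[model_name] = ClrFit(
                contrast, model_name, np.nan, np.nan, np.nan, (np.nan, np.nan),
                n_informative, n_cases, n_controls, estimable=False,
            )
    return results


def _fit_conditional(y, X, groups, names):
    """Newton-type fit of the conditional logistic likelihood; returns
    (beta_exposure, se_exposure, estimable)."""
    import warnings as _warnings

    with _warnings.catch_warnings():
        _warnings.simplefilter("ignore")
        try:
            model = sm.ConditionalLogit(y, X, groups=groups)
            res = model.fit(method="newton", disp=0, maxiter=200)
        except Exception as err:  # separation / singular information
            logger.warning("conditional logistic fit failed: %s", err)
            return np.nan, np.nan, False
    k = names.index("x")
    beta = float(res.params[k])
    se = float(res.bse[k])
    if not np.isfinite(beta) or not np.isfinite(se) or abs(beta) > 15 or se > 50:
        return beta, se, False
    return beta, se, True


def audit_matched_sets(
    matched: pd.DataFrame,
    cases: pd.DataFrame,
    persons: pd.DataFrame,
    diagnoses: pd.DataFrame,
    outcome: HealthOutcome,
    age_tolerance: int = 1,
    exclude_hospitalized: bool = True,
) -> pd.DataFrame:
    """Independent validator pass over emitted matched sets.

    Re-checks every control against all matching criteria with
    straightforward per-row logic (deliberately unshared with the sampler):
    at-risk at the case's t_index, same sex and provider, age at index within
    tolerance, no outcome diagnosis on or before the control index day, not
    hospitalized at the index day, not the case itself. Returns a frame of
    violations (empty = clean audit).
    """
    pers = persons.set_index("patient_id")
    case_by_set = matched[matched["role"] == "case"].set_index("set_id")["patient_id"]
    d_out = diagnoses[diagnoses["icd"].isin(outcome.codes)]
    first_out = d_out.groupby("patient_id")["event_date"].min()
    hosp = diagnoses[diagnoses["inpatient"].astype(bool)]
    hosp_set = set(zip(hosp["patient_id"], hosp["event_date"]))

    violations = []

    def flag(row, criterion):
        violations.append(
            {"set_id": row["set_id"], "patient_id": row["patient_id"], "criterion": criterion}
        )

    for _, row in matched[matched["role"] == "control"].iterrows():
        case_id = case_by_set[row["set_id"]]
        cperson = pers.loc[case_id]
        person = pers.loc[row["patient_id"]]
        t_index = row["t_index"]
        ctrl_index = person["cohort_entry"] + pd.Timedelta(days=int(t_index))
        if row["patient_id"] == case_id:
            flag(row, "is the case")
        if person["cohort_exit"] < ctrl_index:
            flag(row, "not at risk at t_index")
        if person["sex"] != cperson["sex"]:
            flag(row, "sex mismatch")
        if person["provider_id"] != cperson["provider_id"]:
            flag(row, "provider mismatch")
        case_index = cperson["cohort_entry"] + pd.Timedelta(days=int(t_index))
        case_age = case_index.year - cperson["birth_year"]
        ctrl_age = ctrl_index.year - person["birth_year"]
        if abs(ctrl_age - case_age) > age_tolerance:
            flag(row, "age mismatch")
        fo = first_out.get(row["patient_id"])
        if fo is not None and fo <= ctrl_index:
            flag(row, "outcome on or before control index")
        if exclude_hospitalized and (row["patient_id"], ctrl_index) in hosp_set:
            flag(row, "hospitalized at index")
        if ctrl_index != row["index_day"]:
            flag(row, "index day inconsistent with time-in-cohort")
    return pd.DataFrame(violations, columns=["set_id", "patient_id", "criterion"])
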