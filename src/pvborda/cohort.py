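"""Longitudinal cohort data model and reductions.

Three claims-style tables — persons, dispensations (ATC-coded), diagnoses
(ICD-10-coded) — are validated, filtered by new-user eligibility rules, and
reduced to the structures the signal detectors consume: a patient-level
analysis matrix (exposure indicator, per-ICD event indicators, covariates),
per-code 2x2 contingency counts, and stratified person-time summaries.

Conventions: dates are closed intervals (a one-day dispensation covers its
dispense date), person-time is measured in years of 365.25 days, and ICD
codes are stored dotless upper-case ("K92.2" -> "K922").
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

DAYS_PER_YEAR = 365.25

PERSON_COLUMNS = ["patient_id", "sex", "birth_year", "cohort_entry", "cohort_exit", "provider_id"]
DISPENSATION_COLUMNS = ["patient_id", "atc", "dispense_date", "supply_days"]
DIAGNOSIS_COLUMNS = ["patient_id", "icd", "event_date", "inpatient"]


class SchemaError(ValueError):
    """A required column is missing or a table cannot be interpreted."""


class EmptyCohortError(ValueError):
    """Eligibility filtering removed every patient."""


def normalize_icd(code: str) -> str:
    """Normalize an ICD-10 code to dotless upper case ("k92.2" -> "K922")."""
    return str(code).strip().upper().replace(".", "")


def format_icd(code: str) -> str:
    """Render a normalized ICD code with the conventional dot ("K922" -> "K92.2")."""
    code = normalize_icd(code)
    return code if len(code) <= 3 else f"{code[:3]}.{code[3:]}"


@dataclass
class ValidationReport:
    """Row-level drops recorded by :func:`validate_tables`."""

    dropped: dict[str, dict[str, int]] = field(default_factory=dict)

    def add(self, table: str, reason: str, count: int) -> None:
        if count:
            self.dropped.setdefault(table, {})[reason] = (
                self.dropped.get(table, {}).get(reason, 0) + int(count)
            )

    def total(self, table: str | None = None) -> int:
        tables = [table] if table else list(self.dropped)
        return sum(sum(self.dropped.get(t, {}).values()) for t in tables)


@dataclass
class CohortTables:
    """Validated persons / dispensations / diagnoses tables."""

    persons: pd.DataFrame
    dispensations: pd.DataFrame
    diagnoses: pd.DataFrame
    report: ValidationReport = field(default_factory=ValidationReport)

    @property
    def n_patients(self) -> int:
        return len(self.persons)


def _require_columns(df: pd.DataFrame, cols: list[str], table: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"table '{table}' is missing required column(s): {missing}")


def _parse_dates(df: pd.DataFrame, col: str, table: str, report: ValidationReport) -> pd.DataFrame:
    parsed = pd.to_datetime(df[col], errors="coerce", format="ISO8601")
    bad = parsed.isna() & df[col].notna()
    report.add(table, f"unparseable {col}", int(bad.sum()))
    df = df.copy()
    df[col] = parsed
    return df[~parsed.isna()]


def validate_tables(
    persons: pd.DataFrame,
    dispensations: pd.DataFrame,
    diagnoses: pd.DataFrame,
) -> CohortTables:
    """Validate the three input tables and return clean :class:`CohortTables`.

    Schema violations (missing columns) raise :class:`SchemaError`. Row-level
    problems — unparseable dates, exit before entry, duplicated patient ids,
    dispensations or diagnoses referencing unknown patients, non-positive
    supply days — drop the offending rows and are counted in the report.
    """
    report = ValidationReport()
    _require_columns(persons, PERSON_COLUMNS, "persons")
    _require_columns(dispensations, DISPENSATION_COLUMNS, "dispensations")
    _require_columns(diagnoses, DIAGNOSIS_COLUMNS, "diagnoses")

    persons = persons.copy()
    persons["sex"] = persons["sex"].astype(str).str.upper().str.strip()
    bad_sex = ~persons["sex"].isin(["F", "M"])
    report.add("persons", "invalid sex", int(bad_sex.sum()))
    persons = persons[~bad_sex]
    persons = _parse_dates(persons, "cohort_entry", "persons", report)
    persons = _parse_dates(persons, "cohort_exit", "persons", report)
    persons["birth_year"] = pd.to_numeric(persons["birth_year"], errors="coerce")
    bad_by = persons["birth_year"].isna() | (
        persons["birth_year"] > persons["cohort_entry"].dt.year
    )
    report.add("persons", "invalid birth_year", int(bad_by.sum()))
    persons = persons[~bad_by]
    persons["birth_year"] = persons["birth_year"].astype(int)
    bad_order = persons["cohort_exit"] < persons["cohort_entry"]
    report.add("persons", "exit before entry", int(bad_order.sum()))
    persons = persons[~bad_order]
    dup = persons["patient_id"].duplicated()
    report.add("persons", "duplicate patient_id", int(dup.sum()))
    persons = persons[~dup].reset_index(drop=True)

    known = pd.Index(persons["patient_id"])

    dispensations = dispensations.copy()
    dispensations = _parse_dates(dispensations, "dispense_date", "dispensations", report)
    dispensations["supply_days"] = pd.to_numeric(dispensations["supply_days"], errors="coerce")
    bad_supply = dispensations["supply_days"].isna() | (dispensations["supply_days"] < 1)
    report.add("dispensations", "invalid supply_days", int(bad_supply.sum()))
    dispensations = dispensations[~bad_supply]
    dispensations["supply_days"] = dispensations["supply_days"].astype(int)
    unknown = ~dispensations["patient_id"].isin(known)
    report.add("dispensations", "unknown patient_id", int(unknown.sum()))
    dispensations = dispensations[~unknown].reset_index(drop=True)
    dispensations["atc"] = dispensations["atc"].astype(str).str.strip().str.upper()

    diagnoses = diagnoses.copy()
    diagnoses = _parse_dates(diagnoses, "event_date", "diagnoses", report)
    unknown = ~diagnoses["patient_id"].isin(known)
    report.add("diagnoses", "unknown patient_id", int(unknown.sum()))
    diagnoses = diagnoses[~unknown]
    diagnoses["icd"] = diagnoses["icd"].map(normalize_icd)
    diagnoses["inpatient"] = (
        diagnoses["inpatient"]
        .astype(str)
        .str.strip()
        .str.lower()
        .isin(["1", "true", "t", "yes"])
    )
    diagnoses = diagnoses.reset_index(drop=True)

    if report.total():
        logger.info("validate_tables dropped rows: %s", report.dropped)
    return CohortTables(persons, dispensations, diagnoses, report)


def load_tables(persons_csv, dispensations_csv, diagnoses_csv) -> CohortTables:
    """Read the three CSV files and validate them."""
    return validate_tables(
        pd.read_csv(persons_csv),
        pd.read_csv(dispensations_csv),
        pd.read_csv(diagnoses_csv),
    )


# ---------------------------------------------------------------------------
# Eligibility
# ---------------------------------------------------------------------------

@dataclass
class EligibilityRules:
    """New-user eligibility rules for the detection cohort.

    ``min_enrollment_months`` requires continuous cohort membership; the
    target-drug rules require a first dispensation at least
    ``min_days_after_entry`` days after cohort entry and no dispensation of
    any ``washout_atc_prefixes`` drug in the ``washout_days`` preceding entry.
    Set ``require_target_use`` False to keep never-users (the unexposed pool)
    while still applying enrollment and washout.
    """

    target_atc: str
    min_enrollment_months: int = 12
    min_days_after_entry: int = 90
    washout_atc_prefixes: tuple[str, ...] = ()
    washout_days: int = 365
    require_target_use: bool = True


@dataclass
class EligibilityResult:
    eligible_ids: pd.Index
    attrition: pd.DataFrame  # columns: rule, n_excluded, n_remaining


def _first_target_dispensation(
    tables: CohortTables, target_atc: str
) -> pd.Series:
    """First dispensation date of the target drug per patient (ATC prefix match)."""
    disp = tables.dispensations
    hit = disp[disp["atc"].str.startswith(target_atc)]
    return hit.groupby("patient_id")["dispense_date"].min()


def apply_eligibility(tables: CohortTables, rules: EligibilityRules) -> EligibilityResult:
    """Apply the eligibility rules in order and return ids plus attrition table."""
    persons = tables.persons
    ids = pd.Index(persons["patient_id"])
    rows = [("input", 0, len(ids))]

    entry = persons.set_index("patient_id")["cohort_entry"]
    exit_ = persons.set_index("patient_id")["cohort_exit"]

    # Rule 1: continuous enrollment.
    min_exit = entry + pd.DateOffset(months=rules.min_enrollment_months)
    keep = ids[(exit_.loc[ids] >= min_exit.loc[ids]).to_numpy()]
    rows.append((f"enrollment >= {rules.min_enrollment_months} months", len(ids) - len(keep), len(keep)))
    ids = keep

    # Rule 2: washout — no dispensation of the washout class before entry.
    if rules.washout_atc_prefixes:
        disp = tables.dispensations
        mask = np.zeros(len(disp), dtype=bool)
        for prefix in rules.washout_atc_prefixes:
            mask |= disp["atc"].str.startswith(prefix).to_numpy()
        wo = disp[mask].merge(
            persons[["patient_id", "cohort_entry"]], on="patient_id", how="left"
        )
        lo = wo["cohort_entry"] - pd.to_timedelta(rules.washout_days, unit="D")
        in_window = (wo["dispense_date"] >= lo) & (wo["dispense_date"] < wo["cohort_entry"])
        excluded = pd.Index(wo.loc[in_window, "patient_id"].unique())
        keep = ids.difference(excluded)
        rows.append((f"washout {rules.washout_days}d: {'/'.join(rules.washout_atc_prefixes)}", len(ids) - len(keep), len(keep)))
        ids = keep

    # Rule 3: first target dispensation late enough after entry.
    if rules.require_target_use:
        first = _first_target_dispensation(tables, rules.target_atc)
        first = first.reindex(ids)
        min_date = entry.loc[ids] + pd.to_timedelta(rules.min_days_after_entry, unit="D")
        ok = (first >= min_date) & (first <= exit_.loc[ids])
        keep = ids[ok.to_numpy()]
        rows.append((f"target use >= {rules.min_days_after_entry}d after entry", len(ids) - len(keep), len(keep)))
        ids = keep

    attrition = pd.DataFrame(rows, columns=["rule", "n_excluded", "n_remaining"])
    if len(ids) == 0:
        raise EmptyCohortError(
            f"no patients satisfy the eligibility rules; attrition:\n{attrition}"
        )
    return EligibilityResult(eligible_ids=ids.sort_values(), attrition=attrition)


# ---------------------------------------------------------------------------
# Exposure windows
# ---------------------------------------------------------------------------

def build_exposure_windows(
    dispensations: pd.DataFrame, drug_code: str, grace_days: int = 14
) -> pd.DataFrame:
    """Merged current-use windows per patient for one drug (ATC prefix match).

    Each dispensation covers the closed interval
    ``[dispense_date, dispense_date + supply_days + grace_days - 1]``;
    overlapping or abutting windows of one patient are merged.
    Returns a frame with columns patient_id, start, end.
    """
    if grace_days < 0:
        raise ValueError("grace_days must be >= 0")
    hit = dispensations[dispensations["atc"].str.startswith(drug_code)]
    if hit.empty:
        return pd.DataFrame(columns=["patient_id", "start", "end"])
    w = pd.DataFrame(
        {
            "patient_id": hit["patient_id"].to_numpy(),
            "start": hit["dispense_date"].to_numpy(),
            "end": (
                hit["dispense_date"]
                + pd.to_timedelta(hit["supply_days"] + grace_days - 1, unit="D")
            ).to_numpy(),
        }
    )
    return merge_windows(w)


def merge_windows(windows: pd.DataFrame) -> pd.DataFrame:
    """Merge overlapping/abutting closed day-intervals per patient. Idempotent."""
    if windows.empty:
        return windows.copy()
    w = windows.sort_values(["patient_id", "start", "end"]).reset_index(drop=True)
    same_patient = w["patient_id"].eq(w["patient_id"].shift())
    # abutting means next start <= previous end + 1 day
    running_end = w["end"].copy()
    new_group = ~(same_patient & (w["start"] <= running_end.shift() + pd.Timedelta(days=1)))
    # cumulative max of end within patient so chains of overlaps merge correctly
    grp = new_group.cumsum()
    # recompute groups using cummax of end: iterate until stable (bounded by chain length)
    while True:
        end_cummax = w.groupby(grp)["end"].cummax()
        new_group2 = ~(same_patient & (w["start"] <= end_cummax.shift() + pd.Timedelta(days=1)))
        grp2 = new_group2.cumsum()
        if grp2.equals(grp):
            break
        grp = grp2
    out = w.groupby(grp).agg(
        patient_id=("patient_id", "first"), start=("start", "min"), end=("end", "max")
    )
    return out.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Analysis matrix
# ---------------------------------------------------------------------------

@dataclass
class AnalysisMatrix:
    """Patient-level design for the binary-outcome detectors.

    ``data`` holds one row per eligible patient with the exposure indicator
    ``y``, one 0/1 column per retained ICD code, and covariate columns.
    """

    data: pd.DataFrame
    adr_codes: list[str]
    covariates: list[str]
    dropped_codes: list[str]

    @property
    def y(self) -> pd.Series:
        return self.data["y"]

    @property
    def X_adr(self) -> pd.DataFrame:
        return self.data[self.adr_codes]


def build_analysis_matrix(
    tables: CohortTables,
    eligible_ids: pd.Index,
    target_atc: str,
    min_count: int = 5,
    min_days_after_entry: int = 90,
    unexposed_run_in_days: int = 90,
    grace_days: int = 14,
) -> AnalysisMatrix:
    """One row per eligible patient: exposure y, ADR indicators, covariates.

    ``y = 1`` iff the patient has a target dispensation at least
    ``min_days_after_entry`` days after entry. The ADR indicator for code j is
    1 iff j occurs in the patient's at-risk window: first exposure onward for
    exposed patients, a pseudo-index at entry + ``unexposed_run_in_days`` for
    unexposed ones (so both groups have comparable observation opportunity).
    Columns with fewer than ``min_count`` positive patients are dropped.
    """
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    persons = tables.persons.set_index("patient_id").loc[eligible_ids]

    first = _first_target_dispensation(tables, target_atc).reindex(eligible_ids)
    min_date = persons["cohort_entry"] + pd.to_timedelta(min_days_after_entry, unit="D")
    y = ((first >= min_date) & (first <= persons["cohort_exit"])).astype(int)
    if y.nunique() < 2:
        raise ValueError(
            "exposure indicator is constant; include unexposed comparator patients"
        )

    at_risk_start = persons["cohort_entry"] + pd.to_timedelta(unexposed_run_in_days, unit="D")
    exposed = y.astype(bool)
    at_risk_start[exposed] = first[exposed]

    diag = tables.diagnoses
    diag = diag[diag["patient_id"].isin(eligible_ids)]
    diag = diag.merge(
        pd.DataFrame(
            {
                "patient_id": eligible_ids,
                "risk_start": at_risk_start.to_numpy(),
                "risk_end": persons["cohort_exit"].to_numpy(),
            }
        ),
        on="patient_id",
    )
    in_window = (diag["event_date"] >= diag["risk_start"]) & (
        diag["event_date"] <= diag["risk_end"]
    )
    hits = diag[in_window][["patient_id", "icd"]].drop_duplicates()

    counts = hits.groupby("icd").size()
    kept = sorted(counts[counts >= min_count].index)
    dropped = sorted(counts[counts < min_count].index)
    if dropped:
        logger.info("build_analysis_matrix dropped %d codes below min_count=%d", len(dropped), min_count)

    indicator = (
        hits[hits["icd"].isin(kept)]
        .assign(v=1)
        .pivot_table(index="patient_id", columns="icd", values="v", fill_value=0)
        .reindex(index=eligible_ids, columns=kept, fill_value=0)
        .astype(int)
    )

    data = indicator.copy()
    data.insert(0, "y", y)
    data["age"] = persons["cohort_entry"].dt.year - persons["birth_year"]
    data["female"] = (persons["sex"] == "F").astype(int)
    data.index.name = "patient_id"
    return AnalysisMatrix(
        data=data, adr_codes=list(kept), covariates=["age", "female"], dropped_codes=dropped
    )


def build_pair_counts(matrix: AnalysisMatrix) -> pd.DataFrame:
    """2x2 contingency cells per retained ICD code.

    Returns a frame indexed by icd with columns n11 (exposed with event),
    n10 (exposed without), n01 (unexposed with event), n00, n.
    """
    y = matrix.y.to_numpy()
    X = matrix.X_adr.to_numpy()
    n = len(y)
    n1_ = int(y.sum())
    n11 = X[y == 1].sum(axis=0).astype(int)
    ncol1 = X.sum(axis=0).astype(int)
    out = pd.DataFrame(
        {
            "n11": n11,
            "n10": n1_ - n11,
            "n01": ncol1 - n11,
            "n00": n - n1_ - (ncol1 - n11),
            "n": n,
        },
        index=pd.Index(matrix.adr_codes, name="icd"),
    )
    return out


# ---------------------------------------------------------------------------
# Person-time
# ---------------------------------------------------------------------------

@dataclass
class StrataConfig:
    """Stratification for person-time rates: sex and age bands (at entry)."""

    age_band_width: int = 10
    by_sex: bool = True


def _stratum_labels(persons: pd.DataFrame, config: StrataConfig) -> pd.Series:
    age = persons["cohort_entry"].dt.year - persons["birth_year"]
    band = (age // config.age_band_width) * config.age_band_width
    lab = band.astype(int).astype(str) + "-" + (band + config.age_band_width - 1).astype(int).astype(str)
    if config.by_sex:
        lab = persons["sex"].astype(str) + "/" + lab
    return lab


def build_person_time(
    tables: CohortTables,
    windows: pd.DataFrame,
    strata: StrataConfig | None = None,
    eligible_ids: pd.Index | None = None,
    codes: list[str] | None = None,
) -> pd.DataFrame:
    """Exposed/unexposed events and person-years per (icd, stratum).

    Each patient's follow-up [entry, exit] is split into time inside the
    merged exposure ``windows`` and the remainder; the first occurrence of
    each code per patient is attributed to the state at its event date.
    Returns a frame with columns icd, stratum, O_exp, PT_exp, O_unexp,
    PT_unexp (person-time in years of 365.25 days; identical across codes
    within a stratum).
    """
    strata = strata or StrataConfig()
    persons = tables.persons
    if eligible_ids is not None:
        persons = persons[persons["patient_id"].isin(eligible_ids)]
    persons = persons.reset_index(drop=True)

    followup_days = (persons["cohort_exit"] - persons["cohort_entry"]).dt.days + 1

    # exposed days per patient: window overlap with [entry, exit], closed intervals
    if windows.empty:
        exp_days = pd.Series(0.0, index=persons["patient_id"])
    else:
        w = windows.merge(
            persons[["patient_id", "cohort_entry", "cohort_exit"]], on="patient_id", how="inner"
        )
        start = w[["start", "cohort_entry"]].max(axis=1)
        end = w[["end", "cohort_exit"]].min(axis=1)
        days = ((end - start).dt.days + 1).clip(lower=0)
        exp_days = days.groupby(w["patient_id"]).sum().reindex(persons["patient_id"]).fillna(0)

    stratum = _stratum_labels(persons, strata)
    pt = pd.DataFrame(
        {
            "patient_id": persons["patient_id"].to_numpy(),
            "stratum": stratum.to_numpy(),
            "pt_exp": exp_days.to_numpy() / DAYS_PER_YEAR,
            "pt_unexp": (followup_days.to_numpy() - exp_days.to_numpy()) / DAYS_PER_YEAR,
        }
    )
    pt_strat = pt.groupby("stratum")[["pt_exp", "pt_unexp"]].sum()

    # first event per patient+code within follow-up
    diag = tables.diagnoses.merge(
        persons[["patient_id", "cohort_entry", "cohort_exit"]], on="patient_id", how="inner"
    )
    if codes is not None:
        diag = diag[diag["icd"].isin(codes)]
    before_entry = diag["event_date"] < diag["cohort_entry"]
    n_before = int(before_entry.sum())
    if n_before:
        logger.warning("build_person_time: %d diagnosis rows before cohort entry excluded", n_before)
    diag = diag[~before_entry & (diag["event_date"] <= diag["cohort_exit"])]
    first = diag.groupby(["patient_id", "icd"], as_index=False)["event_date"].min()

    # attribute each first event to exposed/unexposed state at its date
    if windows.empty:
        first["exposed"] = False
    else:
        m = first.merge(windows, on="patient_id", how="left")
        cover = (m["event_date"] >= m["start"]) & (m["event_date"] <= m["end"])
        first["exposed"] = (
            cover.groupby([m["patient_id"], m["icd"]]).any().to_numpy()
        )
    first = first.merge(
        pd.DataFrame({"patient_id": persons["patient_id"], "stratum": stratum}),
        on="patient_id",
    )
    grp = first.groupby(["icd", "stratum"])["exposed"]
    events = grp.agg(O_exp="sum", O_unexp=lambda s: int((~s).sum()))

    all_codes = codes if codes is not None else sorted(first["icd"].unique())
    idx = pd.MultiIndex.from_product([all_codes, pt_strat.index], names=["icd", "stratum"])
    out = events.reindex(idx, fill_value=0).reset_index()
    out = out.merge(pt_strat.reset_index(), on="stratum")
    out = out.rename(columns={"pt_exp": "PT_exp", "pt_unexp": "PT_unexp"})
    out["O_exp"] = out["O_exp"].astype(int)
    out["O_unexp"] = out["O_unexp"].astype(int)
    return out[["icd", "stratum", "O_exp", "PT_exp", "O_unexp", "PT_unexp"]]


# ---------------------------------------------------------------------------
# Detection / verification split
# ---------------------------------------------------------------------------

def split_cohort(
    persons: pd.DataFrame, detection_fraction: float, seed: int
) -> tuple[pd.Index, pd.Index]:
    """Disjoint, exhaustive, seed-deterministic split of patient ids."""
    if not 0 < detection_fraction < 1:
        raise ValueError("detection_fraction must be in (0, 1)")
    ids = np.sort(persons["patient_id"].to_numpy())
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    k = int(round(detection_fraction * len(ids)))
    return pd.Index(ids[perm[:k]]).sort_values(), pd.Index(ids[perm[k:]]).sort_values()
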