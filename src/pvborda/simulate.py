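"""Synthetic longitudinal healthcare-claims generator with known ground truth.

The generator emulates the structure that makes drug-safety screening hard on
claims data: a new-user cohort with age/sex structure, exposure driven by a
latent indication (indication bias), a bystander drug that is frequently
co-prescribed with the target (innocent-bystander signals), an active
comparator that is mutually exclusive with the target at initiation, and a
catalog of coded medical events falling into four classes:

``true``
    rate multiplied during target-drug current-use windows,
``bystander``
    rate multiplied during bystander-drug windows (so the target picks up a
    spurious association through co-prescription),
``indication``
    rate multiplied whenever the latent indication is present, regardless of
    exposure (confounding by indication),
``null``
    constant baseline rate.

Events follow per-patient, per-code piecewise-constant-rate Poisson processes;
every event is emitted as a diagnosis row (recurrences allowed), so both
patient-level indicator reductions and person-time reductions are meaningful.
Everything is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import CohortTables, validate_tables

ORIGIN = pd.Timestamp("2014-01-01")

TARGET_ATC = "B01AF01"      # rivaroxaban-like direct oral anticoagulant
COMPARATOR_ATC = "B01AA04"  # phenprocoumon-like vitamin-K antagonist
BYSTANDER_ATC = "C09AA05"   # ramipril-like co-medication
INDICATION_ICD = "I48"      # atrial-fibrillation-like indication code


@dataclass(frozen=True)
class AdrSpec:
    """One catalog entry: an ICD code with its event-rate model."""

    icd: str
    klass: str  # {"true", "bystander", "indication", "null"}
    base_rate: float  # baseline events per person-year
    multiplier: float = 1.0  # rate multiplier during the class-relevant state

    def __post_init__(self):
        if self.klass not in {"true", "bystander", "indication", "null"}:
            raise ValueError(f"unknown ADR class {self.klass!r}")
        if self.base_rate <= 0 or self.multiplier <= 0:
            raise ValueError("base_rate and multiplier must be positive")


@dataclass
class SimulationConfig:
    n_patients: int = 20_000
    study_years: float = 3.0
    age_mean: float = 70.0
    age_sd: float = 10.0
    female_fraction: float = 0.5
    n_providers: int = 4
    # exposure model: logit P(target) = b0 + b_age*(age-65)/10 + b_sex*female + b_ind*indication
    exposure_intercept: float = -2.2
    exposure_age: float = 0.3
    exposure_sex: float = -0.1
    exposure_indication: float = 1.5
    # latent indication: logit P = i0 + i_age*(age-65)/10
    indication_intercept: float = -1.0
    indication_age: float = 0.8
    bystander_prob: float = 0.6          # P(bystander | target user)
    bystander_background: float = 0.15   # P(bystander | non-user)
    comparator_uptake: float = 0.0       # P(comparator | not target), scaled up by indication
    # treatment episode shape
    first_dispensation_delay: tuple[int, int] = (90, 180)  # days after entry
    treatment_mean_days: float = 400.0
    supply_days: int = 30
    grace_days: int = 14  # multiplier window extends this far past last supply day
    inpatient_prob: float = 0.1
    followup_min_years: float = 1.0
    adr_catalog: list[AdrSpec] = field(default_factory=list)
    seed: int = 0


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


def _uniform_days_outside(rng, counts, out_len, win_rel_start, win_len, entry_day):
    """Event days drawn uniformly over follow-up minus the exposure window.

    ``out_len`` is the number of follow-up days outside the window; days at or
    past the window start are shifted across it (offset mapping).
    """
    idx = np.repeat(np.arange(len(counts)), counts)
    u = np.floor(rng.random(idx.size) * out_len[idx]).astype(np.int64)
    u = u + (u >= win_rel_start[idx]) * win_len[idx]
    return idx, entry_day[idx] + u


def _uniform_days_inside(rng, counts, win_start, win_len):
    idx = np.repeat(np.arange(len(counts)), counts)
    u = np.floor(rng.random(idx.size) * win_len[idx]).astype(np.int64)
    return idx, win_start[idx] + u


def _expand_dispensations(pid, start_day, duration_days, supply_days):
    """Refill every supply_days from start for the episode duration."""
    k = np.maximum(1, np.ceil(duration_days / supply_days)).astype(np.int64)
    idx = np.repeat(np.arange(len(pid)), k)
    j = np.arange(idx.size) - np.repeat(np.cumsum(k) - k, k)
    return pid[idx], start_day[idx] + j * supply_days


def simulate_cohort(config: SimulationConfig) -> tuple[CohortTables, pd.DataFrame]:
    """Generate tables plus a ground-truth frame (icd, class, multiplier)."""
    if not config.adr_catalog:
        raise ValueError("adr_catalog must not be empty")
    rng = np.random.default_rng(config.seed)
    n = config.n_patients

    female = rng.random(n) < config.female_fraction
    age = np.clip(np.round(rng.normal(config.age_mean, config.age_sd, n)), 30, 95)
    entry_day = rng.integers(0, 365, n)
    followup_days = np.round(
        rng.uniform(config.followup_min_years, config.study_years, n) * 365.25
    ).astype(np.int64)
    exit_day = entry_day + followup_days - 1
    provider = rng.integers(0, config.n_providers, n)
    entry_year = 2014 + (entry_day // 365)
    birth_year = entry_year - age.astype(int)

    z_age = (age - 65.0) / 10.0
    indication = rng.random(n) < _sigmoid(
        config.indication_intercept + config.indication_age * z_age
    )
    p_exposed = _sigmoid(
        config.exposure_intercept
        + config.exposure_age * z_age
        + config.exposure_sex * female
        + config.exposure_indication * indication
    )
    delay_lo, delay_hi = config.first_dispensation_delay
    can_treat = followup_days > delay_hi + config.supply_days
    target = (rng.random(n) < p_exposed) & can_treat
    if (p_exposed * can_treat).sum() < 1:
        raise ValueError("configuration yields an expected zero exposed patients")
    comparator = np.zeros(n, dtype=bool)
    if config.comparator_uptake > 0:
        p_comp = config.comparator_uptake * (0.25 + 0.75 * indication)
        comparator = (~target) & (rng.random(n) < p_comp) & can_treat

    def episode(active):
        start = entry_day + rng.integers(delay_lo, delay_hi + 1, n)
        dur = np.clip(
            np.round(rng.exponential(config.treatment_mean_days, n)),
            config.supply_days,
            np.maximum(config.supply_days, exit_day - start + 1),
        ).astype(np.int64)
        start = np.where(active, start, exit_day + 1)
        dur = np.where(active, dur, 0)
        return start, dur

    t_start, t_dur = episode(target)
    bystander = (target & (rng.random(n) < config.bystander_prob)) | (
        (~target) & (rng.random(n) < config.bystander_background) & can_treat
    )
    b_start_own, b_dur_own = episode(bystander)
    # co-prescribed bystanders share the target's episode timing
    b_start = np.where(target & bystander, t_start, b_start_own)
    b_dur = np.where(target & bystander, t_dur, b_dur_own)
    c_start, c_dur = episode(comparator)

    pid = np.array([f"P{i:07d}" for i in range(n)])

    disp_frames = []
    for atc, active, start, dur in [
        (TARGET_ATC, target, t_start, t_dur),
        (COMPARATOR_ATC, comparator, c_start, c_dur),
        (BYSTANDER_ATC, bystander, b_start, b_dur),
    ]:
        if not active.any():
            continue
        p, d = _expand_dispensations(pid[active], start[active], dur[active], config.supply_days)
        disp_frames.append(
            pd.DataFrame(
                {
                    "patient_id": p,
                    "atc": atc,
                    "dispense_date": ORIGIN + pd.to_timedelta(d, unit="D"),
                    "supply_days": config.supply_days,
                }
            )
        )

    # multiplier windows: current use incl. the grace period, clipped to follow-up
    def effect_window(active, start, dur):
        ws = np.where(active, start, 0)
        we = np.where(active, np.minimum(start + dur + config.grace_days - 1, exit_day), -1)
        w_len = np.where(active, we - ws + 1, 0).astype(np.int64)
        return ws, w_len

    t_ws, t_wlen = effect_window(target, t_start, t_dur)
    b_ws, b_wlen = effect_window(bystander, b_start, b_dur)

    diag_pid, diag_icd, diag_day = [], [], []

    # indication diagnosis recorded at entry for indicated patients
    ind_idx = np.flatnonzero(indication)
    diag_pid.append(pid[ind_idx])
    diag_icd.append(np.repeat(INDICATION_ICD, ind_idx.size))
    diag_day.append(entry_day[ind_idx])

    for spec in config.adr_catalog:
        if spec.klass in ("true", "bystander"):
            ws, wlen = (t_ws, t_wlen) if spec.klass == "true" else (b_ws, b_wlen)
            out_len = followup_days - wlen
            lam_in = spec.base_rate * spec.multiplier / 365.25
            k_in = rng.poisson(lam_in * wlen)
            k_out = rng.poisson(spec.base_rate / 365.25 * out_len)
            i1, d1 = _uniform_days_inside(rng, k_in, ws, np.maximum(wlen, 1))
            i2, d2 = _uniform_days_outside(
                rng, k_out, np.maximum(out_len, 1), ws - entry_day, wlen, entry_day
            )
            idx = np.concatenate([i1, i2])
            day = np.concatenate([d1, d2])
        else:
            mult = (
                np.where(indication, spec.multiplier, 1.0)
                if spec.klass == "indication"
                else np.ones(n)
            )
            k = rng.poisson(spec.base_rate * mult / 365.25 * followup_days)
            idx = np.repeat(np.arange(n), k)
            day = entry_day[idx] + np.floor(
                rng.random(idx.size) * followup_days[idx]
            ).astype(np.int64)
        diag_pid.append(pid[idx])
        diag_icd.append(np.repeat(spec.icd, idx.size))
        diag_day.append(day)

    diagnoses = pd.DataFrame(
        {
            "patient_id": np.concatenate(diag_pid),
            "icd": np.concatenate(diag_icd),
            "event_date": ORIGIN + pd.to_timedelta(np.concatenate(diag_day), unit="D"),
            "inpatient": rng.random(sum(len(a) for a in diag_pid)) < config.inpatient_prob,
        }
    ).sort_values(["patient_id", "event_date", "icd"], kind="stable").reset_index(drop=True)

    persons = pd.DataFrame(
        {
            "patient_id": pid,
            "sex": np.where(female, "F", "M"),
            "birth_year": birth_year,
            "cohort_entry": ORIGIN + pd.to_timedelta(entry_day, unit="D"),
            "cohort_exit": ORIGIN + pd.to_timedelta(exit_day, unit="D"),
            "provider_id": provider,
        }
    )
    dispensations = (
        pd.concat(disp_frames, ignore_index=True)
        if disp_frames
        else pd.DataFrame(columns=["patient_id", "atc", "dispense_date", "supply_days"])
    )
    dispensations = dispensations.sort_values(
        ["patient_id", "dispense_date", "atc"], kind="stable"
    ).reset_index(drop=True)

    tables = validate_tables(persons, dispensations, diagnoses)
    truth = pd.DataFrame(
        {
            "icd": [s.icd for s in config.adr_catalog],
            "class": [s.klass for s in config.adr_catalog],
            "multiplier": [s.multiplier for s in config.adr_catalog],
        }
    )
    return tables, truth


def write_tables(tables: CohortTables, outdir, truth: pd.DataFrame | None = None) -> None:
    """Write the cohort tables (and optional ground truth) as CSV."""
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    persons = tables.persons.copy()
    for c in ("cohort_entry", "cohort_exit"):
        persons[c] = persons[c].dt.strftime("%Y-%m-%d")
    persons.to_csv(outdir / "persons.csv", index=False)
    disp = tables.dispensations.copy()
    disp["dispense_date"] = disp["dispense_date"].dt.strftime("%Y-%m-%d")
    disp.to_csv(outdir / "dispensations.csv", index=False)
    diag = tables.diagnoses.copy()
    diag["event_date"] = diag["event_date"].dt.strftime("%Y-%m-%d")
    diag["inpatient"] = diag["inpatient"].astype(int)
    diag.to_csv(outdir / "diagnoses.csv", index=False)
    if truth is not None:
        truth.to_csv(outdir / "ground_truth.csv", index=False)


# ---------------------------------------------------------------------------
# Packaged fixtures
# ---------------------------------------------------------------------------

def make_catalog(
    n_true: int,
    n_bystander: int,
    n_indication: int,
    n_null: int,
    true_multiplier: float = 3.0,
    bystander_multiplier: float = 3.0,
    indication_multiplier: float = 2.0,
    base_rates: tuple[float, ...] = (0.005, 0.01, 0.02, 0.04),
) -> list[AdrSpec]:
    """Deterministic ADR catalog; baseline rates cycle through ``base_rates``."""
    catalog = []
    for letter, klass, count, mult in [
        ("T", "true", n_true, true_multiplier),
        ("B", "bystander", n_bystander, bystander_multiplier),
        ("J", "indication", n_indication, indication_multiplier),
        ("N", "null", n_null, 1.0),
    ]:
        for j in range(count):
            catalog.append(
                AdrSpec(
                    icd=f"{letter}{j // 10}{j % 10}{(j % 5)}",
                    klass=klass,
                    base_rate=base_rates[j % len(base_rates)],
                    multiplier=mult if klass != "null" else 1.0,
                )
            )
    return catalog


FIXTURE_SIZES = {"tiny": 600, "small": 20_000, "medium": 100_000}


def default_fixture(size: str = "small", seed: int = 0) -> SimulationConfig:
    """Packaged study configurations.

    ``tiny`` (~600 patients, 15 codes across all four classes with inflated
    rates) exercises every pipeline stage in seconds; ``small`` (20,000
    patients, 220 codes: 12 true, 208 null) is the signal-recovery
    condition; ``medium`` (100,000) is for profiling.
    """
    if size not in FIXTURE_SIZES:
        raise ValueError(f"unknown fixture size {size!r}; choose from {sorted(FIXTURE_SIZES)}")
    if size == "tiny":
        catalog = make_catalog(3, 2, 2, 8, base_rates=(0.05, 0.1, 0.15))
    else:
        # signal content is true + null codes; the bystander / indication
        # mechanisms are exercised by dedicated configs (see make_catalog),
        # since confounded codes are statistically real associations and
        # would displace the null ranks by construction
        catalog = make_catalog(12, 0, 0, 208)
    return SimulationConfig(
        n_patients=FIXTURE_SIZES[size], adr_catalog=catalog, comparator_uptake=0.3, seed=seed
    )


def verification_fixture(
    n_patients: int = 50_000,
    conditional_or: float = 1.5,
    outcome_rate: float = 0.03,
    seed: int = 0,
) -> SimulationConfig:
    """Two-drug new-user cohort with one outcome carrying a known conditional OR.

    The outcome's hazard is multiplied by ``conditional_or`` during target
    current use and unaffected by the comparator, so with a rare outcome the
    conditional OR of current target vs current comparator use is the
    multiplier itself.
    """
    catalog = [
        AdrSpec(icd="Y570", klass="true", base_rate=outcome_rate, multiplier=conditional_or),
        AdrSpec(icd="N990", klass="null", base_rate=0.02),
        AdrSpec(icd="N991", klass="null", base_rate=0.02),
    ]
    return SimulationConfig(
        n_patients=n_patients,
        study_years=3.0,
        exposure_intercept=-1.2,
        comparator_uptake=0.45,
        bystander_prob=0.0,
        bystander_background=0.0,
        treatment_mean_days=500.0,
        adr_catalog=catalog,
        seed=seed,
    )


def with_seed(config: SimulationConfig, seed: int) -> SimulationConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
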