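"""Config-driven orchestration: simulate -> detect -> aggregate -> triage -> verify.

Each stage reads its inputs from and writes its artifacts to a single run
directory, so stages can be re-run independently (aggregation, for example,
re-ranks persisted score tables without refitting the detectors). A manifest
records the seed, the config hash and package versions. One global seed
deterministically derives a per-stage seed from the stage name, giving every
stage an independent stream under a single knob.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .borda import (
    BordaResult,
    HealthOutcome,
    MethodRanking,
    borda_aggregate,
    group_health_outcomes,
    kendall_tau_matrix,
    scores_to_ranking,
)
from .cohort import (
    CohortTables,
    EligibilityRules,
    StrataConfig,
    apply_eligibility,
    build_analysis_matrix,
    build_exposure_windows,
    build_pair_counts,
    build_person_time,
    load_tables,
    split_cohort,
)
from .disproportionality import bcpnn_scores, fit_gps_prior, gps_scores, lgps_expected
from .ml import lasso_scores, rf_scores
from .simulate import (
    COMPARATOR_ATC,
    TARGET_ATC,
    SimulationConfig,
    default_fixture,
    simulate_cohort,
    with_seed,
    write_tables,
)
from .verification import (
    classify_index_exposure,
    clr_fit,
    identify_cases,
    risk_set_match,
)

logger = logging.getLogger(__name__)

STAGES = ("simulate", "detect", "aggregate", "triage", "verify")

#: which score column each detector ranks on, and its direction
DETECTOR_SCORE = {
    "bcpnn": ("ic025", "higher_stronger"),
    "lgps": ("eb05", "higher_stronger"),
    "lasso": ("score", "higher_stronger"),
    "rf": ("score", "higher_stronger"),
}


def derive_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed from the single global seed."""
    return (int(global_seed) * 1_000_003 + zlib.crc32(stage.encode())) % (2**31)


@dataclass
class RunConfig:
    seed: int
    fixture: str | None = "tiny"  # packaged simulation, or None to load CSVs
    simulation: SimulationConfig | None = None  # explicit simulation config
    input_dir: str | None = None  # directory with persons/dispensations/diagnoses.csv
    target_atc: str = TARGET_ATC
    comparator_atc: str = COMPARATOR_ATC
    detection_fraction: float = 0.5
    split: bool = True
    min_enrollment_months: int = 12
    min_days_after_entry: int = 90
    washout_atc_prefixes: tuple[str, ...] = ("B01AF", "B01AA")
    washout_days: int = 365
    grace_days: int = 14
    min_count: int = 5
    age_band_width: int = 10
    detectors: tuple[str, ...] = ("bcpnn", "lgps", "lasso", "rf")
    weights: dict = field(default_factory=dict)
    detector_params: dict = field(default_factory=dict)
    outcomes: dict = field(default_factory=dict)  # name -> list of ICD codes
    verification_washout_days: int = 365
    m_max: int = 10
    contrasts: tuple[str, ...] = ("target_vs_comparator", "target_vs_none")
    confounders: dict = field(default_factory=dict)  # name -> list of ICD prefixes

    def __post_init__(self):
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if not self.detectors:
            raise ValueError("at least one detector must be enabled")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = raw.pop("simulation", None)
        cfg = cls(**raw)
        if sim is not None:
            from .simulate import AdrSpec

            catalog = [AdrSpec(**a) for a in sim.pop("adr_catalog", [])]
            cfg.simulation = SimulationConfig(adr_catalog=catalog, **sim)
            cfg.fixture = None
        return cfg

    def config_hash(self) -> str:
        payload = {
            k: (dataclasses.asdict(v) if dataclasses.is_dataclass(v) else v)
            for k, v in dataclasses.asdict(self).items()
        }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


class StageError(RuntimeError):
    def __init__(self, stage: str, err: Exception):
        super().__init__(f"stage {stage!r} failed: {err}")
        self.stage = stage


def run(config: RunConfig, outdir, stages: tuple[str, ...] = STAGES) -> Path:
    """Execute the requested stages in order; returns the artifact directory.

    A stage failure aborts the run with the stage name; artifacts written by
    completed stages persist.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    unknown = set(stages) - set(STAGES)
    if unknown:
        raise ValueError(f"unknown stage(s): {sorted(unknown)}")
    stages = tuple(s for s in STAGES if s in stages)
    for stage in stages:
        logger.info("running stage %s", stage)
        try:
            _STAGE_FUNCS[stage](config, outdir)
        except Exception as err:
            raise StageError(stage, err) from err
    manifest = {
        "package": "pvborda",
        "version": __version__,
        "seed": config.seed,
        "config_hash": config.config_hash(),
        "stages": list(stages),
        "numpy": np.__version__,
        "pandas": pd.__version__,
    }
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
    return outdir


def _stage_simulate(config: RunConfig, outdir: Path) -> None:
    if config.simulation is None and config.fixture is None:
        return  # running on user-supplied CSVs
    sim = config.simulation or default_fixture(config.fixture)
    sim = with_seed(sim, derive_seed(config.seed, "simulate"))
    tables, truth = simulate_cohort(sim)
    write_tables(tables, outdir / "data", truth)


def _load(config: RunConfig, outdir: Path) -> CohortTables:
    data_dir = Path(config.input_dir) if config.input_dir else outdir / "data"
    return load_tables(
        data_dir / "persons.csv", data_dir / "dispensations.csv", data_dir / "diagnoses.csv"
    )


def _detection_ids(config: RunConfig, tables: CohortTables, part: str) -> pd.Index:
    if not config.split:
        return pd.Index(tables.persons["patient_id"]).sort_values()
    det, ver = split_cohort(
        tables.persons, config.detection_fraction, derive_seed(config.seed, "split")
    )
    return det if part == "detection" else ver


def _stage_detect(config: RunConfig, outdir: Path) -> None:
    tables = _load(config, outdir)
    det_ids = _detection_ids(config, tables, "detection")
    tables = CohortTables(
        tables.persons[tables.persons["patient_id"].isin(det_ids)].reset_index(drop=True),
        tables.dispensations[tables.dispensations["patient_id"].isin(det_ids)].reset_index(drop=True),
        tables.diagnoses[tables.diagnoses["patient_id"].isin(det_ids)].reset_index(drop=True),
    )
    rules = EligibilityRules(
        target_atc=config.target_atc,
        min_enrollment_months=config.min_enrollment_months,
        min_days_after_entry=config.min_days_after_entry,
        washout_atc_prefixes=config.washout_atc_prefixes,
        washout_days=config.washout_days,
        require_target_use=False,  # keep never-users as the unexposed pool
    )
    elig = apply_eligibility(tables, rules)
    elig.attrition.to_csv(outdir / "attrition.csv", index=False)
    matrix = build_analysis_matrix(
        tables,
        elig.eligible_ids,
        config.target_atc,
        min_count=config.min_count,
        min_days_after_entry=config.min_days_after_entry,
        grace_days=config.grace_days,
    )
    params = config.detector_params
    if "bcpnn" in config.detectors:
        counts = build_pair_counts(matrix)
        sc = bcpnn_scores(counts)
        sc.rename(columns={"ic025": "score", "ic": "aux1"}).assign(aux2=np.nan).to_csv(
            outdir / "scores_bcpnn.csv"
        )
    if "lgps" in config.detectors:
        windows = build_exposure_windows(
            tables.dispensations, config.target_atc, config.grace_days
        )
        pt = build_person_time(
            tables,
            windows,
            StrataConfig(age_band_width=config.age_band_width),
            eligible_ids=elig.eligible_ids,
            codes=matrix.adr_codes,
        )
        oe = lgps_expected(pt)
        prior = fit_gps_prior(
            oe["O"].to_numpy(), oe["E"].to_numpy(), seed=derive_seed(config.seed, "lgps")
        )
        logger.info("lgps prior: %s", prior)
        sc = gps_scores(oe["O"].to_numpy(), oe["E"].to_numpy(), prior, codes=oe.index)
        sc.rename(columns={"eb05": "score", "ebgm": "aux1", "q_post": "aux2"})[
            ["score", "aux1", "aux2"]
        ].to_csv(outdir / "scores_lgps.csv")
    if "lasso" in config.detectors:
        fit = lasso_scores(
            matrix, seed=derive_seed(config.seed, "lasso"), **params.get("lasso", {})
        )
        fit.scores.rename(columns={"beta": "aux1"}).assign(aux2=fit.lambda_selected)[
            ["score", "aux1", "aux2"]
        ].to_csv(outdir / "scores_lasso.csv")
    if "rf" in config.detectors:
        fit = rf_scores(matrix, seed=derive_seed(config.seed, "rf"), **params.get("rf", {}))
        fit.scores.rename(columns={"importance": "aux1"}).assign(aux2=fit.n_trees)[
            ["score", "aux1", "aux2"]
        ].to_csv(outdir / "scores_rf.csv")


def load_score_tables(outdir: Path, detectors) -> list[MethodRanking]:
    rankings = []
    for det in detectors:
        path = Path(outdir) / f"scores_{det}.csv"
        scores = pd.read_csv(path, index_col="icd")
        _, direction = DETECTOR_SCORE[det]
        rankings.append(
            scores_to_ranking(scores["score"], method_id=det, direction=direction)
        )
    return rankings


def _stage_aggregate(config: RunConfig, outdir: Path) -> None:
    rankings = load_score_tables(outdir, config.detectors)
    weights = config.weights or None
    result = borda_aggregate(rankings, weights=weights)
    result.table.to_csv(outdir / "borda_ranking.csv")
    if len(rankings) > 1:
        kendall_tau_matrix(rankings).to_csv(outdir / "tau_matrix.csv")


def _stage_triage(config: RunConfig, outdir: Path) -> None:
    if not config.outcomes:
        return
    table = pd.read_csv(outdir / "borda_ranking.csv", index_col="icd")
    result = BordaResult(table=table)
    outcomes = [HealthOutcome(name, codes) for name, codes in config.outcomes.items()]
    members, summary = group_health_outcomes(result, outcomes)
    members.to_csv(outdir / "outcome_groups.csv", index=False)
    summary.to_csv(outdir / "outcome_summary.csv", index=False)


def _stage_verify(config: RunConfig, outdir: Path) -> None:
    if not config.outcomes:
        return
    tables = _load(config, outdir)
    ver_ids = _detection_ids(config, tables, "verification")
    persons = tables.persons[tables.persons["patient_id"].isin(ver_ids)].reset_index(drop=True)
    sub = CohortTables(
        persons,
        tables.dispensations[tables.dispensations["patient_id"].isin(ver_ids)].reset_index(drop=True),
        tables.diagnoses[tables.diagnoses["patient_id"].isin(ver_ids)].reset_index(drop=True),
    )
    windows = {
        "target": build_exposure_windows(sub.dispensations, config.target_atc, config.grace_days),
        "comparator": build_exposure_windows(
            sub.dispensations, config.comparator_atc, config.grace_days
        ),
    }
    rows = []
    all_sets = []
    for name, codes in config.outcomes.items():
        outcome = HealthOutcome(name, codes)
        cases = identify_cases(sub, outcome, config.verification_washout_days)
        if cases.empty:
            logger.warning("verification: no incident cases for outcome %r", name)
            continue
        matched = risk_set_match(
            cases,
            persons,
            sub.diagnoses,
            outcome,
            m_max=config.m_max,
            seed=derive_seed(config.seed, f"match:{name}"),
        )
        cats = classify_index_exposure(matched, windows)
        confounders = _confounder_frame(sub, matched, config.confounders.get(name))
        all_sets.append(matched.assign(outcome=name, category=cats.to_numpy()))
        for contrast in config.contrasts:
            try:
                fits = clr_fit(matched, cats, contrast=contrast, confounders=confounders)
            except ValueError as err:
                logger.warning("verification %s/%s: %s", name, contrast, err)
                continue
            for model_name, fit in fits.items():
                rows.append(
                    {
                        "outcome": name,
                        "contrast": contrast,
                        "model": model_name,
                        "or": fit.or_,
                        "lo95": fit.ci95[0],
                        "hi95": fit.ci95[1],
                        "n_cases": fit.n_cases,
                        "n_controls": fit.n_controls,
                        "n_sets_informative": fit.n_sets_informative,
                        "estimable": fit.estimable,
                    }
                )
    if all_sets:
        pd.concat(all_sets, ignore_index=True)[
            ["outcome", "set_id", "role", "patient_id", "index_day", "category"]
        ].to_csv(outdir / "matched_sets.csv", index=False)
    pd.DataFrame(
        rows,
        columns=[
            "outcome", "contrast", "model", "or", "lo95", "hi95",
            "n_cases", "n_controls", "n_sets_informative", "estimable",
        ],
    ).to_csv(outdir / "clr_results.csv", index=False)


def _confounder_frame(tables: CohortTables, matched: pd.DataFrame, prefixes):
    """0/1 history indicators (any matching diagnosis before index) per subject row."""
    if not prefixes:
        return None
    d = tables.diagnoses
    out = {}
    sub = matched[["patient_id", "index_day"]].reset_index(drop=True)
    for prefix in prefixes:
        hit = d[d["icd"].str.startswith(prefix)]
        m = sub.reset_index().merge(hit, on="patient_id", how="left")
        before = m["event_date"] < m["index_day"]
        out[f"hx_{prefix}"] = (
            before.groupby(m["index"]).any().reindex(range(len(sub)), fill_value=False).astype(float)
        )
    return pd.DataFrame(out).set_axis(matched.index)


_STAGE_FUNCS = {
    "simulate": _stage_simulate,
    "detect": _stage_detect,
    "aggregate": _stage_aggregate,
    "triage": _stage_triage,
    "verify": _stage_verify,
}
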