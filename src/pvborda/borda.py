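"""Borda-count rank aggregation of signal-detection methods.

Each detection method is a voter: its scores are converted to a ranking over
drug-event pairs (rank 1 = strongest signal, rank P = no signal), the Borda
count of a pair is the (optionally weighted) sum of its per-method ranks, and
the pair with the smallest count tops the consensus ranking. Ties are handled
tournament-style throughout: tied items share the best rank of their block
and the next block skips by the block size (competition ranking, 1-2-2-4),
which keeps counts integral under unit weights; midranks (1-2.5-2.5-4) are
available via ``tie_method="midrank"``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import normalize_icd

logger = logging.getLogger(__name__)


def _rank(values: np.ndarray, tie_method: str) -> np.ndarray:
    """Rank ascending values (smallest = rank 1) with the chosen tie policy."""
    if tie_method == "competition":
        return stats.rankdata(values, method="min").astype(float)
    if tie_method == "midrank":
        return stats.rankdata(values, method="average")
    raise ValueError(f"unknown tie_method {tie_method!r}")


@dataclass
class MethodRanking:
    """One voter's ranking: code -> rank, 1 = strongest signal."""

    method_id: str
    ranks: pd.Series  # index icd, float ranks

    @property
    def P(self) -> int:
        return len(self.ranks)


def scores_to_ranking(
    scores: pd.Series | pd.DataFrame,
    method_id: str = "",
    direction: str = "higher_stronger",
    tie_method: str = "competition",
) -> MethodRanking:
    """Convert per-code scores into a ranking.

    ``direction`` says whether larger scores mean stronger signals. Missing
    scores (NaN) are treated as the weakest possible signal and logged.
    """
    if isinstance(scores, pd.DataFrame):
        scores = scores["score"]
    if len(scores) == 0:
        raise ValueError("empty score table")
    if direction not in ("higher_stronger", "lower_stronger"):
        raise ValueError(f"unknown direction {direction!r}")
    s = scores.astype(float)
    n_missing = int(s.isna().sum())
    if n_missing:
        logger.warning(
            "%s: %d missing scores ranked weakest", method_id or "scores_to_ranking", n_missing
        )
    key = -s if direction == "higher_stronger" else s
    # NaN -> +inf sorts to the weak end either way
    key = key.fillna(np.inf)
    ranks = pd.Series(_rank(key.to_numpy(), tie_method), index=s.index)
    return MethodRanking(method_id=method_id, ranks=ranks)


@dataclass
class BordaResult:
    """Aggregated ranking: per code the Borda count, final and relative rank."""

    table: pd.DataFrame  # index icd; columns borda_count, final_rank, relative_rank
    weights: dict = field(default_factory=dict)

    @property
    def P(self) -> int:
        return len(self.table)


def borda_aggregate(
    rankings: list[MethodRanking],
    weights: dict[str, float] | None = None,
    tie_method: str = "competition",
) -> BordaResult:
    """Weighted Borda aggregation of method rankings over a common code set.

    count(j) = sum_q w_q * rank_q(j); smaller counts rank first. Ties in the
    counts share the competition rank; within a tie block the display order
    is alphabetical by code, which affects presentation only, never ranks.
    """
    if not rankings:
        raise ValueError("need at least one ranking")
    base = set(rankings[0].ranks.index)
    for r in rankings[1:]:
        other = set(r.ranks.index)
        if other != base:
            diff = sorted(base.symmetric_difference(other))
            raise ValueError(
                f"rankings disagree on the code set (method {r.method_id!r}); "
                f"symmetric difference: {diff}"
            )
    if weights is None:
        weights = {r.method_id: 1.0 for r in rankings}
    for r in rankings:
        if weights.get(r.method_id, 0) <= 0:
            raise ValueError(f"weight for method {r.method_id!r} must be positive")

    codes = sorted(base)
    counts = np.zeros(len(codes))
    for r in rankings:
        counts += weights[r.method_id] * r.ranks.reindex(codes).to_numpy()
    final = _rank(counts, tie_method)
    P = len(codes)
    rel = (final - 1) / (P - 1) if P > 1 else np.zeros(P)
    table = pd.DataFrame(
        {"borda_count": counts, "final_rank": final, "relative_rank": rel},
        index=pd.Index(codes, name="icd"),
    ).sort_values(["borda_count", "icd"])
    return BordaResult(table=table, weights=dict(weights))


def relative_ranks(result: BordaResult) -> pd.Series:
    """(final_rank - 1) / (P - 1): 0 = strongest signal, 1 = no signal."""
    return result.table["relative_rank"]


def kendall_tau_matrix(rankings: list[MethodRanking]) -> pd.DataFrame:
    """Kendall tau-b correlation between every pair of method rankings.

    Tau-b corrects for ties, which the competition rankings contain by
    construction. A constant ranking has undefined correlation and is
    reported as NaN, not 0.
    """
    ids = [r.method_id for r in rankings]
    codes = sorted(rankings[0].ranks.index)
    mat = pd.DataFrame(np.eye(len(rankings)), index=ids, columns=ids)
    for i in range(len(rankings)):
        for j in range(i + 1, len(rankings)):
            a = rankings[i].ranks.reindex(codes).to_numpy()
            b = rankings[j].ranks.reindex(codes).to_numpy()
            if len(np.unique(a)) < 2 or len(np.unique(b)) < 2:
                tau = np.nan
            else:
                tau = stats.kendalltau(a, b).statistic
            mat.iloc[i, j] = mat.iloc[j, i] = tau
    return mat


@dataclass(frozen=True)
class HealthOutcome:
    """A named, expert-defined set of ICD codes treated as one clinical entity."""

    name: str
    codes: frozenset[str]

    def __init__(self, name: str, codes):
        object.__setattr__(self, "name", name)
        normalized = frozenset(normalize_icd(c) for c in codes)
        if not normalized:
            raise ValueError(f"health outcome {name!r} has an empty code set")
        object.__setattr__(self, "codes", normalized)


def group_health_outcomes(
    result: BordaResult, outcomes: list[HealthOutcome]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Relative ranks of each outcome's member codes, for dot-plot triage.

    Returns (members, summary): ``members`` has one row per (outcome, code)
    with the code's relative rank (NaN if the code was not ranked);
    ``summary`` has per-outcome min and median over present codes plus
    missing-code counts. Outcomes with no ranked member are flagged.
    """
    rel = result.table["relative_rank"]
    rows = []
    for oc in outcomes:
        for code in sorted(oc.codes):
            rows.append(
                {
                    "outcome": oc.name,
                    "icd": code,
                    "relative_rank": rel.get(code, np.nan),
                    "present": code in rel.index,
                }
            )
    members = pd.DataFrame(rows, columns=["outcome", "icd", "relative_rank", "present"])
    summary_rows = []
    for oc in outcomes:
        sub = members[(members["outcome"] == oc.name) & members["present"]]
        summary_rows.append(
            {
                "outcome": oc.name,
                "n_present": len(sub),
                "n_missing": len(oc.codes) - len(sub),
                "min_relative_rank": sub["relative_rank"].min() if len(sub) else np.nan,
                "median_relative_rank": sub["relative_rank"].median() if len(sub) else np.nan,
            }
        )
        if not len(sub):
            logger.warning("health outcome %r has no codes in the ranking", oc.name)
    return members, pd.DataFrame(summary_rows)
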