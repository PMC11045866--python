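"""Composite FMT donor selection from metabolic and microbiota-shift data.

The procedure ranks an intervention cohort three times:

1. *Metabolic*: each of six clinical parameters (waist-to-hip ratio, BMI,
   free fat mass, cholesterol, triglycerides, fasting glucose) yields a
   ranking by improvement; the six ranks are combined by mean rank (Borda).
2. *Microbiota shift*: among the top metabolic responders, paired pre/post
   community shifts measured by Bray-Curtis and weighted UniFrac each yield
   a ranking; combined again by mean rank.
3. *Overall*: the mean of the (within-eligible-set) metabolic rank and the
   gut rank orders the final donor list.

Ties share the mean rank throughout; the final tie-break is lexicographic
on (metabolic rank, participant id), which is deterministic and auditable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "METABOLIC_PARAMETERS",
    "DEFAULT_DIRECTIONS",
    "RankingResult",
    "rank_metabolic",
    "rank_microbiota_shift",
    "select_donors",
]

METABOLIC_PARAMETERS = (
    "waist_to_hip_ratio",
    "body_mass_index",
    "free_fat_mass",
    "cholesterol",
    "triglycerides",
    "glucose",
)

# +1: a decrease pre -> post is an improvement; -1: an increase is.
# "free fat mass" defaults to increase-is-good (read as fat-free mass);
# the direction is configurable because the term is ambiguous.
DEFAULT_DIRECTIONS = {
    "waist_to_hip_ratio": +1,
    "body_mass_index": +1,
    "free_fat_mass": -1,
    "cholesterol": +1,
    "triglycerides": +1,
    "glucose": +1,
}


@dataclass
class RankingResult:
    """Per-stage ranking with full per-criterion audit trail."""

    ranks: pd.DataFrame  # per-criterion ranks, one row per participant
    combined_score: pd.Series  # mean rank across criteria
    final_rank: pd.Series  # rank of the combined score (1 = best, ties mean)
    stage: str

    def ordered_ids(self) -> list:
        return list(self.final_rank.sort_values(kind="mergesort").index)


def _rank_desc(values: pd.Series) -> pd.Series:
    """Rank with 1 = largest value; ties share the mean rank."""
    return pd.Series(rankdata(-values.to_numpy()), index=values.index)


def rank_metabolic(
    cohort: pd.DataFrame,
    directions: dict | None = None,
    percent_of_baseline: bool = False,
) -> RankingResult:
    """Rank participants by improvement across the six metabolic parameters.

    ``cohort`` must carry ``<param>_pre`` / ``<param>_post`` columns indexed
    by participant id.  Improvement = direction x (pre - post), optionally
    divided by the baseline value.  Participants with any missing value are
    excluded with a warning.
    """
    directions = dict(DEFAULT_DIRECTIONS if directions is None else directions)
    missing_dirs = [p for p in METABOLIC_PARAMETERS if p not in directions]
    if missing_dirs:
        raise ValueError(f"improvement direction missing for: {missing_dirs}")
    cols = [f"{p}_{t}" for p in METABOLIC_PARAMETERS for t in ("pre", "post")]
    absent = [c for c in cols if c not in cohort.columns]
    if absent:
        raise ValueError(f"cohort lacks columns: {absent}")

    usable = cohort[cols].dropna()
    dropped = cohort.index.difference(usable.index)
    if len(dropped):
        warnings.warn(
            f"excluding participants with missing values: {list(dropped)}",
            stacklevel=2,
        )
    if len(usable) < 2:
        raise ValueError("need at least 2 complete participants to rank")

    ranks = {}
    for param in METABOLIC_PARAMETERS:
        delta = usable[f"{param}_pre"] - usable[f"{param}_post"]
        improvement = directions[param] * delta
        if percent_of_baseline:
            improvement = improvement / usable[f"{param}_pre"]
        ranks[param] = _rank_desc(improvement)
    rank_frame = pd.DataFrame(ranks)
    combined = rank_frame.mean(axis=1)
    final = pd.Series(rankdata(combined.to_numpy()), index=combined.index)
    return RankingResult(rank_frame, combined, final, "metabolic")


def rank_microbiota_shift(shifts: pd.DataFrame) -> RankingResult:
    """Combine Bray-Curtis and weighted UniFrac shift rankings (1 = largest
    shift) into one gut bacterial ranking by mean rank."""
    for col in ("bc_shift", "wu_shift"):
        if col not in shifts.columns:
            raise ValueError(f"shift table lacks column {col!r}")
        if shifts[col].isna().any():
            bad = list(shifts.index[shifts[col].isna()])
            raise ValueError(f"missing {col} for participants: {bad}")
    rank_frame = pd.DataFrame(
        {
            "bc_shift": _rank_desc(shifts["bc_shift"]),
            "wu_shift": _rank_desc(shifts["wu_shift"]),
        }
    )
    combined = rank_frame.mean(axis=1)
    final = pd.Series(rankdata(combined.to_numpy()), index=combined.index)
    return RankingResult(rank_frame, combined, final, "microbiota")


def select_donors(
    metabolic: RankingResult,
    gut: RankingResult,
    top_metabolic: int = 10,
    n_donors: int = 5,
) -> tuple[list, pd.DataFrame]:
    """Final donor selection among the top metabolic responders.

    ``gut`` must be computed on exactly the ``top_metabolic`` best metabolic
    responders.  Overall score = mean of the metabolic rank re-ranked within
    the eligible set and the gut rank; ties broken on (metabolic rank,
    participant id).  Returns the ordered donor list and the audit table.
    """
    eligible = list(gut.final_rank.index)
    expected = set(metabolic.ordered_ids()[:top_metabolic])
    if len(eligible) != top_metabolic or set(eligible) != expected:
        # tolerate tie-induced differences only if the sets agree
        if set(eligible) != expected:
            raise ValueError(
                "gut ranking must cover exactly the top metabolic responders"
            )
    if n_donors > len(eligible):
        raise ValueError(
            f"cannot select {n_donors} donors from {len(eligible)} eligible"
        )

    met_within = pd.Series(
        rankdata(metabolic.combined_score.loc[eligible].to_numpy()),
        index=eligible,
    )
    overall = (met_within + gut.final_rank.loc[eligible]) / 2.0
    audit = pd.DataFrame(
        {
            "metabolic_rank_full": metabolic.final_rank.loc[eligible],
            "metabolic_rank_eligible": met_within,
            "gut_rank": gut.final_rank.loc[eligible],
            "overall_score": overall,
        }
    )
    # stable sorts: participant id breaks remaining ties deterministically
    audit = audit.sort_index(kind="mergesort").sort_values(
        by=["overall_score", "metabolic_rank_eligible"], kind="mergesort"
    )
    audit["overall_rank"] = np.arange(1, len(audit) + 1)
    donors = list(audit.index[:n_donors])
    return donors, audit
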