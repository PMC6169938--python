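"""Combined clinical × genetic risk scores and their log transforms."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import math

import numpy as np
import pandas as pd

from .gail import AbsoluteRiskPair
from .io import SubjectRecord
from .prs import PrsResult

LOG_COLUMNS = ("log_bcrat_5yr", "log_bcrat_lifetime", "log_snp", "log_combined_5yr", "log_combined_lifetime")


@dataclass
class RiskScoreSet:
    """All five scores for one subject, raw and natural-log transformed.

    Combined scores are the SNP score multiplied into the clinical
    absolute risk, capped at 1 so they retain probability semantics for
    threshold-based reclassification.
    """

    subject_id: str
    bcrat_5yr: float
    bcrat_lifetime: float
    snp_score: float
    combined_5yr: float
    combined_lifetime: float
    log_bcrat_5yr: Optional[float] = None
    log_bcrat_lifetime: Optional[float] = None
    log_snp: Optional[float] = None
    log_combined_5yr: Optional[float] = None
    log_combined_lifetime: Optional[float] = None


def combine(snp_score: float, absolute_risk: float) -> float:
    """min(1, snp_score * absolute_risk)."""
    if snp_score <= 0:
        raise ValueError(f"snp_score must be > 0, got {snp_score}")
    if not 0.0 < absolute_risk <= 1.0:
        raise ValueError(f"absolute risk must be in (0,1], got {absolute_risk}")
    return min(1.0, snp_score * absolute_risk)


def build_score_sets(
    prs_results: Sequence[PrsResult],
    risk_pairs: Sequence[AbsoluteRiskPair],
) -> list[RiskScoreSet]:
    """Join PRS and absolute-risk results by subject and combine them."""
    prs_by_id = {r.subject_id: r for r in prs_results}
    out = []
    for pair in risk_pairs:
        prs = prs_by_id.get(pair.subject_id)
        if prs is None:
            raise ValueError(f"no SNP score for subject {pair.subject_id!r}")
        out.append(
            RiskScoreSet(
                subject_id=pair.subject_id,
                bcrat_5yr=pair.five_year,
                bcrat_lifetime=pair.lifetime,
                snp_score=prs.snp_score,
                combined_5yr=combine(prs.snp_score, pair.five_year),
                combined_lifetime=combine(prs.snp_score, pair.lifetime),
            )
        )
    return out


def log_transform_scores(scores: Sequence[RiskScoreSet]) -> Sequence[RiskScoreSet]:
    """Populate the natural-log fields of every score set, in place."""
    for s in scores:
        raw = {
            "log_bcrat_5yr": s.bcrat_5yr,
            "log_bcrat_lifetime": s.bcrat_lifetime,
            "log_snp": s.snp_score,
            "log_combined_5yr": s.combined_5yr,
            "log_combined_lifetime": s.combined_lifetime,
        }
        for name, value in raw.items():
            if value <= 0:
                raise ValueError(f"subject {s.subject_id!r}: nonpositive score for {name[4:]} ({value})")
            setattr(s, name, math.log(value))
    return scores


def score_correlations(scores: Sequence[RiskScoreSet]) -> pd.DataFrame:
    """Pearson correlation matrix of the five log-transformed scores.

    Zero-variance columns yield NaN correlations for their pairs.
    """
    if len(scores) < 3:
        raise ValueError("need at least 3 subjects for correlations")
    if any(getattr(scores[0], c) is None for c in LOG_COLUMNS):
        scores = log_transform_scores(list(scores))
    df = pd.DataFrame({c: [getattr(s, c) for s in scores] for c in LOG_COLUMNS})
    corr = df.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    return corr


def scores_to_frame(scores: Sequence[RiskScoreSet], subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Flat per-subject table: status, age and the five scores."""
    by_id = {s.subject_id: s for s in subjects}
    rows = []
    for s in scores:
        rec = by_id.get(s.subject_id)
        rows.append(
            {
                "subject_id": s.subject_id,
                "status": rec.status if rec else None,
                "age": rec.age if rec else None,
                "bcrat_5yr": s.bcrat_5yr,
                "bcrat_lifetime": s.bcrat_lifetime,
                "snp_score": s.snp_score,
                "combined_5yr": s.combined_5yr,
                "combined_lifetime": s.combined_lifetime,
            }
        )
    return pd.DataFrame(rows)


__all__ = [
    "LOG_COLUMNS",
    "RiskScoreSet",
    "combine",
    "build_score_sets",
    "log_transform_scores",
    "score_correlations",
    "scores_to_frame",
]
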