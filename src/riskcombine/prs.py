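"""Normalized SNP-based relative risk score.

Each SNP contributes the factor ``OR**dosage / mu``, where ``mu`` is the
Hardy–Weinberg population-average risk for that SNP, so every factor has
expectation 1 in the source population and the product score is centred
near 1.  Missing genotypes contribute a neutral factor of 1 and are
counted per subject.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .io import GenotypeMatrix, SnpPanelEntry, SubjectRecord


@dataclass(frozen=True)
class PrsResult:
    subject_id: str
    snp_score: float
    n_missing: int


def population_average_risk(p: float, or_: float) -> float:
    """HWE-weighted mean per-genotype relative risk of one SNP.

    Returns ``(1-p)^2 + 2 p (1-p) OR + p^2 OR^2``.
    """
    if not 0.0 <= p <= 1.0:
        raise ValueError(f"risk allele frequency must be in [0,1], got {p}")
    if or_ <= 0:
        raise ValueError(f"per-allele OR must be > 0, got {or_}")
    return (1 - p) ** 2 + 2 * p * (1 - p) * or_ + p**2 * or_**2


def adjusted_risk_value(dosage: int, or_: float, mu: float) -> float:
    """Per-genotype relative risk normalized by the population average.

    Returns ``OR**dosage / mu`` for a risk-allele dosage in {0, 1, 2}.
    """
    if dosage not in (0, 1, 2):
        raise ValueError(f"dosage must be in {{0,1,2}}, got {dosage}")
    if mu <= 0:
        raise ValueError(f"mu must be > 0, got {mu}")
    return or_**dosage / mu


def compute_prs(genotypes: GenotypeMatrix, panel: Sequence[SnpPanelEntry]) -> list[PrsResult]:
    """Per-subject product of adjusted risk values over non-missing SNPs.

    Accumulated in log space: ``log score = sum(dosage * log(OR) - log(mu))``
    over observed SNPs, which avoids underflow for large panels.
    """
    if len(panel) == 0:
        raise ValueError("empty SNP panel")
    if genotypes.rsids != [e.rsid for e in panel]:
        raise ValueError("genotype matrix columns are not aligned to the panel")
    log_or = np.log([e.per_allele_or for e in panel])
    log_mu = np.log([e.mu for e in panel])
    dosages = genotypes.dosages
    observed = ~np.isnan(dosages)
    log_scores = np.where(observed, np.nan_to_num(dosages) * log_or - log_mu, 0.0).sum(axis=1)
    n_missing = (~observed).sum(axis=1)
    return [
        PrsResult(subject_id=sid, snp_score=float(np.exp(ls)), n_missing=int(nm))
        for sid, ls, nm in zip(genotypes.subject_ids, log_scores, n_missing)
    ]


def prs_summary(results: Sequence[PrsResult], subjects: Sequence[SubjectRecord]) -> pd.DataFrame:
    """Mean and SD of the SNP score, overall and by case/control status."""
    status_by_id = {s.subject_id: s.status for s in subjects}
    rows = [(status_by_id[r.subject_id], r.snp_score) for r in results if r.subject_id in status_by_id]
    if not rows:
        raise ValueError("no overlap between PRS results and subject records")
    df = pd.DataFrame(rows, columns=["status", "snp_score"])

    def _stats(scores: pd.Series) -> tuple[float, float, int]:
        sd = float(scores.std(ddof=1)) if len(scores) > 1 else 0.0
        if len(scores) == 1:
            import logging

            logging.getLogger(__name__).warning("single-subject stratum: SD reported as 0")
        return float(scores.mean()), sd, len(scores)

    out = {}
    out["overall"] = _stats(df["snp_score"])
    for status, grp in df.groupby("status"):
        out[str(status)] = _stats(grp["snp_score"])
    return pd.DataFrame(out, index=["mean", "sd", "n"]).T


def prs_to_frame(results: Sequence[PrsResult]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "subject_id": [r.subject_id for r in results],
            "snp_score": [r.snp_score for r in results],
            "n_missing": [r.n_missing for r in results],
        }
    )


__all__ = [
    "PrsResult",
    "population_average_risk",
    "adjusted_risk_value",
    "compute_prs",
    "prs_summary",
    "prs_to_frame",
]
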