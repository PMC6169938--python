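"""Seeded synthetic cohort generator with known ground-truth effects.

Generates every pipeline input — SNP panel, Hardy–Weinberg genotypes,
questionnaire records, hazard tables — and assigns case/control status
from a logistic model on the true log clinical and log SNP scores, so
parameter-recovery and null-calibration tests can run without any
external data.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
from scipy.optimize import brentq
from scipy.special import expit

from . import gail, prs
from .gail import AbsoluteRiskPair, HazardTable, RelativeRiskModel
from .io import (
    NULLIPAROUS,
    CohortDataset,
    GenotypeMatrix,
    SnpPanelEntry,
    SubjectRecord,
)

_BASES = "ACGT"

# Control-like marginal distributions for questionnaire draws (observed
# categories only; missingness is applied separately per field).
_AGE_BANDS = [(35, 40), (40, 45), (45, 50), (50, 55), (55, 60), (60, 65), (65, 70), (70, 75), (75, 86)]
_AGE_WEIGHTS = [0.070, 0.123, 0.157, 0.227, 0.181, 0.095, 0.082, 0.038, 0.027]
_MENARCHE_AGES = [9, 10, 11, 12, 13, 14, 15, 16, 17]
_MENARCHE_WEIGHTS = [0.046, 0.097, 0.101, 0.305, 0.217, 0.101, 0.059, 0.048, 0.028]
_FIRST_BIRTH_BANDS = [(15, 20), (20, 25), (25, 30), (30, 35), (35, 41)]
_FIRST_BIRTH_WEIGHTS = [0.382, 0.384, 0.139, 0.078, 0.017]
_FDR_CATEGORIES = ["0", "1", "2+"]
_FDR_WEIGHTS = [0.849, 0.138, 0.013]
_BIOPSY_COUNTS = [0, 1, 2]
_BIOPSY_WEIGHTS = [0.775, 0.175, 0.05]
_HYPERPLASIA_WEIGHTS = {"no": 0.9, "yes": 0.1}


def _norm(weights) -> np.ndarray:
    w = np.asarray(weights, dtype=float)
    return w / w.sum()


_MENARCHE_WEIGHTS = _norm(_MENARCHE_WEIGHTS)
_FDR_WEIGHTS = _norm(_FDR_WEIGHTS)
_BIOPSY_WEIGHTS = _norm(_BIOPSY_WEIGHTS)


@dataclass(frozen=True)
class SimulationConfig:
    """Everything that determines one synthetic cohort."""

    n_snps: int = 75
    freq_range: tuple[float, float] = (0.1, 0.9)
    log_or_mean: float = 0.0
    log_or_sd: float = 0.1
    n_cases: int = 319
    n_controls: int = 559
    genetic_effect: float = 1.0
    clinical_effect: float = 1.0
    genotype_missing_rate: float = 0.0
    questionnaire_missing_rates: dict[str, float] = field(
        default_factory=lambda: {
            "n_first_degree_relatives": 0.22,
            "age_menarche": 0.03,
            "age_first_birth": 0.15,
            "n_biopsies": 0.93,
            "hyperplasia": 0.93,
        }
    )
    nulliparous_prob: float = 0.05
    family_history_oversampling: bool = False
    family_history_log_enrichment: float = math.log(2.0)
    age_matching: bool = True
    pool_factor: float = 4.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_snps <= 0 or self.n_cases <= 0 or self.n_controls <= 0:
            raise ValueError("counts must be positive")
        lo, hi = self.freq_range
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"degenerate frequency range {self.freq_range}")
        if not 0.0 <= self.genotype_missing_rate <= 1.0:
            raise ValueError("genotype_missing_rate must be in [0,1]")
        for name, rate in self.questionnaire_missing_rates.items():
            if not 0.0 <= rate <= 1.0:
                raise ValueError(f"missing rate for {name} must be in [0,1]")


def simulate_panel(config: SimulationConfig, rng: Optional[np.random.Generator] = None) -> list[SnpPanelEntry]:
    """Draw a panel of independent SNPs with lognormal per-allele ORs."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    freqs = rng.uniform(*config.freq_range, size=config.n_snps)
    ors = np.exp(rng.normal(config.log_or_mean, config.log_or_sd, size=config.n_snps))
    return [
        SnpPanelEntry(
            rsid=f"rs{i:05d}",
            risk_allele=_BASES[rng.integers(4)],
            per_allele_or=float(ors[i]),
            risk_allele_freq=float(freqs[i]),
        )
        for i in range(config.n_snps)
    ]


def simulate_genotypes(
    panel: Sequence[SnpPanelEntry],
    n_subjects: int,
    seed_or_rng: Union[int, np.random.Generator] = 0,
    missing_rate: float = 0.0,
    subject_ids: Optional[Sequence[str]] = None,
) -> GenotypeMatrix:
    """HWE dosages: Binomial(2, p) per SNP, independently across SNPs."""
    rng = seed_or_rng if isinstance(seed_or_rng, np.random.Generator) else np.random.default_rng(seed_or_rng)
    freqs = np.array([e.risk_allele_freq for e in panel])
    dosages = rng.binomial(2, freqs, size=(n_subjects, len(panel))).astype(float)
    if missing_rate > 0:
        dosages[rng.random(dosages.shape) < missing_rate] = np.nan
    if subject_ids is None:
        subject_ids = [f"S{i:06d}" for i in range(n_subjects)]
    return GenotypeMatrix(subject_ids=list(subject_ids), rsids=[e.rsid for e in panel], dosages=dosages)


def _draw_band_value(rng: np.random.Generator, bands, weights) -> int:
    lo, hi = bands[rng.choice(len(bands), p=np.asarray(weights) / np.sum(weights))]
    return int(rng.integers(lo, hi))


def simulate_questionnaire(
    n_subjects: int,
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> list[SubjectRecord]:
    """Draw questionnaire records (status unset) with per-field missingness."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    miss = config.questionnaire_missing_rates
    records = []
    for i in range(n_subjects):
        fdr = None
        if rng.random() >= miss.get("n_first_degree_relatives", 0.0):
            fdr = _FDR_CATEGORIES[rng.choice(3, p=_FDR_WEIGHTS)]
        menarche = None
        if rng.random() >= miss.get("age_menarche", 0.0):
            menarche = int(_MENARCHE_AGES[rng.choice(len(_MENARCHE_AGES), p=_MENARCHE_WEIGHTS)])
        afb: Union[int, str, None] = None
        if rng.random() >= miss.get("age_first_birth", 0.0):
            if rng.random() < config.nulliparous_prob:
                afb = NULLIPAROUS
            else:
                afb = _draw_band_value(rng, _FIRST_BIRTH_BANDS, _FIRST_BIRTH_WEIGHTS)
        biopsies = None
        if rng.random() >= miss.get("n_biopsies", 0.0):
            biopsies = int(_BIOPSY_COUNTS[rng.choice(3, p=_BIOPSY_WEIGHTS)])
        hyper = None
        if rng.random() >= miss.get("hyperplasia", 0.0):
            hyper = "yes" if rng.random() < _HYPERPLASIA_WEIGHTS["yes"] else "no"
        records.append(
            SubjectRecord(
                subject_id=f"S{i:06d}",
                status=None,
                age=_draw_band_value(rng, _AGE_BANDS, _AGE_WEIGHTS),
                n_first_degree_relatives=fdr,
                age_menarche=menarche,
                age_first_birth=afb,
                n_biopsies=biopsies,
                hyperplasia=hyper,
            )
        )
    return records


def simulate_hazard_tables(seed: int = 0) -> HazardTable:
    """Plausible smooth age-increasing incidence and competing mortality.

    Incidence sits in the 1e-3 to 1e-2 per-year range; small seeded
    jitter keeps distinct seeds distinct while preserving monotone shape.
    """
    rng = np.random.default_rng(seed)
    bands = tuple((a, a + 5) for a in range(35, 90, 5))
    mids = np.array([(a + b) / 2 for a, b in bands])
    incidence = 1.4e-3 * np.exp(0.022 * (mids - 35)) * np.exp(rng.normal(0, 0.04, len(bands)))
    competing = 2.5e-3 * np.exp(0.065 * (mids - 35)) * np.exp(rng.normal(0, 0.04, len(bands)))
    return HazardTable(
        age_bands=bands,
        incidence=tuple(float(h) for h in incidence),
        competing_mortality=tuple(float(h) for h in competing),
    )


def default_relative_risk_model() -> RelativeRiskModel:
    """Plausible log-RR coefficients for the synthetic clinical model."""
    return RelativeRiskModel(
        coefficients={
            "n_first_degree_relatives": {"0": 0.0, "1": 0.45, "2+": 0.90},
            "age_menarche": {">=14": 0.0, "12-13": 0.10, "<12": 0.21},
            "age_first_birth": {"<20": 0.0, "20-24": 0.12, "25-29": 0.25, ">=30": 0.40, NULLIPAROUS: 0.25},
            "n_biopsies": {"0": 0.0, "1": 0.35, ">=2": 0.60},
            "hyperplasia": {"no": -0.30, "yes": 0.45},
        }
    )


@dataclass
class GroundTruth:
    """True generative parameters recorded for recovery tests."""

    seed: int
    alpha: float
    genetic_effect: float
    clinical_effect: float
    log_ors: list[float]
    risk_allele_freqs: list[float]

    def to_json(self, path: Union[str, Path]) -> None:
        with open(path, "w") as fh:
            json.dump(dataclasses.asdict(self), fh, indent=2)


def assign_status(
    subjects: Sequence[SubjectRecord],
    genotypes: GenotypeMatrix,
    panel: Sequence[SnpPanelEntry],
    risks: Sequence[AbsoluteRiskPair],
    config: SimulationConfig,
    rng: Optional[np.random.Generator] = None,
) -> tuple[CohortDataset, GroundTruth]:
    """Label a subject pool and sample a case-control cohort from it.

    Case probability follows ``logit P = alpha + clinical_effect *
    log(bcrat_5yr) + genetic_effect * log(snp_score)`` with ``alpha``
    solved so the pool yields enough cases; exactly ``n_cases`` cases are
    then drawn, and controls are drawn age-matched (5-year bands) to the
    case age distribution when ``age_matching`` is on.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    n_pool = len(subjects)
    prs_results = prs.compute_prs(genotypes, panel)
    log_snp = np.log([r.snp_score for r in prs_results])
    log_b5 = np.log([p.five_year for p in risks])
    eta = config.clinical_effect * log_b5 + config.genetic_effect * log_snp
    if config.family_history_oversampling:
        has_fh = np.array([s.n_first_degree_relatives in ("1", "2+") for s in subjects])
        eta = eta + config.family_history_log_enrichment * has_fh

    target_cases = min(2.0 * config.n_cases, 0.5 * n_pool)
    if target_cases < config.n_cases:
        raise ValueError("subject pool too small for requested case count")

    def expected_cases(alpha: float) -> float:
        return float(expit(alpha + eta).sum()) - target_cases

    alpha = brentq(expected_cases, -50, 50)
    is_case = rng.random(n_pool) < expit(alpha + eta)
    case_idx = np.flatnonzero(is_case)
    ctrl_idx = np.flatnonzero(~is_case)
    if len(case_idx) < config.n_cases or len(ctrl_idx) < config.n_controls:
        raise ValueError(
            f"infeasible cohort: pool produced {len(case_idx)} cases / {len(ctrl_idx)} controls, "
            f"need {config.n_cases}/{config.n_controls}"
        )

    chosen_cases = rng.choice(case_idx, size=config.n_cases, replace=False)
    ages = np.array([s.age for s in subjects])
    if config.age_matching:
        chosen_ctrls = _age_matched_controls(rng, ages, chosen_cases, ctrl_idx, config.n_controls)
    else:
        chosen_ctrls = rng.choice(ctrl_idx, size=config.n_controls, replace=False)

    chosen = np.concatenate([chosen_cases, chosen_ctrls])
    new_subjects = []
    for i in chosen:
        s = subjects[i]
        new_subjects.append(dataclasses.replace(s, status="case" if is_case[i] else "control"))
    new_genotypes = GenotypeMatrix(
        subject_ids=[subjects[i].subject_id for i in chosen],
        rsids=list(genotypes.rsids),
        dosages=genotypes.dosages[chosen],
    )
    truth = GroundTruth(
        seed=config.seed,
        alpha=float(alpha),
        genetic_effect=config.genetic_effect,
        clinical_effect=config.clinical_effect,
        log_ors=[math.log(e.per_allele_or) for e in panel],
        risk_allele_freqs=[e.risk_allele_freq for e in panel],
    )
    return CohortDataset(subjects=new_subjects, genotypes=new_genotypes, panel=list(panel)), truth


def _age_matched_controls(
    rng: np.random.Generator,
    ages: np.ndarray,
    case_idx: np.ndarray,
    ctrl_idx: np.ndarray,
    n_controls: int,
) -> np.ndarray:
    """Sample controls so their 5-year age-band mix tracks the cases'."""
    band = (ages // 5).astype(int)
    case_bands, case_counts = np.unique(band[case_idx], return_counts=True)
    quota = {b: int(round(c / len(case_idx) * n_controls)) for b, c in zip(case_bands, case_counts)}
    chosen: list[int] = []
    remaining = set(ctrl_idx.tolist())
    for b, want in sorted(quota.items()):
        pool = [i for i in remaining if band[i] == b]
        take = rng.choice(pool, size=min(want, len(pool)), replace=False) if pool else np.array([], dtype=int)
        chosen.extend(int(i) for i in take)
        remaining.difference_update(int(i) for i in take)
    # fill any rounding/scarcity deficit with nearest-band leftovers
    while len(chosen) < n_controls:
        pool = sorted(remaining)
        if not pool:
            raise ValueError("control pool exhausted during age matching")
        target_bands = np.array([band[i] for i in pool])
        want_band = band[case_idx[rng.integers(len(case_idx))]]
        pick = pool[int(np.argmin(np.abs(target_bands - want_band)))]
        chosen.append(pick)
        remaining.discard(pick)
    return np.array(chosen[:n_controls])


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CohortDataset, GroundTruth, RelativeRiskModel, HazardTable]:
    """End-to-end generation of one labelled case-control cohort."""
    rng = np.random.default_rng(config.seed)
    panel = simulate_panel(config, rng)
    n_pool = int(config.pool_factor * (config.n_cases + config.n_controls))
    pool_subjects = simulate_questionnaire(n_pool, config, rng)
    pool_genotypes = simulate_genotypes(
        panel, n_pool, rng, config.genotype_missing_rate, [s.subject_id for s in pool_subjects]
    )
    model = default_relative_risk_model()
    hazards = simulate_hazard_tables(config.seed)
    risks = gail.score_cohort(pool_subjects, model, hazards)
    cohort, truth = assign_status(pool_subjects, pool_genotypes, panel, risks, config, rng)
    return cohort, truth, model, hazards


__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_panel",
    "simulate_genotypes",
    "simulate_questionnaire",
    "simulate_hazard_tables",
    "default_relative_risk_model",
    "assign_status",
    "simulate_cohort",
]
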