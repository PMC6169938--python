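"""Core record types and CSV ingestion for the three tabular inputs.

All inputs are RFC-4180 CSV with a header row:

- SNP panel: ``rsid,risk_allele,or,freq``
- genotype matrix: ``subject_id`` followed by one dosage column per rsid
- questionnaire: ``subject_id,status,age,n_first_degree_relatives,
  age_menarche,age_first_birth,n_biopsies,hyperplasia``

Missing values may be written as the empty string, ``NA`` or ``NaN``
(case-insensitive). Genotypes are risk-allele dosages in {0, 1, 2};
conversion from raw base calls and strand disambiguation are the data
producer's responsibility.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel category for a parous age-at-first-birth that never happened.
NULLIPAROUS = "nulliparous"

_MISSING_TOKENS = {"", "na", "nan"}

VALID_STATUSES = ("case", "control")
FAMILY_HISTORY_CATEGORIES = ("0", "1", "2+")


def _is_missing_token(value: object) -> bool:
    if value is None:
        return True
    if isinstance(value, float) and math.isnan(value):
        return True
    return str(value).strip().lower() in _MISSING_TOKENS


class DataError(ValueError):
    """Raised for malformed or inconsistent tabular input."""


@dataclass(frozen=True)
class SnpPanelEntry:
    """One panel SNP: risk allele, per-allele OR, risk-allele frequency.

    ``mu`` is the unscaled population-average risk
    ``(1 - p)^2 + 2 p (1 - p) OR + p^2 OR^2`` under Hardy–Weinberg
    proportions, computed on construction.
    """

    rsid: str
    risk_allele: str
    per_allele_or: float
    risk_allele_freq: float
    mu: float = field(init=False)

    def __post_init__(self) -> None:
        if self.per_allele_or <= 0:
            raise DataError(f"{self.rsid}: per-allele OR must be > 0, got {self.per_allele_or}")
        if not 0.0 <= self.risk_allele_freq <= 1.0:
            raise DataError(f"{self.rsid}: risk allele frequency must be in [0,1], got {self.risk_allele_freq}")
        if len(self.risk_allele) != 1 or self.risk_allele.upper() not in "ACGTURYSWKMBDHVN":
            raise DataError(f"{self.rsid}: risk allele must be a single IUPAC base, got {self.risk_allele!r}")
        p, or_ = self.risk_allele_freq, self.per_allele_or
        object.__setattr__(self, "mu", (1 - p) ** 2 + 2 * p * (1 - p) * or_ + p**2 * or_**2)


@dataclass
class GenotypeMatrix:
    """Subjects × SNPs risk-allele dosages; ``nan`` marks missing."""

    subject_ids: list[str]
    rsids: list[str]
    dosages: np.ndarray  # float array, shape (n_subjects, n_snps)

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=float)
        if self.dosages.shape != (len(self.subject_ids), len(self.rsids)):
            raise DataError(
                f"dosage shape {self.dosages.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.rsids)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise DataError("duplicate subject_ids in genotype matrix")
        if len(set(self.rsids)) != len(self.rsids):
            raise DataError("duplicate rsids in genotype matrix")
        observed = self.dosages[~np.isnan(self.dosages)]
        if not np.isin(observed, (0.0, 1.0, 2.0)).all():
            bad = observed[~np.isin(observed, (0.0, 1.0, 2.0))]
            raise DataError(f"dosages outside {{0,1,2}}: {sorted(set(bad.tolist()))}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.rsids)


@dataclass
class SubjectRecord:
    """Questionnaire record for one subject.

    ``None`` encodes MISSING/UNKNOWN throughout.  ``age_first_birth`` may
    additionally hold the :data:`NULLIPAROUS` sentinel.  ``status`` is
    ``None`` only for simulated subjects awaiting case/control assignment.
    """

    subject_id: str
    status: Optional[str]
    age: int
    n_first_degree_relatives: Optional[str] = None  # "0", "1", "2+"
    age_menarche: Optional[int] = None
    age_first_birth: Union[int, str, None] = None
    n_biopsies: Optional[int] = None
    hyperplasia: Optional[str] = None  # "yes" / "no"

    def __post_init__(self) -> None:
        if self.status is not None and self.status not in VALID_STATUSES:
            raise DataError(f"{self.subject_id}: unknown status {self.status!r}")
        if self.n_first_degree_relatives is not None and self.n_first_degree_relatives not in FAMILY_HISTORY_CATEGORIES:
            raise DataError(
                f"{self.subject_id}: n_first_degree_relatives must be one of "
                f"{FAMILY_HISTORY_CATEGORIES}, got {self.n_first_degree_relatives!r}"
            )
        if isinstance(self.age_first_birth, str) and self.age_first_birth != NULLIPAROUS:
            raise DataError(f"{self.subject_id}: invalid age_first_birth {self.age_first_birth!r}")
        if self.n_biopsies is not None and self.n_biopsies < 0:
            raise DataError(f"{self.subject_id}: n_biopsies must be >= 0")
        if self.hyperplasia is not None and self.hyperplasia not in ("yes", "no"):
            raise DataError(f"{self.subject_id}: hyperplasia must be yes/no, got {self.hyperplasia!r}")

    @property
    def is_case(self) -> bool:
        return self.status == "case"


@dataclass
class CohortDataset:
    """A consistent bundle of questionnaire, genotypes and panel."""

    subjects: list[SubjectRecord]
    genotypes: GenotypeMatrix
    panel: list[SnpPanelEntry]

    def __post_init__(self) -> None:
        q_ids = {s.subject_id for s in self.subjects}
        missing = [i for i in self.genotypes.subject_ids if i not in q_ids]
        if missing:
            raise DataError(f"genotype subjects absent from questionnaire: {missing[:5]}")
        if set(self.genotypes.rsids) != {e.rsid for e in self.panel}:
            raise DataError("genotype rsids do not match panel rsids")


# ---------------------------------------------------------------------------
# readers


def read_snp_panel(path: Union[str, Path]) -> list[SnpPanelEntry]:
    """Read a SNP panel CSV (columns ``rsid,risk_allele,or,freq``)."""
    df = pd.read_csv(path, dtype={"rsid": str, "risk_allele": str}, keep_default_na=False)
    required = {"rsid", "risk_allele", "or", "freq"}
    if not required.issubset(df.columns):
        raise DataError(f"panel file missing columns: {sorted(required - set(df.columns))}")
    entries: list[SnpPanelEntry] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        rsid = row["rsid"]
        if rsid in seen:
            raise DataError(f"duplicate rsid {rsid!r} at row {i}")
        seen.add(rsid)
        try:
            entries.append(
                SnpPanelEntry(
                    rsid=rsid,
                    risk_allele=row["risk_allele"],
                    per_allele_or=float(row["or"]),
                    risk_allele_freq=float(row["freq"]),
                )
            )
        except (DataError, ValueError) as exc:
            raise DataError(f"panel row {i} ({rsid!r}): {exc}") from exc
    logger.info("read %d panel SNPs from %s", len(entries), path)
    return entries


def read_genotype_matrix(path: Union[str, Path], panel: Sequence[SnpPanelEntry]) -> GenotypeMatrix:
    """Read a dosage CSV and align its columns to the panel order.

    Columns for rsids not in the panel are dropped with a warning; a panel
    rsid absent from the file is an error.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    if "subject_id" not in df.columns:
        raise DataError("genotype file has no subject_id column")
    panel_rsids = [e.rsid for e in panel]
    file_rsids = [c for c in df.columns if c != "subject_id"]
    extra = [r for r in file_rsids if r not in set(panel_rsids)]
    if extra:
        logger.warning("dropping %d genotype columns absent from panel: %s", len(extra), extra[:5])
    absent = [r for r in panel_rsids if r not in set(file_rsids)]
    if absent:
        raise DataError(f"panel rsids missing from genotype file: {absent[:5]}")

    subject_ids = df["subject_id"].tolist()
    dosages = np.full((len(subject_ids), len(panel_rsids)), np.nan)
    for j, rsid in enumerate(panel_rsids):
        for i, raw in enumerate(df[rsid]):
            if _is_missing_token(raw):
                continue
            try:
                value = float(raw)
            except ValueError:
                raise DataError(f"subject {subject_ids[i]!r}, SNP {rsid!r}: non-numeric dosage {raw!r}") from None
            if value not in (0.0, 1.0, 2.0):
                raise DataError(f"subject {subject_ids[i]!r}, SNP {rsid!r}: dosage {value} outside {{0,1,2}}")
            dosages[i, j] = value
    logger.info("read genotypes for %d subjects x %d SNPs from %s", len(subject_ids), len(panel_rsids), path)
    return GenotypeMatrix(subject_ids=subject_ids, rsids=list(panel_rsids), dosages=dosages)


def _parse_optional_int(value: object, *, context: str) -> Optional[int]:
    if _is_missing_token(value):
        return None
    try:
        return int(float(value))  # tolerate "12.0"
    except ValueError:
        raise DataError(f"{context}: non-numeric value {value!r}") from None


def read_questionnaire(path: Union[str, Path], *, min_age: int = 35) -> list[SubjectRecord]:
    """Read questionnaire records; subjects under ``min_age`` are dropped.

    The number of age-based exclusions is logged.
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {
        "subject_id", "status", "age", "n_first_degree_relatives",
        "age_menarche", "age_first_birth", "n_biopsies", "hyperplasia",
    }
    if not required.issubset(df.columns):
        raise DataError(f"questionnaire missing columns: {sorted(required - set(df.columns))}")
    records: list[SubjectRecord] = []
    n_excluded = 0
    for i, row in df.iterrows():
        sid = row["subject_id"]
        status = row["status"].strip().lower()
        if status not in VALID_STATUSES:
            raise DataError(f"row {i} ({sid!r}): unknown status code {row['status']!r}")
        age = _parse_optional_int(row["age"], context=f"row {i} ({sid!r}) age")
        if age is None:
            raise DataError(f"row {i} ({sid!r}): age is required")
        if age < min_age:
            n_excluded += 1
            continue
        fdr_raw = row["n_first_degree_relatives"]
        if _is_missing_token(fdr_raw):
            fdr: Optional[str] = None
        else:
            fdr = fdr_raw.strip()
            if fdr not in FAMILY_HISTORY_CATEGORIES:
                # numeric counts collapse into the Table-1 categories
                n = _parse_optional_int(fdr, context=f"row {i} ({sid!r}) n_first_degree_relatives")
                fdr = "2+" if n >= 2 else str(n)
        afb_raw = row["age_first_birth"]
        if _is_missing_token(afb_raw):
            afb: Union[int, str, None] = None
        elif afb_raw.strip().lower() == NULLIPAROUS:
            afb = NULLIPAROUS
        else:
            afb = _parse_optional_int(afb_raw, context=f"row {i} ({sid!r}) age_first_birth")
        hyp_raw = row["hyperplasia"]
        hyp = None if _is_missing_token(hyp_raw) else hyp_raw.strip().lower()
        records.append(
            SubjectRecord(
                subject_id=sid,
                status=status,
                age=age,
                n_first_degree_relatives=fdr,
                age_menarche=_parse_optional_int(row["age_menarche"], context=f"row {i} ({sid!r}) age_menarche"),
                age_first_birth=afb,
                n_biopsies=_parse_optional_int(row["n_biopsies"], context=f"row {i} ({sid!r}) n_biopsies"),
                hyperplasia=hyp,
            )
        )
    if n_excluded:
        logger.info("excluded %d subjects under age %d", n_excluded, min_age)
    if not records:
        logger.warning("questionnaire %s produced no records", path)
    return records


# ---------------------------------------------------------------------------
# writers (round-trip counterparts of the readers)


def write_snp_panel(panel: Sequence[SnpPanelEntry], path: Union[str, Path]) -> None:
    pd.DataFrame(
        {
            "rsid": [e.rsid for e in panel],
            "risk_allele": [e.risk_allele for e in panel],
            "or": [e.per_allele_or for e in panel],
            "freq": [e.risk_allele_freq for e in panel],
        }
    ).to_csv(path, index=False)


def write_genotype_matrix(matrix: GenotypeMatrix, path: Union[str, Path]) -> None:
    df = pd.DataFrame(matrix.dosages, columns=matrix.rsids)
    df = df.map(lambda v: "" if np.isnan(v) else str(int(v)))
    df.insert(0, "subject_id", matrix.subject_ids)
    df.to_csv(path, index=False)


def write_questionnaire(subjects: Sequence[SubjectRecord], path: Union[str, Path]) -> None:
    def fmt(v: object) -> str:
        return "" if v is None else str(v)

    pd.DataFrame(
        {
            "subject_id": [s.subject_id for s in subjects],
            "status": [fmt(s.status) for s in subjects],
            "age": [s.age for s in subjects],
            "n_first_degree_relatives": [fmt(s.n_first_degree_relatives) for s in subjects],
            "age_menarche": [fmt(s.age_menarche) for s in subjects],
            "age_first_birth": [fmt(s.age_first_birth) for s in subjects],
            "n_biopsies": [fmt(s.n_biopsies) for s in subjects],
            "hyperplasia": [fmt(s.hyperplasia) for s in subjects],
        }
    ).to_csv(path, index=False)


__all__ = [
    "NULLIPAROUS",
    "DataError",
    "SnpPanelEntry",
    "GenotypeMatrix",
    "SubjectRecord",
    "CohortDataset",
    "read_snp_panel",
    "read_genotype_matrix",
    "read_questionnaire",
    "write_snp_panel",
    "write_genotype_matrix",
    "write_questionnaire",
]
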