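"""Guideline-threshold categorization, reclassification tables and NRI.

Risks at or above the threshold are "high" (the boundary is high).
Default thresholds: 1.66% for 5-year risk, 20% for lifetime risk.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

Z95 = 1.96

THRESHOLD_5YR = 0.0166
THRESHOLD_LIFETIME = 0.20

LOW, HIGH = "low", "high"


def classify(risk: float, threshold: float) -> str:
    """"high" iff risk >= threshold."""
    if not 0.0 <= risk <= 1.0:
        raise ValueError(f"risk must be in [0,1], got {risk}")
    return HIGH if risk >= threshold else LOW


@dataclass(frozen=True)
class ReclassificationTable:
    """Paired 2x2 (old class -> new class) counts for cases and controls.

    Count arrays are indexed ``[old][new]`` with 0 = low, 1 = high.
    """

    threshold: float
    case_counts: np.ndarray
    control_counts: np.ndarray

    def __post_init__(self) -> None:
        for name in ("case_counts", "control_counts"):
            arr = np.asarray(getattr(self, name), dtype=int)
            if arr.shape != (2, 2) or (arr < 0).any():
                raise ValueError(f"{name} must be a non-negative 2x2 array")
            object.__setattr__(self, name, arr)

    @property
    def n_cases(self) -> int:
        return int(self.case_counts.sum())

    @property
    def n_controls(self) -> int:
        return int(self.control_counts.sum())


def cross_tabulate(clinical, combined, status, threshold: float) -> ReclassificationTable:
    """Cross-tabulate old (clinical) vs new (combined) risk classes by status."""
    clinical = np.asarray(clinical, dtype=float)
    combined = np.asarray(combined, dtype=float)
    status = np.asarray(status)
    if len(clinical) != len(combined) or len(clinical) != len(status):
        raise ValueError("clinical, combined and status must cover the same subjects")
    old_high = (clinical >= threshold).astype(int)
    new_high = (combined >= threshold).astype(int)
    is_case = status == "case" if status.dtype.kind in "OUS" else status.astype(bool)
    counts = {True: np.zeros((2, 2), dtype=int), False: np.zeros((2, 2), dtype=int)}
    for o, n, c in zip(old_high, new_high, is_case):
        counts[bool(c)][o, n] += 1
    return ReclassificationTable(threshold=threshold, case_counts=counts[True], control_counts=counts[False])


@dataclass(frozen=True)
class NriResult:
    nri: float
    ci_low: float
    ci_high: float
    p_up_case: float
    p_down_case: float
    p_up_control: float
    p_down_control: float


def nri(
    table: ReclassificationTable,
    *,
    bootstrap: bool = False,
    n_boot: int = 2000,
    seed: int = 0,
) -> NriResult:
    """Two-category net reclassification improvement.

    ``NRI = P(up|case) - P(down|case) + P(down|control) - P(up|control)``.
    The default CI uses the asymptotic normal variance

        var = [(pu_c + pd_c) - (pu_c - pd_c)^2]/n_cases
            + [(pu_k + pd_k) - (pd_k - pu_k)^2]/n_controls;

    ``bootstrap=True`` replaces it with a seeded multinomial percentile
    bootstrap over the table cells.
    """
    m, n = table.n_cases, table.n_controls
    if m == 0 or n == 0:
        raise ValueError("need at least one case and one control")
    pu_c = table.case_counts[0, 1] / m
    pd_c = table.case_counts[1, 0] / m
    pu_k = table.control_counts[0, 1] / n
    pd_k = table.control_counts[1, 0] / n
    value = pu_c - pd_c + pd_k - pu_k
    if bootstrap:
        rng = np.random.default_rng(seed)
        case_p = table.case_counts.ravel() / m
        ctrl_p = table.control_counts.ravel() / n
        cases = rng.multinomial(m, case_p, size=n_boot) / m
        ctrls = rng.multinomial(n, ctrl_p, size=n_boot) / n
        reps = cases[:, 1] - cases[:, 2] + ctrls[:, 2] - ctrls[:, 1]
        lo, hi = np.quantile(reps, [0.025, 0.975])
    else:
        var = ((pu_c + pd_c) - (pu_c - pd_c) ** 2) / m + ((pu_k + pd_k) - (pd_k - pu_k) ** 2) / n
        half = Z95 * np.sqrt(var)
        lo, hi = value - half, value + half
    return NriResult(
        nri=float(value),
        ci_low=float(lo),
        ci_high=float(hi),
        p_up_case=float(pu_c),
        p_down_case=float(pd_c),
        p_up_control=float(pu_k),
        p_down_control=float(pd_k),
    )


def reclassified_fractions(table: ReclassificationTable) -> dict[str, float]:
    """Up/down move fractions among all and among previously-low/high subjects.

    Fractions with an empty denominator are reported as NaN.
    """
    def frac(num: int, den: int) -> float:
        return num / den if den > 0 else float("nan")

    cc, kk = table.case_counts, table.control_counts
    return {
        "cases_up_of_all": frac(cc[0, 1], table.n_cases),
        "cases_up_of_low": frac(cc[0, 1], cc[0].sum()),
        "cases_down_of_all": frac(cc[1, 0], table.n_cases),
        "cases_down_of_high": frac(cc[1, 0], cc[1].sum()),
        "controls_up_of_all": frac(kk[0, 1], table.n_controls),
        "controls_up_of_low": frac(kk[0, 1], kk[0].sum()),
        "controls_down_of_all": frac(kk[1, 0], table.n_controls),
        "controls_down_of_high": frac(kk[1, 0], kk[1].sum()),
    }


def table_from_counts(
    case_counts, control_counts, threshold: float = THRESHOLD_5YR
) -> ReclassificationTable:
    """Build a table directly from eight printed counts.

    ``case_counts``/``control_counts`` are (low->low, low->high, high->low,
    high->high) quadruples.
    """
    return ReclassificationTable(
        threshold=threshold,
        case_counts=np.asarray(case_counts, dtype=int).reshape(2, 2),
        control_counts=np.asarray(control_counts, dtype=int).reshape(2, 2),
    )


__all__ = [
    "THRESHOLD_5YR",
    "THRESHOLD_LIFETIME",
    "LOW",
    "HIGH",
    "classify",
    "ReclassificationTable",
    "cross_tabulate",
    "NriResult",
    "nri",
    "reclassified_fractions",
    "table_from_counts",
]
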