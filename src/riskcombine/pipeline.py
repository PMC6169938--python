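"""End-to-end orchestration: score -> combine -> evaluate -> reclassify.

All artifacts (per-subject scores, evaluation table, reclassification
tables, machine-readable summary, config echo and log) are written under
one output directory; a run is fully determined by its inputs and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
import numpy as np
import pandas as pd

from . import combine as combine_mod
from . import evaluation, gail, prs, reclassify
from .io import read_genotype_matrix, read_questionnaire, read_snp_panel

logger = logging.getLogger(__name__)

SCORE_COLUMNS = {
    "bcrat_5yr": "log_bcrat_5yr",
    "bcrat_lifetime": "log_bcrat_lifetime",
    "snp": "log_snp",
    "combined_5yr": "log_combined_5yr",
    "combined_lifetime": "log_combined_lifetime",
}


@dataclass(frozen=True)
class RunConfig:
    panel: Path
    genotypes: Path
    questionnaire: Path
    hazards: Path
    out_dir: Path
    seed: int = 0
    threshold_5yr: float = reclassify.THRESHOLD_5YR
    threshold_lifetime: float = reclassify.THRESHOLD_LIFETIME
    bootstrap_ci: bool = False
    opera_variant: str = "covariate"

    def __post_init__(self) -> None:
        for name in ("threshold_5yr", "threshold_lifetime"):
            value = getattr(self, name)
            if not 0.0 < value < 1.0:
                raise ValueError(f"{name} must be in (0,1), got {value}")

    def digest(self) -> str:
        payload = {k: str(v) for k, v in dataclasses.asdict(self).items()}
        return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:12]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write all artifacts.

    Returns the machine-readable summary (also written as summary.json).
    On any module failure partial outputs are removed before re-raising.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_path = out / "run.log"
    handler = logging.FileHandler(log_path, mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s"))
    root = logging.getLogger("riskcombine")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    written: list[Path] = []
    try:
        logger.info("run config digest=%s seed=%d", config.digest(), config.seed)
        panel = read_snp_panel(config.panel)
        genotypes = read_genotype_matrix(config.genotypes, panel)
        subjects = read_questionnaire(config.questionnaire)
        model, hazards = gail.load_risk_config(config.hazards)
        logger.info("loaded %d SNPs, %d genotyped subjects, %d questionnaire records",
                    len(panel), genotypes.n_subjects, len(subjects))

        genotyped = set(genotypes.subject_ids)
        subjects = [s for s in subjects if s.subject_id in genotyped]
        prs_results = prs.compute_prs(genotypes, panel)
        risks = gail.score_cohort(subjects, model, hazards)
        score_sets = combine_mod.build_score_sets(prs_results, risks)
        combine_mod.log_transform_scores(score_sets)
        frame = combine_mod.scores_to_frame(score_sets, subjects)
        logger.info("scored %d subjects", len(frame))

        scores_path = out / "scores.csv"
        frame.to_csv(scores_path, index=False)
        written.append(scores_path)

        status = frame["status"].to_numpy()
        age = frame["age"].to_numpy(dtype=float)
        eval_rows = []
        for name in SCORE_COLUMNS:
            raw = frame[name if name != "snp" else "snp_score"].to_numpy(dtype=float)
            op = evaluation.opera(np.log(raw), status, age, score_name=name, variant=config.opera_variant)
            au = evaluation.auc(raw, status, score_name=name)
            eval_rows.append(
                {
                    "score": name,
                    "opera_or": op.opera_or,
                    "opera_ci_low": op.ci_low,
                    "opera_ci_high": op.ci_high,
                    "opera_p": op.p_value,
                    "opera_s": op.s,
                    "auc": au.auc,
                    "auc_ci_low": au.ci_low,
                    "auc_ci_high": au.ci_high,
                }
            )
        eval_df = pd.DataFrame(eval_rows)
        eval_path = out / "evaluation.csv"
        eval_df.to_csv(eval_path, index=False)
        written.append(eval_path)

        chi2_5, p_5 = evaluation.auc_compare(
            frame["combined_5yr"], frame["bcrat_5yr"], status
        )
        chi2_lt, p_lt = evaluation.auc_compare(
            frame["combined_lifetime"], frame["bcrat_lifetime"], status
        )

        summary: dict = {
            "seed": config.seed,
            "config_digest": config.digest(),
            "n_subjects": int(len(frame)),
            "n_cases": int((status == "case").sum()),
            "n_controls": int((status == "control").sum()),
            "evaluation": eval_rows,
            "auc_change": {
                "5yr": {"chi2": chi2_5, "p": p_5},
                "lifetime": {"chi2": chi2_lt, "p": p_lt},
            },
            "reclassification": {},
        }

        for label, clinical_col, combined_col, threshold in (
            ("5yr", "bcrat_5yr", "combined_5yr", config.threshold_5yr),
            ("lifetime", "bcrat_lifetime", "combined_lifetime", config.threshold_lifetime),
        ):
            table = reclassify.cross_tabulate(
                frame[clinical_col], frame[combined_col], status, threshold
            )
            result = reclassify.nri(table, bootstrap=config.bootstrap_ci, seed=config.seed)
            fractions = reclassify.reclassified_fractions(table)
            tab_df = pd.DataFrame(
                {
                    "stratum": ["case"] * 4 + ["control"] * 4,
                    "old_class": ["low", "low", "high", "high"] * 2,
                    "new_class": ["low", "high", "low", "high"] * 2,
                    "count": list(table.case_counts.ravel()) + list(table.control_counts.ravel()),
                }
            )
            tab_path = out / f"reclassification_{label}.csv"
            tab_df.to_csv(tab_path, index=False)
            written.append(tab_path)
            summary["reclassification"][label] = {
                "threshold": threshold,
                "nri": result.nri,
                "nri_ci_low": result.ci_low,
                "nri_ci_high": result.ci_high,
                "fractions": fractions,
            }
            logger.info("%s NRI = %.4f (%.4f, %.4f)", label, result.nri, result.ci_low, result.ci_high)

        summary_path = out / "summary.json"
        with open(summary_path, "w") as fh:
            json.dump(summary, fh, indent=2)
        written.append(summary_path)
        config_path = out / "config.json"
        with open(config_path, "w") as fh:
            json.dump({k: str(v) for k, v in dataclasses.asdict(config).items()}, fh, indent=2)
        written.append(config_path)
        return summary
    except Exception:
        for path in written:
            path.unlink(missing_ok=True)
        raise
    finally:
        root.removeHandler(handler)
        handler.close()


__all__ = ["RunConfig", "run_pipeline", "SCORE_COLUMNS"]
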