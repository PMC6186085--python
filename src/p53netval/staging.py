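"""Tumor-stage comparison of per-gene score distributions.

Per gene, a one-way ANOVA compares pathway-activity scores across tumor
stages (1-4); stage-discriminating genes (p < 0.05) get a direction by
comparing the stage-4 vs stage-3 median score: positive means the median
rises in stage 4, negative means it falls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .survival import PatientRecord

logger = logging.getLogger(__name__)

__all__ = ["StageResult", "compare_stages", "stage_table"]

STAGES = (1, 2, 3, 4)
MIN_PATIENTS_PER_STAGE = 2


@dataclass(frozen=True)
class StageResult:
    gene: str
    median_by_stage: dict[int, float]
    anova_p: float
    direction: str  # "positive" | "negative" | "none"


def _anova_p(groups: list[np.ndarray]) -> float:
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:
        return 1.0  # identical scores everywhere: no evidence of difference
    if all(np.ptp(g) == 0 for g in groups):
        return 0.0  # zero within-group variance but differing means
    return float(stats.f_oneway(*groups).pvalue)


def compare_stages(
    scores: pd.DataFrame,
    records: Sequence[PatientRecord],
    genes: Iterable[str] | None = None,
) -> list[StageResult]:
    """One-way ANOVA of per-gene scores across stage groups.

    *scores* is patients x genes (index = patient id).  Stages with fewer
    than 2 patients are excluded from the test (logged); genes with fewer
    than 2 eligible stage groups are skipped.  The direction compares the
    stage-4 and stage-3 medians ("none" when either stage is absent or the
    medians tie); significance (anova_p < 0.05) is the caller's filter.
    """
    staged = [r for r in records if r.stage is not None and r.id in scores.index]
    by_stage: dict[int, list[str]] = {s: [] for s in STAGES}
    for r in staged:
        by_stage[r.stage].append(r.id)
    eligible = {s: ids for s, ids in by_stage.items() if len(ids) >= MIN_PATIENTS_PER_STAGE}
    dropped = sorted(set(by_stage) - set(eligible))
    if dropped:
        logger.info("compare_stages: stages %s excluded (<%d patients)",
                    dropped, MIN_PATIENTS_PER_STAGE)
    genes = list(genes) if genes is not None else list(scores.columns)
    results: list[StageResult] = []
    if len(eligible) < 2:
        logger.warning("compare_stages: fewer than 2 eligible stage groups; nothing to test")
        return results
    for g in genes:
        groups = [scores.loc[ids, g].to_numpy(float) for ids in eligible.values()]
        p = _anova_p(groups)
        medians = {s: float(np.median(scores.loc[ids, g])) for s, ids in eligible.items()}
        direction = "none"
        if 3 in medians and 4 in medians and medians[4] != medians[3]:
            direction = "positive" if medians[4] > medians[3] else "negative"
        results.append(StageResult(gene=g, median_by_stage=medians, anova_p=p,
                                   direction=direction))
    return results


def stage_table(results: Iterable[StageResult]) -> pd.DataFrame:
    """Flatten stage results into a TSV-ready table."""
    rows = []
    for r in results:
        row = {"gene": r.gene}
        for s in STAGES:
            row[f"median_s{s}"] = r.median_by_stage.get(s, np.nan)
        row["anova_p"] = r.anova_p
        row["direction"] = r.direction
        rows.append(row)
    cols = ["gene", *[f"median_s{s}" for s in STAGES], "anova_p", "direction"]
    return pd.DataFrame(rows, columns=cols)
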