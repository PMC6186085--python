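"""Patient stratification, score-survival correlation, univariate Cox.

Patients are partitioned by TP53 status (wt/mut) x chemotherapy (yes/no).
Per gene, the pathway-activity score is related to survival two ways:

* Pearson correlation between score and survival time (ignores
  censoring, as a ranking heuristic);
* univariate Cox proportional-hazards regression (honors censoring),
  fitted by Newton-Raphson on the Breslow partial likelihood, reporting
  beta, the hazard ratio exp(beta) with a 95% Wald confidence interval,
  and the Wald p-value.  HR > 1 marks a bad prognostic factor
  (higher score, higher hazard), HR < 1 a good one.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "PatientRecord",
    "GeneSurvivalCorrelation",
    "CoxResult",
    "read_patients_tsv",
    "write_patients_tsv",
    "records_to_frame",
    "stratify_patients",
    "correlate_scores_with_survival",
    "univariate_cox",
    "cox_table",
    "interpret_hr",
    "GROUP_LABELS",
]

#: The four stratification groups, (p53_status, chemo).
GROUP_LABELS: tuple[tuple[str, bool], ...] = (
    ("wt", True),
    ("wt", False),
    ("mut", True),
    ("mut", False),
)


@dataclass(frozen=True)
class PatientRecord:
    id: str
    p53_status: str  # "wt" | "mut"
    chemo: bool
    survival_days: float
    event: bool
    stage: int | None = None

    def __post_init__(self) -> None:
        if self.p53_status not in ("wt", "mut"):
            raise ValueError(f"p53_status must be 'wt' or 'mut', got {self.p53_status!r}")
        if self.survival_days <= 0:
            raise ValueError("survival_days must be > 0")
        if self.stage is not None and self.stage not in (1, 2, 3, 4):
            raise ValueError(f"stage must be 1-4, got {self.stage}")


@dataclass(frozen=True)
class GeneSurvivalCorrelation:
    gene: str
    r: float


@dataclass(frozen=True)
class CoxResult:
    gene: str
    beta: float
    hr: float
    ci_low: float
    ci_high: float
    wald_p: float
    n: int = 0
    n_events: int = 0


# -- metadata I/O --------------------------------------------------------------

_BOOL = {"1": True, "0": False, "true": True, "false": False, "yes": True, "no": False}


def read_patients_tsv(path: str | Path) -> list[PatientRecord]:
    """Read patient metadata TSV: id, p53_status, chemo, survival_days, event, stage.

    A missing ``event`` column defaults to all-events (death observed for
    everyone) with a loud warning, since Pearson-vs-time analyses ignore
    censoring anyway but Cox must not silently assume it.
    """
    df = pd.read_csv(path, sep="\t", dtype={"id": str})
    if "event" not in df.columns:
        warnings.warn(
            "patient metadata has no 'event' column; assuming every survival "
            "time is an observed death (no censoring)",
            stacklevel=2,
        )
        df["event"] = 1
    records = []
    for row in df.itertuples(index=False):
        stage = getattr(row, "stage", None)
        stage = None if stage is None or pd.isna(stage) else int(stage)
        records.append(
            PatientRecord(
                id=str(row.id),
                p53_status=str(row.p53_status),
                chemo=_BOOL.get(str(row.chemo).lower(), bool(row.chemo)),
                survival_days=float(row.survival_days),
                event=_BOOL.get(str(row.event).lower(), bool(row.event)),
                stage=stage,
            )
        )
    return records


def records_to_frame(records: Iterable[PatientRecord]) -> pd.DataFrame:
    rows = [
        {
            "id": r.id,
            "p53_status": r.p53_status,
            "chemo": int(r.chemo),
            "survival_days": r.survival_days,
            "event": int(r.event),
            "stage": r.stage if r.stage is not None else np.nan,
        }
        for r in records
    ]
    return pd.DataFrame(rows).set_index("id")


def write_patients_tsv(records: Iterable[PatientRecord], path: str | Path) -> None:
    records_to_frame(records).to_csv(path, sep="\t", index_label="id")


# -- operations ----------------------------------------------------------------


def stratify_patients(
    records: Sequence[PatientRecord],
) -> dict[tuple[str, bool], list[PatientRecord]]:
    """Partition patients into the four (p53 status x chemotherapy) groups.

    Empty groups are allowed (a real cohort's mut+chemo group can have a
    single patient or none) but logged as warnings.
    """
    ids = [r.id for r in records]
    if len(ids) != len(set(ids)):
        dupes = sorted({i for i in ids if ids.count(i) > 1})
        raise ValueError(f"duplicate patient ids: {dupes[:5]}")
    groups: dict[tuple[str, bool], list[PatientRecord]] = {g: [] for g in GROUP_LABELS}
    for r in records:
        groups[(r.p53_status, r.chemo)].append(r)
    for g, members in groups.items():
        if not members:
            logger.warning("stratify_patients: empty group %s", g)
    return groups


def correlate_scores_with_survival(
    scores: pd.DataFrame,
    records: Sequence[PatientRecord],
    genes: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Pearson r between per-patient gene score and survival time, per gene.

    *scores* is patients x genes (index = patient id).  Genes with zero
    score variance (or zero survival variance) are skipped with a log
    entry.  The result is sorted ascending by r, so the most negatively
    survival-associated genes come first.
    """
    recs = [r for r in records if r.id in scores.index]
    if len(recs) < 3:
        raise ValueError("need at least 3 patients with scores for correlation")
    time = np.array([r.survival_days for r in recs])
    sub = scores.loc[[r.id for r in recs]]
    genes = list(genes) if genes is not None else list(sub.columns)
    rows = []
    if np.var(time) == 0:
        raise ValueError("survival times have zero variance")
    for g in genes:
        x = sub[g].to_numpy(float)
        if np.var(x) == 0:
            logger.info("correlate_scores_with_survival: %s skipped (zero variance)", g)
            continue
        r, _ = stats.pearsonr(x, time)
        rows.append({"gene": g, "r": float(r)})
    return pd.DataFrame(rows, columns=["gene", "r"]).sort_values("r").reset_index(drop=True)


def univariate_cox(
    x: Sequence[float],
    time: Sequence[float],
    event: Sequence[bool],
    gene: str = "",
    max_iter: int = 50,
    tol: float = 1e-10,
) -> CoxResult:
    """Single-covariate Cox proportional-hazards fit.

    Newton-Raphson maximization of the Breslow partial likelihood; the
    standard error comes from the observed information at the optimum,
    the 95% CI is ``exp(beta +/- 1.96 se)`` and the Wald p-value compares
    ``(beta/se)^2`` against chi-square(1).
    """
    x = np.asarray(x, dtype=float)
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    if not (len(x) == len(time) == len(event)):
        raise ValueError("x, time and event must have equal length")
    n_events = int(event.sum())
    if n_events < 2:
        raise ValueError("need at least 2 observed events for a Cox fit")
    if np.var(x) == 0:
        raise ValueError("constant covariate carries no information")

    # sort by time; Breslow ties: events at the same time share the risk set
    order = np.argsort(time, kind="stable")
    x_s, t_s, e_s = x[order], time[order], event[order]
    et_sorted = t_s[e_s]
    event_times, first_idx, m = np.unique(et_sorted, return_index=True, return_counts=True)
    x_event_sum = np.add.reduceat(x_s[e_s], first_idx)
    risk_idx = np.searchsorted(t_s, event_times, side="left")

    def _suffix(v: np.ndarray) -> np.ndarray:
        return np.cumsum(v[::-1])[::-1]

    def score_info(beta: float) -> tuple[float, float, float]:
        w = np.exp(beta * x_s)
        s0 = _suffix(w)[risk_idx]
        s1 = _suffix(w * x_s)[risk_idx]
        s2 = _suffix(w * x_s**2)[risk_idx]
        loglik = float((beta * x_event_sum - m * np.log(s0)).sum())
        u = float((x_event_sum - m * s1 / s0).sum())
        info = float((m * (s2 / s0 - (s1 / s0) ** 2)).sum())
        return loglik, u, info

    beta = 0.0
    for _ in range(max_iter):
        _, u, info = score_info(beta)
        if info <= 0:
            raise RuntimeError("singular information matrix in Cox fit")
        step = u / info
        beta += step
        if abs(beta) > 50:
            raise RuntimeError(
                f"Cox fit diverged (|beta| > 50){f' for {gene}' if gene else ''}: "
                "monotone likelihood / complete separation of the covariate"
            )
        if abs(step) < tol:
            break
    else:
        raise RuntimeError("Cox Newton-Raphson did not converge")

    _, _, info = score_info(beta)
    se = 1.0 / np.sqrt(info)
    hr = float(np.exp(beta))
    wald = (beta / se) ** 2
    return CoxResult(
        gene=gene,
        beta=float(beta),
        hr=hr,
        ci_low=float(np.exp(beta - 1.96 * se)),
        ci_high=float(np.exp(beta + 1.96 * se)),
        wald_p=float(stats.chi2.sf(wald, df=1)),
        n=len(x),
        n_events=n_events,
    )


def cox_table(
    scores: pd.DataFrame,
    records: Sequence[PatientRecord],
    genes: Iterable[str] | None = None,
    standardize: bool = False,
) -> pd.DataFrame:
    """Univariate Cox fit per gene over all supplied patients.

    Genes whose fit fails (constant score, separation) are skipped with a
    log entry.  ``standardize=True`` z-scores each gene's covariate across
    patients first, making betas comparable between genes.
    """
    recs = [r for r in records if r.id in scores.index]
    sub = scores.loc[[r.id for r in recs]]
    time = [r.survival_days for r in recs]
    event = [r.event for r in recs]
    genes = list(genes) if genes is not None else list(sub.columns)
    rows = []
    for g in genes:
        xg = sub[g].to_numpy(float)
        if standardize:
            sd = xg.std(ddof=0)
            if sd > 0:
                xg = (xg - xg.mean()) / sd
        try:
            res = univariate_cox(xg, time, event, gene=g)
        except (ValueError, RuntimeError) as exc:
            logger.info("cox_table: %s skipped (%s)", g, exc)
            continue
        rows.append(
            {
                "gene": g,
                "beta": res.beta,
                "hr": res.hr,
                "ci_low": res.ci_low,
                "ci_high": res.ci_high,
                "wald_p": res.wald_p,
            }
        )
    return pd.DataFrame(
        rows, columns=["gene", "beta", "hr", "ci_low", "ci_high", "wald_p"]
    )


def interpret_hr(result: CoxResult) -> str:
    """Prognostic reading of a hazard ratio."""
    if result.hr < 1:
        return "good prognostic factor"
    if result.hr > 1:
        return "bad prognostic factor"
    return "no effect"
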