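"""Model-vs-experiment comparison and validation summaries.

Per gene, the absolute difference |E_mod - E_exp| classifies a prediction
as correct (0), small error (1: the model predicts a change where none is
seen, or vice versa) or large error (2: the model predicts the opposite
direction).  A validation summary reports counts, percentages and a
significance: the exact binomial point probability of observing the given
number of correct predictions when each of the three outcomes is
equiprobable (success probability 1/3) — the reconstruction that matches
the published summary tables; an upper-tail variant is available.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .lssa import Scenario

__all__ = [
    "ComparisonSpec",
    "ValidationSummary",
    "classify_predictions",
    "binom_point_prob",
    "binom_significance",
    "summarize",
]


@dataclass(frozen=True)
class ComparisonSpec:
    """Labels one validation run: which data contrast vs which simulation."""

    source: str = ""
    target: str = ""
    simulation: tuple[Scenario, Scenario] | None = None

    def describe(self) -> str:
        sim = ""
        if self.simulation:
            sim = f" [{self.simulation[0]} vs {self.simulation[1]}]"
        return f"{self.source} -> {self.target}{sim}"


def classify_predictions(
    emod: Mapping[str, int], eexp: pd.DataFrame
) -> pd.Series:
    """Per-gene |E_mod - E_exp| in {0, 1, 2}.

    *eexp* is a DE table with an ``eexp`` column; its gene set must already
    be intersected with the model (see ``map_genes_to_model``) so every
    gene appears on both sides.
    """
    missing_model = [g for g in eexp.index if g not in emod]
    if missing_model:
        raise ValueError(f"genes absent from model prediction: {missing_model[:5]}")
    calls = eexp["eexp"]
    return pd.Series(
        {g: abs(int(emod[g]) - int(calls[g])) for g in eexp.index}, name="error_class"
    )


def binom_point_prob(n: int, k: int, p: float = 1.0 / 3.0) -> float:
    """Exact binomial point probability C(n,k) p^k (1-p)^(n-k), in log space."""
    if not (0 <= k <= n):
        raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
    if not (0 <= p <= 1):
        raise ValueError(f"need 0 <= p <= 1, got p={p}")
    return float(np.exp(stats.binom.logpmf(k, n, p)))


def binom_significance(
    n: int, k: int, p: float = 1.0 / 3.0,
    mode: Literal["point", "upper_tail"] = "point",
) -> float:
    """Significance of k correct out of n under the 1/3-null.

    ``point`` (default) is the exact point mass, which reproduces the
    published summary-table values; ``upper_tail`` is P(X >= k).
    """
    if mode == "point":
        return binom_point_prob(n, k, p)
    if mode == "upper_tail":
        if not (0 <= k <= n):
            raise ValueError(f"need 0 <= k <= n, got k={k}, n={n}")
        return float(stats.binom.sf(k - 1, n, p))
    raise ValueError(f"unknown mode {mode!r}")


@dataclass
class ValidationSummary:
    """Counts, percentages and significance of one validation run."""

    n_genes: int
    n_correct: int
    n_small: int
    n_large: int
    significance: float
    spec: ComparisonSpec = field(default_factory=ComparisonSpec)

    def __post_init__(self) -> None:
        if self.n_correct + self.n_small + self.n_large != self.n_genes:
            raise ValueError("error-class counts do not sum to n_genes")

    @property
    def pct_correct(self) -> float:
        return round(100.0 * self.n_correct / self.n_genes, 2)

    @property
    def pct_small(self) -> float:
        return round(100.0 * self.n_small / self.n_genes, 2)

    @property
    def pct_large(self) -> float:
        return round(100.0 * self.n_large / self.n_genes, 2)

    def to_dict(self) -> dict:
        return {
            "source": self.spec.source,
            "target": self.spec.target,
            "n_genes": self.n_genes,
            "n_correct": self.n_correct,
            "pct_correct": self.pct_correct,
            "significance": self.significance,
            "n_small": self.n_small,
            "pct_small": self.pct_small,
            "n_large": self.n_large,
            "pct_large": self.pct_large,
        }


def summarize(
    classes: pd.Series,
    spec: ComparisonSpec = ComparisonSpec(),
    null_p: float = 1.0 / 3.0,
    mode: Literal["point", "upper_tail"] = "point",
) -> ValidationSummary:
    """Summarize per-gene error classes into a validation-table row."""
    if len(classes) == 0:
        raise ValueError("empty classification")
    counts = classes.value_counts()
    n = int(len(classes))
    n_correct = int(counts.get(0, 0))
    return ValidationSummary(
        n_genes=n,
        n_correct=n_correct,
        n_small=int(counts.get(1, 0)),
        n_large=int(counts.get(2, 0)),
        significance=binom_significance(n, n_correct, null_p, mode=mode),
        spec=spec,
    )
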