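"""Expression matrices, probe collapsing, differential expression, E_exp.

The experimental counterpart of the model prediction is ``E_exp``: a
per-gene call in {-1, 0, +1} from a two-condition differential-expression
table, using the fold-change filter |log2FC| >= log2(1.5) together with a
raw p-value < 0.05.  Upstream model fits (limma for arrays, edgeR for
counts) are not re-implemented: externally computed DE tables can be
ingested as TSV, and for synthetic data a Welch two-sample test on the
log2 scale stands in.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .network import InteractionNetwork

logger = logging.getLogger(__name__)

Scale = Literal["log_intensity", "intensity", "counts"]

#: Default call thresholds: fold change 1.5 on the log2 scale, raw p < 0.05.
DEFAULT_FC_THRESHOLD = math.log2(1.5)
DEFAULT_ALPHA = 0.05


@dataclass(frozen=True)
class DEThresholds:
    """Differential-expression call thresholds.

    ``fc_threshold`` is inclusive (|log2fc| >= threshold) and ``alpha`` is
    strict (p < alpha), reading "fold change of 1.5 and p-value < 0.05"
    literally.
    """

    fc_threshold: float = DEFAULT_FC_THRESHOLD
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.fc_threshold <= 0:
            raise ValueError("fc_threshold must be > 0")
        if not (0 < self.alpha < 1):
            raise ValueError("alpha must be in (0, 1)")


@dataclass
class ExpressionMatrix:
    """Genes x samples expression table with per-sample group labels.

    ``scale`` declares the measurement scale:

    * ``log_intensity`` — already log2 (normalized array intensities);
      used as-is;
    * ``intensity`` — linear positive intensities; log2 is applied;
    * ``counts`` — non-negative integer read counts; log2(x+1) is applied.
    """

    values: pd.DataFrame
    groups: dict[str, str] = field(default_factory=dict)
    scale: Scale = "log_intensity"

    def __post_init__(self) -> None:
        if self.values.index.has_duplicates:
            raise ValueError("duplicate gene ids in expression matrix")
        if self.values.index.isna().any():
            raise ValueError("missing gene ids in expression matrix")
        if self.scale not in ("log_intensity", "intensity", "counts"):
            raise ValueError(f"unknown scale {self.scale!r}")
        if self.scale == "counts":
            vals = self.values.to_numpy()
            if (vals < 0).any() or not np.allclose(vals, np.round(vals)):
                raise ValueError("counts scale requires non-negative integers")
        unknown = set(self.groups) - set(self.values.columns)
        if unknown:
            raise ValueError(f"group labels for unknown samples: {sorted(unknown)}")

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    @property
    def samples(self) -> list[str]:
        return list(self.values.columns)

    def log2_values(self) -> pd.DataFrame:
        """Values brought to the log2 scale according to ``scale``."""
        if self.scale == "log_intensity":
            return self.values.astype(float)
        if self.scale == "intensity":
            if (self.values.to_numpy() <= 0).any():
                raise ValueError("intensity scale requires strictly positive values")
            return np.log2(self.values.astype(float))
        return np.log2(self.values.astype(float) + 1.0)

    def samples_in_group(self, label: str) -> list[str]:
        return [s for s, g in self.groups.items() if g == label]


# -- I/O ----------------------------------------------------------------------


def read_expression_tsv(
    path: str | Path,
    groups: Mapping[str, str] | None = None,
    scale: Scale = "log_intensity",
) -> ExpressionMatrix:
    """Read a genes-x-samples TSV (first column gene id, header sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    return ExpressionMatrix(values=df, groups=dict(groups or {}), scale=scale)


def write_expression_tsv(matrix: ExpressionMatrix, path: str | Path) -> None:
    matrix.values.to_csv(path, sep="\t", index_label="gene")


def read_de_table(path: str | Path) -> pd.DataFrame:
    """Read a DE table TSV with columns gene, log2fc, pvalue[, eexp]."""
    df = pd.read_csv(path, sep="\t")
    required = {"gene", "log2fc", "pvalue"}
    if not required.issubset(df.columns):
        raise ValueError(f"DE table must have columns {sorted(required)}")
    return df.set_index("gene")


def write_de_table(de: pd.DataFrame, path: str | Path) -> None:
    de.to_csv(path, sep="\t", index_label="gene")


# -- operations ----------------------------------------------------------------


def collapse_by_gene(
    matrix: ExpressionMatrix, probe_map: Mapping[str, str]
) -> ExpressionMatrix:
    """Collapse probe-level rows to one row per gene by the median.

    Probes absent from *probe_map* are dropped (count logged); each gene's
    value per sample is the median over its probes, so the result is
    invariant to probe order.
    """
    if not probe_map:
        raise ValueError("empty probe-to-gene mapping")
    mapped = [p for p in matrix.values.index if p in probe_map]
    dropped = len(matrix.values.index) - len(mapped)
    if dropped:
        logger.info("collapse_by_gene: dropped %d unmapped probes", dropped)
    if not mapped:
        raise ValueError("no probes map to any gene")
    sub = matrix.values.loc[mapped]
    collapsed = sub.groupby([probe_map[p] for p in mapped]).median()
    return ExpressionMatrix(values=collapsed, groups=matrix.groups, scale=matrix.scale)


def differential_expression(
    matrix: ExpressionMatrix, group_a: str, group_b: str
) -> pd.DataFrame:
    """Per-gene log2 fold change (b vs a) and Welch-test p-value.

    ``log2fc = mean(group_b) - mean(group_a)`` on the log2 scale; p-values
    from a two-sample unequal-variance t-test.  Degenerate cases: with one
    sample per group the p-value is NaN (the gene is later excluded from
    calling); zero variance in both groups yields p = 1 for equal means
    and p = 0 otherwise.
    """
    a = matrix.samples_in_group(group_a)
    b = matrix.samples_in_group(group_b)
    if not a:
        raise ValueError(f"no samples labeled {group_a!r}")
    if not b:
        raise ValueError(f"no samples labeled {group_b!r}")
    log2 = matrix.log2_values()
    xa = log2[a].to_numpy(float)
    xb = log2[b].to_numpy(float)
    log2fc = xb.mean(axis=1) - xa.mean(axis=1)
    if len(a) < 2 or len(b) < 2:
        pvalue = np.full(len(log2fc), np.nan)
    else:
        with np.errstate(divide="ignore", invalid="ignore"):
            pvalue = stats.ttest_ind(xb, xa, axis=1, equal_var=False).pvalue
        degenerate = (xa.var(axis=1) == 0) & (xb.var(axis=1) == 0)
        pvalue = np.where(degenerate, np.where(log2fc == 0, 1.0, 0.0), pvalue)
    return pd.DataFrame({"log2fc": log2fc, "pvalue": pvalue}, index=log2.index)


def derive_eexp(
    de: pd.DataFrame, thresholds: DEThresholds = DEThresholds()
) -> pd.DataFrame:
    """Fill the experimental call ``eexp`` in {-1, 0, +1}.

    +1 when log2fc >= fc_threshold with p < alpha, -1 when
    log2fc <= -fc_threshold with p < alpha, 0 otherwise (including NaN
    p-values, i.e. untestable genes).
    """
    out = de.copy()
    sig = de["pvalue"].to_numpy() < thresholds.alpha  # NaN compares False
    fc = de["log2fc"].to_numpy()
    eexp = np.where(sig & (fc >= thresholds.fc_threshold), 1,
                    np.where(sig & (fc <= -thresholds.fc_threshold), -1, 0))
    out["eexp"] = eexp.astype(int)
    return out


def map_genes_to_model(de: pd.DataFrame, net: InteractionNetwork) -> pd.DataFrame:
    """Restrict a DE table to the model's gene nodes by exact id match."""
    if de.index.has_duplicates:
        raise ValueError("duplicate gene rows in DE table; collapse probes first")
    model_genes = set(net.genes())
    keep = [g for g in de.index if g in model_genes]
    logger.info(
        "map_genes_to_model: %d of %d DE genes mapped to model", len(keep), len(de)
    )
    if not keep:
        raise ValueError(
            "no DE genes match model node ids; check gene-symbol normalization"
        )
    return de.loc[keep]
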