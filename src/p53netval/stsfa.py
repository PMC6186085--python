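"""Semi-quantitative signal-transduction score-flow analysis (STSFA).

Expression-derived initial node scores (log2 expression scaled by 100)
are propagated along the signed edges of the network: each node's final
score is its initial score plus the sign-weighted, out-degree-normalized
final scores of its regulators, clamped at zero.  On an acyclic network
this is a single pass in topological order; cycles are handled by damped
fixed-point iteration.

Between two scenarios the per-gene log10 fold change of final scores is
classified against the mean +/- one standard deviation of the fold-change
distribution: above the upper limit -> up-regulated (E_mod = +1), below
the lower limit -> down-regulated (E_mod = -1), otherwise unchanged.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from .expression import ExpressionMatrix
from .lssa import Scenario
from .network import InteractionNetwork

logger = logging.getLogger(__name__)

__all__ = [
    "StsfaConfig",
    "ScoreMap",
    "ScoreFoldChange",
    "initialize_scores",
    "flow_scores",
    "topological_flow_scores",
    "stsfa_emod",
    "score_map_to_frame",
]


@dataclass(frozen=True)
class StsfaConfig:
    """Tunable knobs of the score-flow heuristic.

    scale_factor
        Multiplier applied to log2 expression when seeding node scores
        (default 100, turning log2 intensities into integer-ish inputs).
    tolerance
        Convergence threshold on the maximum relative score change per
        iteration.
    max_iterations
        Cap on fixed-point iterations; ``None`` means ``10 * |V|``.
    clamp_negative
        Clamp final scores at zero (scores are activity levels, not
        signed quantities).
    damping
        Step size of the damped fixed-point update
        ``x <- (1 - damping) * x + damping * F(x)``.  The default 1
        (undamped) is exact on acyclic networks within |V| sweeps;
        values < 1 stabilize oscillatory cycles.
    normalize_by_outdegree
        Divide each regulator's contribution by its out-degree so a hub
        distributes rather than replicates its score.
    """

    scale_factor: float = 100.0
    tolerance: float = 1e-9
    max_iterations: int | None = None
    clamp_negative: bool = True
    damping: float = 1.0
    normalize_by_outdegree: bool = True

    def __post_init__(self) -> None:
        if self.scale_factor <= 0:
            raise ValueError("scale_factor must be > 0")
        if self.tolerance <= 0:
            raise ValueError("tolerance must be > 0")
        if not (0 < self.damping <= 1):
            raise ValueError("damping must be in (0, 1]")


@dataclass
class ScoreMap:
    """Initial and final node scores for one scenario."""

    scenario: Scenario
    init: dict[str, float]
    final: dict[str, float]
    n_iterations: int = 0
    residual: float = 0.0


@dataclass(frozen=True)
class ScoreFoldChange:
    """Per-gene log10 fold change of final scores with mean +/- SD limits."""

    log10fc: pd.Series
    mean_fc: float
    sd_fc: float

    @property
    def upper(self) -> float:
        return self.mean_fc + self.sd_fc

    @property
    def lower(self) -> float:
        return self.mean_fc - self.sd_fc


class ConvergenceError(RuntimeError):
    """Fixed-point iteration failed to reach the tolerance."""


def initialize_scores(
    matrix: ExpressionMatrix,
    sample: str | Iterable[str],
    net: InteractionNetwork,
    scenario: Scenario,
    cfg: StsfaConfig = StsfaConfig(),
) -> dict[str, float]:
    """Seed node scores from one sample (or the mean of a sample group).

    Mapped model genes get ``log2(expression) * scale_factor`` (the log2
    transform follows the matrix scale).  The DNA-damage input node gets
    the arithmetic mean of the mapped gene scores when the scenario has
    damage ON, their minimum when OFF; every unmapped model node gets the
    minimum of the mapped gene scores.
    """
    samples = [sample] if isinstance(sample, str) else list(sample)
    log2 = matrix.log2_values()[samples].mean(axis=1)
    model_genes = set(net.genes())
    mapped = {g: float(log2[g]) * cfg.scale_factor for g in log2.index if g in model_genes}
    if not mapped:
        raise ValueError("no expression genes map to model nodes")
    lowest = min(mapped.values())
    dna_damage = (
        float(np.mean(list(mapped.values()))) if scenario.dna_damage == "ON" else lowest
    )
    init: dict[str, float] = {}
    for v in net.nodes:
        if v == net.input_node:
            init[v] = dna_damage
        else:
            init[v] = mapped.get(v, lowest)
    return init


def _flow_matrix(net: InteractionNetwork, order: list[str], cfg: StsfaConfig) -> np.ndarray:
    idx = {v: i for i, v in enumerate(order)}
    w = np.zeros((len(order), len(order)))
    outdeg = {v: net.out_degree(v) for v in order}
    for e in net.edges:
        weight = float(e.sign)
        if cfg.normalize_by_outdegree and outdeg[e.source] > 0:
            weight /= outdeg[e.source]
        w[idx[e.target], idx[e.source]] += weight
    return w


def flow_scores(
    net: InteractionNetwork,
    init: Mapping[str, float],
    cfg: StsfaConfig = StsfaConfig(),
    scenario: Scenario | None = None,
) -> ScoreMap:
    """Solve ``final = clamp0(init + W @ final)`` by damped iteration.

    ``W[v, u] = sign(u->v) / outdegree(u)`` (normalization optional).
    Starts from ``final = init`` and stops when the maximum relative
    change drops below the tolerance; raises :class:`ConvergenceError`
    with the residual otherwise.  On acyclic networks the solution equals
    a single pass in topological order.
    """
    order = list(net.nodes)
    missing = [v for v in order if v not in init]
    if missing:
        raise ValueError(f"init scores missing for nodes: {missing[:5]}")
    w = _flow_matrix(net, order, cfg)
    x0 = np.array([float(init[v]) for v in order])
    x = x0.copy()
    max_iter = cfg.max_iterations if cfg.max_iterations is not None else 10 * len(order)
    residual = np.inf
    for it in range(1, max_iter + 1):
        fx = x0 + w @ x
        if cfg.clamp_negative:
            np.maximum(fx, 0.0, out=fx)
        x_new = (1.0 - cfg.damping) * x + cfg.damping * fx
        residual = float(np.max(np.abs(x_new - x) / np.maximum(1.0, np.abs(x))))
        x = x_new
        if residual < cfg.tolerance:
            break
    else:
        raise ConvergenceError(
            f"score flow did not converge in {max_iter} iterations "
            f"(residual {residual:.3e} > tolerance {cfg.tolerance:.1e})"
        )
    return ScoreMap(
        scenario=scenario if scenario is not None else Scenario(),
        init=dict(init),
        final={v: float(x[i]) for i, v in enumerate(order)},
        n_iterations=it,
        residual=residual,
    )


def topological_flow_scores(
    net: InteractionNetwork,
    init: Mapping[str, float],
    cfg: StsfaConfig = StsfaConfig(),
) -> dict[str, float]:
    """Single-pass exact evaluation in topological order (acyclic only).

    Independent closed-form route used to cross-check the iterative
    solver; raises on cyclic networks.
    """
    g = net.to_networkx()
    order = list(nx.topological_sort(g))  # raises NetworkXUnfeasible on cycles
    outdeg = {v: net.out_degree(v) for v in net.nodes}
    final: dict[str, float] = {}
    incoming: dict[str, list] = {v: [] for v in net.nodes}
    for e in net.edges:
        incoming[e.target].append(e)
    for v in order:
        total = float(init[v])
        for e in incoming[v]:
            weight = float(e.sign)
            if cfg.normalize_by_outdegree and outdeg[e.source] > 0:
                weight /= outdeg[e.source]
            total += weight * final[e.source]
        final[v] = max(total, 0.0) if cfg.clamp_negative else total
    return final


def stsfa_emod(
    scores1: ScoreMap,
    scores2: ScoreMap,
    genes: Iterable[str],
    pseudocount: float = 1.0,
) -> tuple[dict[str, int], ScoreFoldChange]:
    """Classify per-gene score fold changes into E_mod calls.

    ``log10fc = log10((final2 + eps) / (final1 + eps))`` with a pseudocount
    so clamped zero scores stay finite.  The mean and (sample) standard
    deviation are taken over the supplied gene set; calls are +1 strictly
    above mean+SD, -1 strictly below mean-SD, else 0.
    """
    genes = list(genes)
    if len(genes) < 2:
        raise ValueError("need at least 2 genes to form mean +/- SD limits")
    f1 = np.array([scores1.final[g] for g in genes]) + pseudocount
    f2 = np.array([scores2.final[g] for g in genes]) + pseudocount
    log10fc = pd.Series(np.log10(f2 / f1), index=genes, name="log10fc")
    mean_fc = float(log10fc.mean())
    sd_fc = float(log10fc.std(ddof=1))
    fc = ScoreFoldChange(log10fc=log10fc, mean_fc=mean_fc, sd_fc=sd_fc)
    emod = {
        g: (1 if v > fc.upper else (-1 if v < fc.lower else 0))
        for g, v in log10fc.items()
    }
    return emod, fc


def score_map_to_frame(scores: ScoreMap) -> pd.DataFrame:
    """Node/init/final table (TSV-ready) for one scenario's scores."""
    return pd.DataFrame(
        {"init": pd.Series(scores.init), "final": pd.Series(scores.final)}
    ).rename_axis("node")
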