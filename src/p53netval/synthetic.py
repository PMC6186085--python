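"""Synthetic data generators standing in for the study's real datasets.

Two generators make every pipeline stage testable without downloads:

* :func:`generate_expression_experiment` emulates a two-condition
  cell-line expression experiment (drug-induced DNA damage vs control)
  over a network's genes, with a controllable *concordance*: the fraction
  of model genes whose intended differential-expression call matches the
  logical model prediction E_mod for the chosen scenario pair.

* :func:`generate_cohort` emulates a surgical mesothelioma cohort:
  per-patient read counts over the network genes, TP53 status and
  chemotherapy groups, tumor stages, and survival times drawn from an
  exponential proportional-hazards model whose log-hazard is a linear
  combination of chosen driver genes' standardized pathway scores.

Both are seed-deterministic and return machine-readable ground truth.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .expression import ExpressionMatrix
from .lssa import Scenario, compute_steady_state, derive_emod
from .network import InteractionNetwork
from .stsfa import StsfaConfig, flow_scores, initialize_scores
from .survival import PatientRecord

__all__ = [
    "SynthExperimentSpec",
    "SynthCohortSpec",
    "generate_expression_experiment",
    "generate_cohort",
]

#: Cohort composition of the emulated 71-patient surgical series:
#: (p53 status, chemotherapy) -> fraction.
DEFAULT_GROUP_FRACTIONS: dict[tuple[str, bool], float] = {
    ("wt", True): 27 / 71,
    ("wt", False): 26 / 71,
    ("mut", True): 1 / 71,
    ("mut", False): 17 / 71,
}

#: Stage mix of a surgical mesothelioma series (stages 3-4 dominate).
DEFAULT_STAGE_PROBS: tuple[float, ...] = (0.10, 0.20, 0.40, 0.30)


@dataclass(frozen=True)
class SynthExperimentSpec:
    """Two-condition expression experiment tied to a scenario pair.

    ``concordance`` is the probability that a gene's intended DE call
    equals its model prediction E_mod; a discordant gene's intended call
    is drawn uniformly from the two wrong classes.  ``effect_size`` (log2
    units, default 1.0 = 2-fold) must clear the call threshold log2(1.5);
    ``noise_sd`` (default 0.25) and ``n_replicates`` (default 3) mirror a
    small triplicate array experiment.
    """

    network: InteractionNetwork
    scenario_pair: tuple[Scenario, Scenario] = (
        Scenario("wt", "OFF"),
        Scenario("wt", "ON"),
    )
    concordance: float = 0.75
    n_replicates: int = 3
    noise_sd: float = 0.25
    effect_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 <= self.concordance <= 1):
            raise ValueError("concordance must be in [0, 1]")
        if self.effect_size <= np.log2(1.5):
            raise ValueError("effect_size must exceed log2(1.5) to be callable")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def generate_expression_experiment(
    spec: SynthExperimentSpec,
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Draw a log-intensity matrix whose expected DE calls track E_mod.

    Per model gene: baseline log2 mean ~ U(6, 12); the treated-group mean
    is shifted by ``intended_call * effect_size``; both groups get i.i.d.
    Gaussian noise.  Returns the matrix (groups ``control``/``treated``)
    and a truth table with columns ``emod`` and ``intended_call``.
    """
    net = spec.network
    genes = net.genes()
    if not genes:
        raise ValueError("network has no gene nodes")
    s1 = compute_steady_state(net, spec.scenario_pair[0])
    s2 = compute_steady_state(net, spec.scenario_pair[1])
    emod = derive_emod(s1, s2)

    rng = np.random.default_rng(spec.seed)
    calls = np.empty(len(genes), dtype=int)
    for i, g in enumerate(genes):
        if rng.random() < spec.concordance:
            calls[i] = emod[g]
        else:
            wrong = [c for c in (-1, 0, 1) if c != emod[g]]
            calls[i] = wrong[int(rng.integers(2))]

    n = spec.n_replicates
    baseline = rng.uniform(6.0, 12.0, size=len(genes))
    control = rng.normal(baseline[:, None], spec.noise_sd, size=(len(genes), n))
    treated = rng.normal(
        (baseline + calls * spec.effect_size)[:, None], spec.noise_sd, size=(len(genes), n)
    )
    samples = [f"ctrl_{i+1}" for i in range(n)] + [f"trt_{i+1}" for i in range(n)]
    values = pd.DataFrame(
        np.hstack([control, treated]), index=pd.Index(genes, name="gene"), columns=samples
    )
    groups = {s: ("control" if s.startswith("ctrl") else "treated") for s in samples}
    matrix = ExpressionMatrix(values=values, groups=groups, scale="log_intensity")
    truth = pd.DataFrame(
        {"emod": [emod[g] for g in genes], "intended_call": calls},
        index=pd.Index(genes, name="gene"),
    )
    return matrix, truth


@dataclass(frozen=True)
class SynthCohortSpec:
    """Synthetic surgical cohort with proportional-hazards survival.

    ``driver_genes`` maps gene id -> true beta (log hazard per 1 SD of
    pathway score); ``stage_effect_genes`` maps gene id -> log2 shift
    applied to stage-4 patients' expression of that gene.  Defaults model
    the emulated 71-patient series: its group mix, ~30% censoring, and a
    median survival around 500 days.
    """

    n_patients: int = 71
    group_fractions: Mapping[tuple[str, bool], float] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_FRACTIONS)
    )
    driver_genes: Mapping[str, float] = field(default_factory=dict)
    censoring_fraction: float = 0.3
    stage_effect_genes: Mapping[str, float] = field(default_factory=dict)
    stage_probs: tuple[float, ...] = DEFAULT_STAGE_PROBS
    patient_sd: float = 1.0
    median_survival_days: float = 500.0
    seed: int = 0

    def __post_init__(self) -> None:
        total = sum(self.group_fractions.values())
        if not np.isclose(total, 1.0):
            raise ValueError(f"group fractions must sum to 1, got {total}")
        if self.n_patients < 8:
            raise ValueError("n_patients must be >= 8")
        if not (0 <= self.censoring_fraction < 1):
            raise ValueError("censoring_fraction must be in [0, 1)")


def _group_sizes(
    fractions: Mapping[tuple[str, bool], float], n: int
) -> dict[tuple[str, bool], int]:
    # largest-remainder apportionment so sizes are deterministic and sum to n
    keys = list(fractions)
    raw = np.array([fractions[k] * n for k in keys])
    sizes = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - sizes))[: n - sizes.sum()]:
        sizes[i] += 1
    return {k: int(s) for k, s in zip(keys, sizes)}


def generate_cohort(
    spec: SynthCohortSpec,
    net: InteractionNetwork,
    cfg: StsfaConfig = StsfaConfig(),
) -> tuple[ExpressionMatrix, list[PatientRecord], dict]:
    """Draw a cohort: counts matrix, patient records and ground truth.

    Pipeline: per-patient log2 expression ~ N(gene baseline, patient_sd)
    (stage-4 shifts applied to the designated genes) -> rounded to counts
    -> per-patient pathway scores via the score-flow machinery (scenario
    from the patient's group: damage ON iff chemotherapy, p53 null iff
    mutant) -> survival ~ Exponential with hazard
    ``lambda0 * exp(sum_g beta_g * z_g)`` over standardized driver scores
    -> independent exponential censoring tuned to the requested fraction.

    The truth dict carries the per-patient scores (patients x genes), the
    standardized driver covariates, the drawn event times and the spec.
    """
    for g in spec.driver_genes:
        if g not in net.nodes:
            raise ValueError(f"driver gene {g!r} not in network")
    for g in spec.stage_effect_genes:
        if g not in net.nodes:
            raise ValueError(f"stage-effect gene {g!r} not in network")

    rng = np.random.default_rng(spec.seed)
    genes = net.genes()
    sizes = _group_sizes(spec.group_fractions, spec.n_patients)
    group_of: list[tuple[str, bool]] = []
    for key, size in sizes.items():
        group_of.extend([key] * size)
    rng.shuffle(group_of)

    patient_ids = [f"P{i+1:03d}" for i in range(spec.n_patients)]
    stages = rng.choice(
        [1, 2, 3, 4], size=spec.n_patients, p=np.asarray(spec.stage_probs)
    )

    baseline = rng.uniform(4.0, 10.0, size=len(genes))
    log2x = rng.normal(baseline[None, :], spec.patient_sd,
                       size=(spec.n_patients, len(genes)))
    for g, shift in spec.stage_effect_genes.items():
        j = genes.index(g)
        log2x[stages == 4, j] += shift
    counts = np.rint(np.maximum(2.0**log2x, 0.0))
    values = pd.DataFrame(counts.T, index=pd.Index(genes, name="gene"),
                          columns=patient_ids)
    matrix = ExpressionMatrix(values=values, groups={}, scale="counts")

    # per-patient pathway scores under the patient's own scenario
    score_rows = {}
    for i, pid in enumerate(patient_ids):
        status, chemo = group_of[i]
        scenario = Scenario(
            "null" if status == "mut" else "wt", "ON" if chemo else "OFF"
        )
        init = initialize_scores(matrix, pid, net, scenario, cfg)
        score_rows[pid] = flow_scores(net, init, cfg, scenario=scenario).final
    scores = pd.DataFrame.from_dict(score_rows, orient="index")[list(net.nodes)]
    scores.index.name = "id"

    # proportional-hazards survival on standardized driver scores
    z = pd.DataFrame(index=scores.index)
    linpred = np.zeros(spec.n_patients)
    for g, beta in spec.driver_genes.items():
        col = scores[g].to_numpy(float)
        sd = col.std(ddof=0)
        zg = (col - col.mean()) / sd if sd > 0 else np.zeros_like(col)
        z[g] = zg
        linpred += beta * zg
    lambda0 = np.log(2) / spec.median_survival_days
    hazard = lambda0 * np.exp(linpred)
    event_time = rng.exponential(1.0 / hazard)

    if spec.censoring_fraction > 0:
        # independent Exp(mu) censoring; mu solved so the expected censored
        # fraction over the cohort's hazards equals the request
        def expected_censored(mu: float) -> float:
            return float(np.mean(mu / (mu + hazard)))

        lo, hi = 1e-12, 1e3 * hazard.max()
        mu = brentq(lambda m: expected_censored(m) - spec.censoring_fraction, lo, hi)
        censor_time = rng.exponential(1.0 / mu, size=spec.n_patients)
    else:
        censor_time = np.full(spec.n_patients, np.inf)

    observed = np.minimum(event_time, censor_time)
    event = event_time <= censor_time
    records = [
        PatientRecord(
            id=pid,
            p53_status=group_of[i][0],
            chemo=group_of[i][1],
            survival_days=float(max(observed[i], 1e-6)),
            event=bool(event[i]),
            stage=int(stages[i]),
        )
        for i, pid in enumerate(patient_ids)
    ]
    truth = {
        "scores": scores,
        "standardized_drivers": z,
        "driver_betas": dict(spec.driver_genes),
        "stage_effects": dict(spec.stage_effect_genes),
        "event_time": pd.Series(event_time, index=scores.index, name="event_time"),
        "group_sizes": sizes,
        "spec": spec,
    }
    return matrix, records, truth
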