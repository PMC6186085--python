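"""End-to-end orchestration: file-based runs producing report tables.

Each run reads TSV/JSON inputs, executes the module chain, and writes the
result tables (TSV + JSON) plus a manifest (inputs, config hash, seed,
versions) sufficient to reproduce the outputs exactly.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import platform
from dataclasses import dataclass, field
from importlib import metadata, resources
from pathlib import Path

import pandas as pd

from . import expression as expr
from .expression import DEThresholds
from .lssa import Scenario, compute_steady_state, derive_emod
from .network import InteractionNetwork, read_network
from .staging import compare_stages, stage_table
from .stsfa import StsfaConfig, flow_scores, initialize_scores, stsfa_emod
from .survival import (
    correlate_scores_with_survival,
    cox_table,
    read_patients_tsv,
    stratify_patients,
)
from .validation import ComparisonSpec, classify_predictions, summarize

logger = logging.getLogger(__name__)

__all__ = [
    "RunConfig",
    "run_lssa_validation",
    "run_stsfa_validation",
    "run_patient_analysis",
    "load_drug_targets",
]

MIN_GROUP_SIZE = 3  # smallest stratification group worth a per-group table


@dataclass
class RunConfig:
    """File paths, scenario pair, thresholds and output location of a run."""

    network_path: str | Path | None = None
    expression_path: str | Path | None = None
    de_path: str | Path | None = None
    metadata_path: str | Path | None = None
    design: dict[str, str] = field(default_factory=dict)  # sample -> group label
    group_a: str = "control"
    group_b: str = "treated"
    scenario_pair: tuple[Scenario, Scenario] = (
        Scenario("wt", "OFF"),
        Scenario("wt", "ON"),
    )
    thresholds: DEThresholds = field(default_factory=DEThresholds)
    stsfa: StsfaConfig = field(default_factory=StsfaConfig)
    expression_scale: str = "log_intensity"
    out_dir: str | Path = "p53netval_out"
    seed: int = 0

    def outdir(self) -> Path:
        out = Path(self.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        return out


def _config_hash(cfg: RunConfig) -> str:
    def default(o):
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return str(o)

    payload = json.dumps(dataclasses.asdict(cfg), default=default, sort_keys=True)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _write_manifest(cfg: RunConfig, out: Path, stage: str) -> None:
    try:
        version = metadata.version("p53netval")
    except metadata.PackageNotFoundError:  # editable/dev tree
        version = "dev"
    manifest = {
        "stage": stage,
        "config_hash": _config_hash(cfg),
        "seed": cfg.seed,
        "inputs": {
            k: str(getattr(cfg, k))
            for k in ("network_path", "expression_path", "de_path", "metadata_path")
            if getattr(cfg, k) is not None
        },
        "package_version": version,
        "python": platform.python_version(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2) + "\n")


def _load_network(cfg: RunConfig) -> InteractionNetwork:
    if cfg.network_path is None:
        raise FileNotFoundError("run config has no network_path")
    return read_network(cfg.network_path)


def _load_eexp(cfg: RunConfig, net: InteractionNetwork) -> pd.DataFrame:
    """DE table with eexp calls restricted to model genes."""
    if cfg.de_path is not None:
        de = expr.read_de_table(cfg.de_path)
    elif cfg.expression_path is not None:
        matrix = expr.read_expression_tsv(
            cfg.expression_path, groups=cfg.design, scale=cfg.expression_scale
        )
        de = expr.differential_expression(matrix, cfg.group_a, cfg.group_b)
    else:
        raise FileNotFoundError("run config needs de_path or expression_path")
    de = expr.derive_eexp(de, cfg.thresholds)
    return expr.map_genes_to_model(de, net)


def run_lssa_validation(cfg: RunConfig):
    """Logical steady-state validation: E_mod vs E_exp summary files."""
    out = cfg.outdir()
    net = _load_network(cfg)
    eexp = _load_eexp(cfg, net)
    s1 = compute_steady_state(net, cfg.scenario_pair[0])
    s2 = compute_steady_state(net, cfg.scenario_pair[1])
    emod = derive_emod(s1, s2)
    classes = classify_predictions(emod, eexp)
    spec = ComparisonSpec(source=cfg.group_a, target=cfg.group_b,
                          simulation=cfg.scenario_pair)
    summary = summarize(classes, spec)
    _emit_validation(summary, classes, out, "lssa")
    _write_manifest(cfg, out, "lssa")
    return summary


def run_stsfa_validation(cfg: RunConfig):
    """Score-flow validation: scenario-pair score fold changes vs E_exp."""
    out = cfg.outdir()
    net = _load_network(cfg)
    if cfg.expression_path is None:
        raise FileNotFoundError("STSFA validation needs expression_path")
    matrix = expr.read_expression_tsv(
        cfg.expression_path, groups=cfg.design, scale=cfg.expression_scale
    )
    eexp = _load_eexp(cfg, net)

    maps = []
    for scenario, label in zip(cfg.scenario_pair, (cfg.group_a, cfg.group_b)):
        samples = matrix.samples_in_group(label) or matrix.samples
        init = initialize_scores(matrix, samples, net, scenario, cfg.stsfa)
        maps.append(flow_scores(net, init, cfg.stsfa, scenario=scenario))
    emod, fc = stsfa_emod(maps[0], maps[1], genes=list(eexp.index))
    classes = classify_predictions(emod, eexp)
    spec = ComparisonSpec(source=cfg.group_a, target=cfg.group_b,
                          simulation=cfg.scenario_pair)
    summary = summarize(classes, spec)
    fc_table = pd.DataFrame(
        {"log10fc": fc.log10fc, "call": pd.Series(emod)}
    ).rename_axis("gene")
    fc_table.to_csv(out / "stsfa_fold_changes.tsv", sep="\t")
    _emit_validation(summary, classes, out, "stsfa")
    _write_manifest(cfg, out, "stsfa")
    return summary


def _emit_validation(summary, classes, out: Path, prefix: str) -> None:
    row = pd.DataFrame([summary.to_dict()])
    row.to_csv(out / f"{prefix}_validation.tsv", sep="\t", index=False)
    (out / f"{prefix}_validation.json").write_text(
        json.dumps(summary.to_dict(), indent=2) + "\n"
    )
    classes.rename_axis("gene").to_frame().to_csv(
        out / f"{prefix}_error_classes.tsv", sep="\t"
    )


def run_patient_analysis(cfg: RunConfig):
    """Per-patient scoring, stratified Pearson tables, pooled Cox, staging."""
    out = cfg.outdir()
    net = _load_network(cfg)
    if cfg.expression_path is None or cfg.metadata_path is None:
        raise FileNotFoundError("patient analysis needs expression_path and metadata_path")
    matrix = expr.read_expression_tsv(cfg.expression_path, scale=cfg.expression_scale)
    records = read_patients_tsv(cfg.metadata_path)
    groups = stratify_patients(records)
    logger.info(
        "patient groups: %s",
        {f"{s}_{'T' if c else 'UT'}": len(m) for (s, c), m in groups.items()},
    )

    score_rows = {}
    for r in records:
        if r.id not in matrix.samples:
            logger.warning("patient %s has no expression column; skipped", r.id)
            continue
        scenario = Scenario("null" if r.p53_status == "mut" else "wt",
                            "ON" if r.chemo else "OFF")
        init = initialize_scores(matrix, r.id, net, scenario, cfg.stsfa)
        score_rows[r.id] = flow_scores(net, init, cfg.stsfa, scenario=scenario).final
    scores = pd.DataFrame.from_dict(score_rows, orient="index")[list(net.nodes)]
    scores.rename_axis("id").to_csv(out / "patient_scores.tsv", sep="\t")

    genes = net.genes()
    results: dict[str, pd.DataFrame] = {}
    for (status, chemo), members in groups.items():
        label = f"{status}_{'T' if chemo else 'UT'}"
        if len(members) < MIN_GROUP_SIZE:
            logger.warning("group %s below minimum size (%d); skipped",
                           label, len(members))
            continue
        table = correlate_scores_with_survival(scores, members, genes)
        table.to_csv(out / f"pearson_{label}.tsv", sep="\t", index=False)
        results[label] = table

    cox = cox_table(scores, records, genes, standardize=True)
    cox.to_csv(out / "cox_univariate.tsv", sep="\t", index=False)

    staged = [r for r in records if r.stage is not None]
    if staged:
        stages = stage_table(compare_stages(scores, records, genes))
        stages.to_csv(out / "stage_anova.tsv", sep="\t", index=False)
    else:
        logger.warning("no stage information; staging analysis skipped")
        stages = None
    _write_manifest(cfg, out, "patient")
    return {"pearson": results, "cox": cox, "stages": stages, "scores": scores}


def load_drug_targets() -> pd.DataFrame:
    """Packaged static drug-target table (approved drugs, direct targets)."""
    with resources.files("p53netval").joinpath("data/drug_targets.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")
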