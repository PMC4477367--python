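"""End-to-end orchestration: network -> modules -> prognosis -> crosstalk.

All stage parameters live in one :class:`PipelineConfig` whose defaults
are the analysis' standard settings (37-month stratification, 0.90
interaction confidence, 10,000 score resamples, top 1% + p < 0.01 module
selection, 0.1 survival screen, 0.1 regulator cutoff).  Every run writes
the resolved configuration (with a content hash) next to its outputs,
and all randomness flows from the single global seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from survmod import io as smio
from survmod.cohort import SurvivalCohort, read_cohort
from survmod.crosstalk import InteractionUniverse, crosstalk_with_celldeath
from survmod.modules import (
    AnnealConfig,
    adjust_modules,
    merge_modules,
    select_candidates,
    simulated_annealing_search,
)
from survmod.network import build_weighted_network
from survmod.survival import evaluate_module

log = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Paths and parameters for a full run."""

    expression_train: str = ""
    clinical_train: str = ""
    expression_test: str | None = None
    clinical_test: str | None = None
    expression_external: str | None = None
    clinical_external: str | None = None
    edges: str = ""
    rna_edges: str | None = None
    celldeath: str | None = None
    out_dir: str = "survmod_run"

    threshold_months: float = 37.0
    min_confidence: float = 0.90
    censored_policy: str = "exclude"
    n_perm: int = 10_000
    top_fraction: float = 0.01
    module_p_cutoff: float = 0.01
    overlap_merge: float = 0.8
    alpha_screen: float = 0.1
    regulator_p_cutoff: float = 0.1
    max_module_size: int = 20
    n_restarts: int = 20
    n_iterations: int = 10_000
    seed: int = 0

    def resolved(self) -> dict:
        d = dataclasses.asdict(self)
        blob = json.dumps(d, sort_keys=True).encode()
        d["config_hash"] = hashlib.sha256(blob).hexdigest()[:16]
        return d

    @classmethod
    def from_file(cls, path: str | Path) -> "PipelineConfig":
        text = Path(path).read_text()
        if str(path).endswith((".yaml", ".yml")):
            import yaml

            data = yaml.safe_load(text)
        else:
            data = json.loads(text)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)


@dataclass
class ValidationReport:
    fatal: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.fatal

    def to_dict(self) -> dict:
        return {"ok": self.ok, "fatal": self.fatal, "warnings": self.warnings}


def validate_inputs(config: PipelineConfig) -> ValidationReport:
    """Schema and cross-reference checks; fatal findings abort a run."""
    report = ValidationReport()
    for label, path in [
        ("expression_train", config.expression_train),
        ("clinical_train", config.clinical_train),
        ("edges", config.edges),
    ]:
        if not path or not Path(path).exists():
            report.fatal.append(f"missing required input {label}: {path!r}")
    if report.fatal:
        return report
    try:
        cohort = read_cohort(config.expression_train, config.clinical_train)
    except Exception as err:  # schema violations surface here
        report.fatal.append(f"training cohort failed to parse: {err}")
        return report
    try:
        edges = smio.read_edge_list(config.edges)
    except Exception as err:
        report.fatal.append(f"edge list failed to parse: {err}")
        return report
    if ((edges["confidence"] < 0) | (edges["confidence"] > 1)).any():
        report.fatal.append("edge confidences outside [0, 1]")
    net_genes = set(edges["gene_a"]) | set(edges["gene_b"])
    expressed = set(cohort.genes)
    orphan = net_genes - expressed
    if orphan:
        report.warnings.append(
            f"{len(orphan)} network genes absent from expression (dropped downstream)"
        )
    if len(net_genes & expressed) < 2:
        report.fatal.append("fewer than 2 genes shared between network and expression")
    for label, ep, cp in [
        ("test", config.expression_test, config.clinical_test),
        ("external", config.expression_external, config.clinical_external),
    ]:
        if (ep is None) != (cp is None):
            report.fatal.append(f"{label} cohort needs both expression and clinical paths")
        elif ep is not None and (not Path(ep).exists() or not Path(cp).exists()):
            report.fatal.append(f"{label} cohort file missing: {ep} / {cp}")
    return report


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write stage outputs under ``config.out_dir``,
    and return the machine-readable summary."""
    report = validate_inputs(config)
    if not report.ok:
        raise ValueError("input validation failed: " + "; ".join(report.fatal))

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    resolved = config.resolved()
    (out / "config_resolved.json").write_text(json.dumps(resolved, indent=2) + "\n")

    train = read_cohort(config.expression_train, config.clinical_train, "training")
    test = (
        read_cohort(config.expression_test, config.clinical_test, "test")
        if config.expression_test
        else None
    )
    external = (
        read_cohort(config.expression_external, config.clinical_external, "external")
        if config.expression_external
        else None
    )
    edges = smio.read_edge_list(config.edges)

    log.info("stage 1/4: weighted network construction")
    network = build_weighted_network(
        train,
        edges,
        threshold=config.threshold_months,
        min_confidence=config.min_confidence,
        censored_policy=config.censored_policy,
    )
    network.write(out / "network")

    log.info("stage 2/4: simulated-annealing module search")
    seeds = np.random.SeedSequence(config.seed).generate_state(2)
    anneal = AnnealConfig(
        n_iterations=config.n_iterations,
        max_module_size=config.max_module_size,
        n_restarts=config.n_restarts,
        seed=int(seeds[0] % 2**31),
    )
    raw_modules = simulated_annealing_search(network, anneal)
    merged = merge_modules(raw_modules, network, config.overlap_merge)
    adjusted = adjust_modules(
        merged, network, n_perm=config.n_perm, seed=int(seeds[1] % 2**31)
    )
    selected, score_threshold = select_candidates(
        adjusted, config.top_fraction, config.module_p_cutoff
    )
    log.info(
        "modules: %d per-restart -> %d merged -> %d selected",
        len(raw_modules), len(merged), len(selected),
    )
    smio.write_gmt(adjusted, out / "modules_all.gmt")
    smio.write_gmt(selected, out / "modules_selected.gmt")

    log.info("stage 3/4: prognostic evaluation")
    evaluations = []
    for mod in selected:
        rep = evaluate_module(
            mod.genes, train, test, external, alpha_screen=config.alpha_screen
        )
        evaluations.append(rep)

    log.info("stage 4/4: crosstalk analysis")
    rna = smio.read_rna_edges(config.rna_edges) if config.rna_edges else None
    celldeath = smio.read_gene_list(config.celldeath) if config.celldeath else []
    universe = InteractionUniverse(ppi_edges=edges, rna_protein_edges=rna)
    crosstalks = []
    for mod in selected:
        ct = crosstalk_with_celldeath(
            mod.genes, universe, celldeath, p_cutoff=config.regulator_p_cutoff
        )
        crosstalks.append(ct)
        if ct.wiring is not None:
            ct.wiring.to_csv(
                out / f"wiring_{len(crosstalks):03d}.tsv", sep="\t", index=False
            )

    summary = {
        "config_hash": resolved["config_hash"],
        "n_nodes": network.n_nodes(),
        "n_edges": network.n_edges(),
        "strata": {
            "longer": network.strata.n_longer,
            "shorter": network.strata.n_shorter,
        },
        "n_modules_restarts": len(raw_modules),
        "n_modules_merged": len(merged),
        "n_modules_selected": len(selected),
        "score_threshold": score_threshold,
        "modules": [m.to_dict() for m in selected],
        "prognosis": [r.to_dict() for r in evaluations],
        "crosstalk": [c.to_dict() for c in crosstalks],
    }
    (out / "summary.json").write_text(json.dumps(summary, indent=2) + "\n")
    _write_human_report(summary, out / "report.txt")
    return summary


def _write_human_report(summary: dict, path: Path) -> None:
    lines = [
        "survmod run summary",
        "===================",
        f"network: {summary['n_nodes']} genes, {summary['n_edges']} interactions",
        f"strata: {summary['strata']['longer']} longer / {summary['strata']['shorter']} shorter survivors",
        f"modules: {summary['n_modules_restarts']} restart bests -> "
        f"{summary['n_modules_merged']} merged -> {summary['n_modules_selected']} selected",
    ]
    for i, (mod, prog) in enumerate(zip(summary["modules"], summary["prognosis"]), 1):
        tr = prog["cohorts"]["training"]
        lines.append(
            f"module {i}: {mod['n_genes']} genes, adjusted score "
            f"{mod['adjusted_score']:.2f} (p={mod['empirical_p']:.4f}); "
            f"training log-rank p={tr['logrank_p']:.3g}"
        )
    for i, ct in enumerate(summary["crosstalk"], 1):
        lines.append(
            f"module {i} crosstalk: {ct['n_regulators']} regulators, "
            f"{ct['overlap_count']} overlap cell-death genes (p={ct['overlap_p']})"
        )
    path.write_text("\n".join(lines) + "\n")
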