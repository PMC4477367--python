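"""Synthetic cohorts, interaction networks and annotations with a planted module.

The generator emulates the statistical structure the downstream analysis
assumes, without any external data:

* a scale-free background interaction network with a wired-in connected
  module of ``planted_module_size`` genes;
* right-censored survival times from an exponential proportional-hazards
  model driven by a latent module-activity factor, so planted genes carry
  survival association (``node_effect``);
* planted-module gene pairs whose Pearson correlation differs by
  ``edge_effect`` between patients in the longer- and shorter-survival
  strata (stratum defined by ``survival_threshold_months``);
* regulator genes adjacent to the module, a cell-death gene list enriched
  for those regulators, and a few miRNA identifiers wired to module genes
  through directed RNA->protein edges.

Every quantity is drawn from a single seeded stream, so an identical
configuration yields a byte-identical bundle.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import brentq

from survmod.cohort import SurvivalCohort

SPLITS = ("training", "test", "external")


@dataclass(frozen=True)
class SimulationConfig:
    """All knobs of the synthetic study, with the default study conditions.

    ``node_effect`` is the log-hazard ratio per unit of latent module
    activity; ``edge_effect`` is the target correlation difference
    (r_longer - r_shorter) on planted edges.  ``baseline_coexpression``
    is the stratum-averaged within-module correlation around which the
    two strata are placed symmetrically.
    """

    n_genes: int = 500
    n_patients_per_cohort: int = 200
    planted_module_size: int = 12
    node_effect: float = 0.7
    edge_effect: float = 0.6
    baseline_coexpression: float = 0.35
    background_degree: float = 4.0
    module_extra_edge_prob: float = 0.25
    censoring_rate: float = 0.3
    survival_threshold_months: float = 37.0
    n_celldeath: int = 60
    n_regulators: int = 15
    regulator_links: int = 3
    regulator_celldeath_fraction: float = 0.8
    n_rna_regulators: int = 4
    min_confidence: float = 0.90
    seed: int = 0

    def validate(self) -> None:
        if self.planted_module_size < 2:
            raise ValueError("planted_module_size must be >= 2")
        if self.n_genes < self.planted_module_size:
            raise ValueError(
                f"n_genes ({self.n_genes}) must be >= planted_module_size "
                f"({self.planted_module_size})"
            )
        if not 0 <= self.censoring_rate < 1:
            raise ValueError("censoring_rate must lie in [0, 1)")
        if not -2 < self.edge_effect < 2:
            raise ValueError("edge_effect must lie in (-2, 2)")
        lo = self.baseline_coexpression - abs(self.edge_effect) / 2
        hi = self.baseline_coexpression + abs(self.edge_effect) / 2
        if lo < 0 or hi > 0.97:
            raise ValueError(
                "baseline_coexpression +/- edge_effect/2 must stay in "
                f"[0, 0.97]; got [{lo:.3f}, {hi:.3f}]"
            )
        if self.n_celldeath > self.n_genes:
            raise ValueError("n_celldeath must not exceed n_genes")
        if self.n_celldeath > self.n_genes - self.planted_module_size:
            raise ValueError(
                "n_celldeath must leave room outside the planted module "
                f"(max {self.n_genes - self.planted_module_size})"
            )
        if self.n_regulators > self.n_genes - self.planted_module_size:
            raise ValueError("n_regulators exceeds available non-module genes")
        if self.survival_threshold_months <= 0:
            raise ValueError("survival_threshold_months must be positive")
        if self.n_patients_per_cohort < 10:
            raise ValueError("n_patients_per_cohort must be >= 10")


class AnnotationSet(NamedTuple):
    celldeath_genes: list[str]
    rna_protein_edges: pd.DataFrame
    planted_regulators: list[str]
    edges: pd.DataFrame  # network augmented with regulator wiring


@dataclass
class SyntheticBundle:
    """Everything one synthetic study produces, plus the generative truth."""

    config: SimulationConfig
    cohorts: dict[str, SurvivalCohort]
    network: pd.DataFrame  # columns gene_a, gene_b, confidence
    rna_protein_edges: pd.DataFrame  # columns rna_id, protein_gene
    celldeath_genes: list[str]
    planted_module: list[str]
    planted_regulators: list[str]

    def truth(self) -> dict:
        return {
            "planted_module": sorted(self.planted_module),
            "planted_regulators": sorted(self.planted_regulators),
        }

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for cohort in self.cohorts.values():
            cohort.write(outdir)
        self.network.to_csv(outdir / "edges.tsv", sep="\t", index=False)
        self.rna_protein_edges.to_csv(
            outdir / "rna_protein.tsv", sep="\t", index=False
        )
        (outdir / "celldeath.txt").write_text(
            "\n".join(self.celldeath_genes) + "\n"
        )
        (outdir / "truth.json").write_text(
            json.dumps(self.truth(), indent=2) + "\n"
        )


def _gene_names(n: int) -> list[str]:
    width = max(4, len(str(n)))
    return [f"G{i:0{width}d}" for i in range(1, n + 1)]


def generate_network(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[pd.DataFrame, list[str]]:
    """Scale-free background plus a wired-in connected planted module.

    Returns the edge list (``gene_a``, ``gene_b``, ``confidence``) and the
    planted gene list.  The planted module is connected by construction: a
    random spanning tree over the planted genes plus Bernoulli extra edges
    at ``module_extra_edge_prob``.  All confidences are drawn uniformly in
    [``min_confidence``, 1] so the default downstream filter keeps them.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    names = _gene_names(config.n_genes)
    m = max(1, int(round(config.background_degree / 2)))
    ba_seed = int(rng.integers(2**31))
    g = nx.barabasi_albert_graph(config.n_genes, m, seed=ba_seed)
    graph = nx.relabel_nodes(g, dict(enumerate(names)))

    planted = sorted(
        str(g) for g in rng.choice(names, size=config.planted_module_size, replace=False)
    )
    # random spanning tree over the planted genes guarantees connectivity
    order = list(rng.permutation(planted))
    for i, gene in enumerate(order[1:], start=1):
        graph.add_edge(gene, order[int(rng.integers(i))])
    for i, a in enumerate(planted):
        for b in planted[i + 1 :]:
            if not graph.has_edge(a, b) and rng.random() < config.module_extra_edge_prob:
                graph.add_edge(a, b)

    pairs = sorted(tuple(sorted(e)) for e in graph.edges())
    conf = rng.uniform(config.min_confidence, 1.0, size=len(pairs))
    edges = pd.DataFrame(
        {
            "gene_a": [p[0] for p in pairs],
            "gene_b": [p[1] for p in pairs],
            "confidence": np.round(conf, 4),
        }
    )
    return edges, list(planted)


def _censoring_horizon(rates: np.ndarray, target: float) -> float:
    """Administrative horizon C with E[fraction surviving past C] = target."""
    if target <= 0:
        return math.inf

    def expected_censored(c: float) -> float:
        return float(np.mean(np.exp(-rates * c))) - target

    hi = 1.0
    while expected_censored(hi) > 0:
        hi *= 2
    return brentq(expected_censored, 1e-9, hi)


def generate_cohort(
    config: SimulationConfig,
    planted: list[str],
    split_label: str,
    rng: np.random.Generator,
) -> SurvivalCohort:
    """One cohort from the shared generative truth with independent noise.

    A latent module-activity factor f ~ N(0,1) per patient drives both the
    hazard (rate = log(2)/threshold * exp(node_effect * f), so the null
    median survival equals the stratification threshold) and, through an
    equicorrelated one-factor model, the planted genes' expression.  The
    within-module correlation is baseline + edge_effect/2 for patients
    whose (uncensored) survival reaches the threshold and baseline -
    edge_effect/2 otherwise, which is exactly the differential
    co-expression the edge statistic measures.  Background genes are
    independent standard normal.  Censoring is administrative at a fixed
    horizon calibrated to the requested rate.
    """
    config.validate()
    n = config.n_patients_per_cohort
    names = _gene_names(config.n_genes)
    planted_set = set(planted)
    if not planted_set <= set(names):
        raise ValueError("planted genes must be drawn from the gene universe")

    factor = rng.standard_normal(n)
    lam0 = math.log(2) / config.survival_threshold_months
    rates = lam0 * np.exp(config.node_effect * factor)
    true_time = rng.exponential(1.0 / rates)

    horizon = _censoring_horizon(rates, config.censoring_rate)
    os_months = np.minimum(true_time, horizon)
    event = (true_time <= horizon).astype(int)
    os_months = np.maximum(os_months, 1e-3)  # keep times positive

    longer = true_time >= config.survival_threshold_months
    if longer.all() or (~longer).all():
        raise ValueError(
            "one survival stratum is empty; increase n_patients_per_cohort "
            "or adjust survival_threshold_months"
        )

    r_long = config.baseline_coexpression + config.edge_effect / 2
    r_short = config.baseline_coexpression - config.edge_effect / 2
    rho = np.where(longer, r_long, r_short)

    expr = rng.standard_normal((config.n_genes, n))
    idx = [i for i, g in enumerate(names) if g in planted_set]
    load = np.sqrt(rho)
    resid = np.sqrt(1.0 - rho)
    expr[idx, :] = load * factor + resid * expr[idx, :]

    prefix = {"training": "TR", "test": "TE", "external": "EX"}.get(
        split_label, split_label[:2].upper()
    )
    patients = [f"{prefix}{i:04d}" for i in range(1, n + 1)]
    expression = pd.DataFrame(
        np.round(expr, 6), index=names, columns=patients
    )

    clinical = pd.DataFrame(
        {
            "os_months": np.round(os_months, 4),
            "event": event,
            "age": np.round(rng.normal(60, 10, size=n)).astype(int),
            "stage": rng.choice(["III", "IV"], size=n, p=[0.7, 0.3]),
            "grade": rng.choice(["G3", "G4"], size=n, p=[0.75, 0.25]),
            "residual": rng.choice(["0-10mm", ">10mm"], size=n, p=[0.55, 0.45]),
        },
        index=pd.Index(patients, name="patient_id"),
    )
    return SurvivalCohort(expression=expression, clinical=clinical, split_label=split_label)


def generate_annotations(
    config: SimulationConfig,
    edges: pd.DataFrame,
    planted: list[str],
    rng: np.random.Generator,
) -> AnnotationSet:
    """Regulators adjacent to the module, cell-death labels, RNA edges.

    ``n_regulators`` non-module genes are each wired to ``regulator_links``
    distinct module genes (edges added when absent, at the network's
    confidence floor), and ``n_rna_regulators`` miRNA identifiers are given
    directed RNA->protein edges to module genes.  A
    ``regulator_celldeath_fraction`` share of all regulators is labelled
    cell-death; the list is padded with random non-neighbour genes up to
    ``n_celldeath``.
    """
    config.validate()
    names = _gene_names(config.n_genes)
    planted_set = set(planted)
    pool = [g for g in names if g not in planted_set]

    regulators = sorted(
        str(g) for g in rng.choice(pool, size=config.n_regulators, replace=False)
    )
    existing = {tuple(sorted(p)) for p in zip(edges["gene_a"], edges["gene_b"])}
    new_rows = []
    for reg in regulators:
        targets = rng.choice(planted, size=min(config.regulator_links, len(planted)), replace=False)
        for t in targets:
            pair = tuple(sorted((reg, t)))
            if pair not in existing:
                existing.add(pair)
                new_rows.append(
                    {
                        "gene_a": pair[0],
                        "gene_b": pair[1],
                        "confidence": round(
                            float(rng.uniform(config.min_confidence, 1.0)), 4
                        ),
                    }
                )
    augmented = pd.concat(
        [edges, pd.DataFrame(new_rows, columns=edges.columns)], ignore_index=True
    ) if new_rows else edges.copy()
    augmented = augmented.sort_values(["gene_a", "gene_b"], ignore_index=True)

    rna_ids = [f"MIR{i:03d}" for i in range(1, config.n_rna_regulators + 1)]
    rna_rows = []
    for rna in rna_ids:
        k = int(rng.integers(2, min(4, len(planted)) + 1))
        for t in sorted(rng.choice(planted, size=k, replace=False)):
            rna_rows.append({"rna_id": rna, "protein_gene": t})
    rna_edges = pd.DataFrame(rna_rows, columns=["rna_id", "protein_gene"])

    all_regs = regulators + rna_ids
    n_cd_regs = int(round(config.regulator_celldeath_fraction * len(all_regs)))
    cd_regs = [str(g) for g in rng.choice(all_regs, size=n_cd_regs, replace=False)] if n_cd_regs else []

    module_neighbors = {
        b for a, b in zip(augmented["gene_a"], augmented["gene_b"]) if a in planted_set
    } | {
        a for a, b in zip(augmented["gene_a"], augmented["gene_b"]) if b in planted_set
    }
    filler_pool = [
        g
        for g in pool
        if g not in set(regulators) and g not in module_neighbors
    ]
    n_fill = max(0, config.n_celldeath - len(cd_regs))
    if n_fill > len(filler_pool):
        filler_pool = sorted(set(pool) - set(cd_regs))
    filler = [str(g) for g in rng.choice(filler_pool, size=n_fill, replace=False)] if n_fill else []
    celldeath = sorted(set(cd_regs) | set(filler))

    return AnnotationSet(
        celldeath_genes=celldeath,
        rna_protein_edges=rna_edges,
        planted_regulators=sorted(all_regs),
        edges=augmented,
    )


def generate_bundle(config: SimulationConfig | None = None, **overrides) -> SyntheticBundle:
    """Generate the full synthetic study: network, three cohorts, annotations.

    Training, internal-test and external cohorts share the generative truth
    (planted module, effect sizes) but have independent noise.  All
    randomness derives from ``config.seed`` via spawned child streams, so
    the bundle is a pure function of the configuration.
    """
    if config is None:
        config = SimulationConfig(**overrides)
    elif overrides:
        config = dataclasses.replace(config, **overrides)
    config.validate()

    root = np.random.SeedSequence(config.seed)
    net_ss, ann_ss, *cohort_ss = root.spawn(2 + len(SPLITS))
    edges, planted = generate_network(config, np.random.default_rng(net_ss))
    annotations = generate_annotations(
        config, edges, planted, np.random.default_rng(ann_ss)
    )
    cohorts = {
        split: generate_cohort(config, planted, split, np.random.default_rng(ss))
        for split, ss in zip(SPLITS, cohort_ss)
    }
    return SyntheticBundle(
        config=config,
        cohorts=cohorts,
        network=annotations.edges,
        rna_protein_edges=annotations.rna_protein_edges,
        celldeath_genes=annotations.celldeath_genes,
        planted_module=planted,
        planted_regulators=annotations.planted_regulators,
    )
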