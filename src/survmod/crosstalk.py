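"""Module crosstalk with cell-death genes via hypergeometric neighbour tests.

For every gene (or RNA) directly interacting with a module gene, the
number of its links into the module is tested against a hypergeometric
null: drawing ``degree`` neighbours from the interaction universe, how
surprising is observing at least ``x`` module genes?  Genes passing
p < 0.1 (raw, matching the screening convention; a BH-adjusted column is
also emitted) are the module's significant regulators.  The regulator
set's overlap with an annotated cell-death gene list is itself tested
hypergeometrically, and the overlapping genes' wiring onto the module is
extracted for visualisation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.stats import hypergeom


def hypergeometric_tail(x: int, K: int, n: int, N: int) -> float:
    """Exact upper-tail P(X >= x) for X ~ Hypergeometric(N, K, n).

    ``N`` population size, ``K`` successes in the population, ``n`` draws,
    ``x`` observed successes.
    """
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"inconsistent parameters: K={K}, n={n}, N={N}")
    if x < 0 or x > n or x > K:
        raise ValueError(f"x={x} outside [0, min(n={n}, K={K})]")
    return float(hypergeom.sf(x - 1, N, K, n))


@dataclass
class InteractionUniverse:
    """Combined PPI + RNA->protein interaction graph.

    PPI edges are undirected; RNA->protein edges attach RNA regulators to
    their protein targets (RNAs never join modules but can regulate
    them).  Adjacency and degree are taken on the undirected union.
    """

    ppi_edges: pd.DataFrame  # gene_a, gene_b (first two columns)
    rna_protein_edges: pd.DataFrame | None = None  # rna_id, protein_gene
    _adj: dict | None = field(default=None, repr=False)
    _rna_nodes: set | None = field(default=None, repr=False)

    def _build(self) -> None:
        adj: dict[str, set[str]] = {}

        def link(a: str, b: str) -> None:
            if a == b:
                return
            adj.setdefault(a, set()).add(b)
            adj.setdefault(b, set()).add(a)

        for a, b in zip(self.ppi_edges.iloc[:, 0], self.ppi_edges.iloc[:, 1]):
            link(str(a), str(b))
        rna_nodes: set[str] = set()
        if self.rna_protein_edges is not None:
            for r, p in zip(
                self.rna_protein_edges.iloc[:, 0], self.rna_protein_edges.iloc[:, 1]
            ):
                rna_nodes.add(str(r))
                link(str(r), str(p))
        self._adj = adj
        self._rna_nodes = rna_nodes

    @property
    def adjacency(self) -> dict[str, set[str]]:
        if self._adj is None:
            self._build()
        return self._adj

    @property
    def rna_nodes(self) -> set[str]:
        if self._rna_nodes is None:
            self._build()
        return self._rna_nodes

    @property
    def nodes(self) -> set[str]:
        return set(self.adjacency)

    def n_total(self) -> int:
        return len(self.adjacency)


@dataclass
class CrosstalkResult:
    """Neighbour-level regulation tests plus cell-death overlap."""

    module_genes: list[str]
    neighbor_table: pd.DataFrame  # gene, links_to_module, degree, p, p_bh
    regulators: list[str]
    p_cutoff: float
    overlap_genes: list[str] = field(default_factory=list)
    overlap_p: float | None = None
    n_celldeath: int | None = None
    wiring: pd.DataFrame | None = None
    components: list[list[str]] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "module_genes": self.module_genes,
            "p_cutoff": self.p_cutoff,
            "n_neighbors_tested": int(len(self.neighbor_table)),
            "n_regulators": len(self.regulators),
            "regulators": self.regulators,
            "n_celldeath": self.n_celldeath,
            "overlap_count": len(self.overlap_genes),
            "overlap_genes": self.overlap_genes,
            "overlap_p": self.overlap_p,
            "components": self.components,
        }


def find_regulators(
    module_genes,
    universe: InteractionUniverse,
    p_cutoff: float = 0.1,
) -> CrosstalkResult:
    """Test every direct neighbour of the module for link enrichment.

    For neighbour g: x = links into the module, n = g's degree in the
    combined graph, K = module size, N = universe size minus g itself.
    Results are invariant to edge-list ordering; a Benjamini-Hochberg
    column accompanies the raw p used for the cutoff.
    """
    adj = universe.adjacency
    module = sorted(set(module_genes) & set(adj))
    missing = set(module_genes) - set(adj)
    if missing:
        raise ValueError(f"module genes missing from the universe: {sorted(missing)}")
    module_set = set(module)
    K = len(module_set)
    N = universe.n_total() - 1

    rows = []
    neighbors = sorted(
        {n for g in module_set for n in adj[g]} - module_set
    )
    for g in neighbors:
        x = len(adj[g] & module_set)
        n = len(adj[g])
        rows.append(
            {
                "gene": g,
                "links_to_module": x,
                "degree": n,
                "p": hypergeometric_tail(x, K, n, N),
                "is_rna": g in universe.rna_nodes,
            }
        )
    table = pd.DataFrame(
        rows, columns=["gene", "links_to_module", "degree", "p", "is_rna"]
    )
    if len(table):
        order = np.argsort(table["p"].to_numpy(), kind="stable")
        m = len(table)
        bh = np.empty(m)
        ranked = table["p"].to_numpy()[order] * m / (np.arange(m) + 1)
        bh[order] = np.minimum.accumulate(ranked[::-1])[::-1]
        table["p_bh"] = np.minimum(bh, 1.0)
    else:
        table["p_bh"] = pd.Series(dtype=float)
    regulators = sorted(table.loc[table["p"] < p_cutoff, "gene"])
    return CrosstalkResult(
        module_genes=module,
        neighbor_table=table,
        regulators=regulators,
        p_cutoff=p_cutoff,
    )


def overlap_significance(set_a, set_b, n_universe: int) -> tuple[float, int]:
    """Hypergeometric upper-tail p for the overlap of two gene sets.

    Draws |A| genes from a universe of ``n_universe`` containing |B|
    successes; returns (p, overlap count).
    """
    a = set(set_a)
    b = set(set_b)
    if len(a) > n_universe or len(b) > n_universe:
        raise ValueError("set larger than the stated universe")
    x = len(a & b)
    p = hypergeometric_tail(x, len(b), len(a), n_universe)
    return p, x


def wiring_subnetwork(
    overlap_genes,
    module_genes,
    universe: InteractionUniverse,
) -> tuple[pd.DataFrame, list[list[str]]]:
    """Edges among overlap genes and from overlap genes into the module.

    Returns the wiring edge list (``source``, ``target``, ``edge_type``)
    and the connected components of the overlap-gene subgraph (how
    tightly the cell-death regulators cluster while pointing at the
    module).
    """
    adj = universe.adjacency
    overlap = sorted(set(overlap_genes) & set(adj))
    module_set = set(module_genes)
    rna = universe.rna_nodes

    rows = []
    seen = set()
    for g in overlap:
        for nbr in sorted(adj[g]):
            if nbr in module_set or nbr in overlap:
                key = tuple(sorted((g, nbr)))
                if key in seen:
                    continue
                seen.add(key)
                etype = "rna_protein" if (g in rna or nbr in rna) else "ppi"
                src, tgt = (g, nbr) if g in rna or nbr in module_set else (nbr, g)
                rows.append({"source": src, "target": tgt, "edge_type": etype})
    wiring = pd.DataFrame(rows, columns=["source", "target", "edge_type"])

    sub = nx.Graph()
    sub.add_nodes_from(overlap)
    for g in overlap:
        for nbr in adj[g]:
            if nbr in overlap and nbr != g:
                sub.add_edge(g, nbr)
    components = sorted(
        (sorted(c) for c in nx.connected_components(sub)),
        key=lambda c: (-len(c), c),
    )
    return wiring, components


def crosstalk_with_celldeath(
    module_genes,
    universe: InteractionUniverse,
    celldeath_genes,
    p_cutoff: float = 0.1,
) -> CrosstalkResult:
    """Full crosstalk stage: regulators, cell-death overlap, wiring."""
    result = find_regulators(module_genes, universe, p_cutoff)
    celldeath = sorted(set(celldeath_genes))
    p, _ = overlap_significance(result.regulators, celldeath, universe.n_total())
    overlap = sorted(set(result.regulators) & set(celldeath))
    wiring, components = wiring_subnetwork(overlap, result.module_genes, universe)
    result.overlap_genes = overlap
    result.overlap_p = p
    result.n_celldeath = len(celldeath)
    result.wiring = wiring
    result.components = components
    return result
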