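"""Maximal-scoring connected module search with permutation calibration.

A module M with n genes and m induced interactions scores

    S_M = (sum_i w_i + sum_e w_e) / sqrt(n + m),

the joint node/edge weight sum normalised by the square root of the
number of contributing terms, so that under the null (all weights
standard normal in magnitude) the score does not grow mechanically with
module size.  Finding the maximal-scoring connected subgraph is NP-hard;
the search is simulated annealing over connected states with
add-neighbour / remove-non-articulation-node moves, restarted from
random edges.  Scores are calibrated against random gene sets of the
same size (mean/SD standardisation plus an add-one empirical p).
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field, replace

import numpy as np

from survmod.network import WeightedNetwork


@dataclass(frozen=True)
class AnnealConfig:
    """Simulated-annealing schedule: geometric cooling T_start -> T_end
    over ``n_iterations`` proposals, repeated for ``n_restarts`` chains."""

    T_start: float = 1.0
    T_end: float = 0.01
    n_iterations: int = 10_000
    max_module_size: int = 20
    n_restarts: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.T_start > self.T_end > 0:
            raise ValueError("need T_start > T_end > 0")
        if self.n_iterations < 1:
            raise ValueError("n_iterations must be >= 1")
        if self.max_module_size < 2:
            raise ValueError("max_module_size must be >= 2")


@dataclass(frozen=True)
class CandidateModule:
    """A connected gene set with raw and permutation-calibrated scores."""

    genes: tuple[str, ...]
    raw_score: float
    n_edges: int
    null_mean: float | None = None
    null_sd: float | None = None
    adjusted_score: float | None = None
    empirical_p: float | None = None

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    def to_dict(self) -> dict:
        return {
            "genes": list(self.genes),
            "n_genes": self.n_genes,
            "n_edges": self.n_edges,
            "raw_score": self.raw_score,
            "null_mean": self.null_mean,
            "null_sd": self.null_sd,
            "adjusted_score": self.adjusted_score,
            "empirical_p": self.empirical_p,
        }


def _induced_edge_stats(genes: set[str], adj: dict) -> tuple[float, int]:
    total = 0.0
    count = 0
    for g in genes:
        for nbr, w in adj[g].items():
            if nbr in genes:
                total += w
                count += 1
    return total / 2.0, count // 2


def _is_connected(genes: set[str], adj: dict) -> bool:
    start = next(iter(genes))
    seen = {start}
    stack = [start]
    while stack:
        for nbr in adj[stack.pop()]:
            if nbr in genes and nbr not in seen:
                seen.add(nbr)
                stack.append(nbr)
    return len(seen) == len(genes)


def module_score(genes, network: WeightedNetwork) -> float:
    """S_M for a connected gene set of size >= 2 (see module docstring)."""
    gene_set = set(genes)
    if len(gene_set) < 2:
        raise ValueError("a module needs at least 2 genes")
    unknown = gene_set - set(network.node_weights.index)
    if unknown:
        raise ValueError(f"genes not in network: {sorted(unknown)}")
    adj = network.adjacency
    if not _is_connected(gene_set, adj):
        raise ValueError("gene set does not induce a connected subgraph")
    node_sum = float(network.node_weights.loc[sorted(gene_set)].sum())
    edge_sum, n_edges = _induced_edge_stats(gene_set, adj)
    return (node_sum + edge_sum) / math.sqrt(len(gene_set) + n_edges)


def _make_candidate(genes: set[str], network: WeightedNetwork) -> CandidateModule:
    adj = network.adjacency
    node_sum = float(network.node_weights.loc[sorted(genes)].sum())
    edge_sum, n_edges = _induced_edge_stats(genes, adj)
    score = (node_sum + edge_sum) / math.sqrt(len(genes) + n_edges)
    return CandidateModule(genes=tuple(sorted(genes)), raw_score=score, n_edges=n_edges)


# ---------------------------------------------------------------------------
# simulated annealing
# ---------------------------------------------------------------------------

def _keeps_connected(genes: set[str], remove: str, adj: dict) -> bool:
    remaining = genes - {remove}
    if not remaining:
        return False
    return _is_connected(remaining, adj)


def _anneal_once(
    nodes: list[str],
    node_w: dict[str, float],
    adj: dict,
    cfg: AnnealConfig,
    rng: np.random.Generator,
) -> tuple[set[str], float] | None:
    """One annealing chain; returns (best gene set, best score)."""
    # seed state: a random edge
    with_edges = [g for g in nodes if adj[g]]
    if not with_edges:
        return None
    start = with_edges[int(rng.integers(len(with_edges)))]
    nbr_list = list(adj[start])
    state = {start, nbr_list[int(rng.integers(len(nbr_list)))]}

    node_sum = sum(node_w[g] for g in state)
    edge_sum, m = _induced_edge_stats(state, adj)
    score = (node_sum + edge_sum) / math.sqrt(len(state) + m)
    best_state, best_score = set(state), score

    cool = (cfg.T_end / cfg.T_start) ** (1.0 / max(1, cfg.n_iterations - 1))
    temp = cfg.T_start
    unif = rng.random(cfg.n_iterations)
    moves = rng.random(cfg.n_iterations)

    for it in range(cfg.n_iterations):
        n = len(state)
        grow = moves[it] < 0.5
        if grow and n >= cfg.max_module_size:
            grow = False
        if not grow and n <= 2:
            grow = True

        if grow:
            frontier = {
                nbr for g in state for nbr in adj[g] if nbr not in state
            }
            if not frontier:
                temp *= cool
                continue
            cand = sorted(frontier)[int(rng.integers(len(frontier)))]
            d_node = node_w[cand]
            d_edge = sum(w for nbr, w in adj[cand].items() if nbr in state)
            d_m = sum(1 for nbr in adj[cand] if nbr in state)
            new_score = (node_sum + d_node + edge_sum + d_edge) / math.sqrt(
                n + 1 + m + d_m
            )
        else:
            members = sorted(state)
            cand = members[int(rng.integers(n))]
            if not _keeps_connected(state, cand, adj):
                temp *= cool
                continue
            d_node = -node_w[cand]
            d_edge = -sum(w for nbr, w in adj[cand].items() if nbr in state)
            d_m = -sum(1 for nbr in adj[cand] if nbr in state)
            new_score = (node_sum + d_node + edge_sum + d_edge) / math.sqrt(
                n - 1 + m + d_m
            )

        delta = new_score - score
        if delta >= 0 or unif[it] < math.exp(delta / temp):
            if grow:
                state.add(cand)
                node_sum += d_node
                edge_sum += d_edge
                m += d_m
            else:
                state.discard(cand)
                node_sum += d_node
                edge_sum += d_edge
                m += d_m
            score = new_score
            if score > best_score:
                best_score = score
                best_state = set(state)
        temp *= cool
    return best_state, best_score


def simulated_annealing_search(
    network: WeightedNetwork, config: AnnealConfig | None = None
) -> list[CandidateModule]:
    """Anneal ``n_restarts`` chains and return each chain's best module.

    Deterministic under a fixed ``config.seed``; duplicate best states
    across restarts are collapsed.  Returns raw-scored candidates sorted
    by descending score.
    """
    cfg = config or AnnealConfig()
    node_w = network.node_weights.to_dict()
    adj = network.adjacency
    nodes = network.genes
    results: dict[tuple[str, ...], CandidateModule] = {}
    root = np.random.SeedSequence(cfg.seed)
    for ss in root.spawn(cfg.n_restarts):
        out = _anneal_once(nodes, node_w, adj, cfg, np.random.default_rng(ss))
        if out is None:
            continue
        state, _ = out
        cand = _make_candidate(state, network)
        results.setdefault(cand.genes, cand)
    return sorted(results.values(), key=lambda c: (-c.raw_score, c.genes))


# ---------------------------------------------------------------------------
# exhaustive oracle for small networks
# ---------------------------------------------------------------------------

def exhaustive_max_module(
    network: WeightedNetwork, max_size: int, _node_limit: int = 15
) -> CandidateModule:
    """True maximum of the module score by enumerating every connected
    subset of 2..max_size genes.  Guarded to tiny networks (<= 15 nodes);
    use simulated annealing beyond that."""
    from itertools import combinations

    nodes = network.genes
    if len(nodes) > _node_limit:
        raise ValueError(
            f"{len(nodes)} nodes is too many for exhaustive enumeration "
            f"(limit {_node_limit}); use simulated_annealing_search"
        )
    adj = network.adjacency
    best: CandidateModule | None = None
    for size in range(2, min(max_size, len(nodes)) + 1):
        for combo in combinations(nodes, size):
            gene_set = set(combo)
            if not _is_connected(gene_set, adj):
                continue
            cand = _make_candidate(gene_set, network)
            if best is None or cand.raw_score > best.raw_score:
                best = cand
    if best is None:
        raise ValueError("network has no connected gene pair")
    return best


# ---------------------------------------------------------------------------
# permutation calibration
# ---------------------------------------------------------------------------

def null_score_distribution(
    network: WeightedNetwork,
    size: int,
    n_perm: int,
    rng: np.random.Generator,
    connected: bool = False,
) -> np.ndarray:
    """Scores of ``n_perm`` random gene sets of the given size.

    Null sets are arbitrary node sets scored with their induced edges and
    no connectivity requirement (the size-matched resampling null); pass
    ``connected=True`` to grow random connected sets instead for
    sensitivity analysis.
    """
    n_nodes = network.n_nodes()
    if size > n_nodes:
        raise ValueError("null set size exceeds network size")
    w = network.node_weights.to_numpy(float)
    csr, _ = network.edge_weight_csr()
    scores = np.empty(n_perm)
    if connected:
        genes = network.genes
        adj = network.adjacency
        index = {g: i for i, g in enumerate(genes)}
        for k in range(n_perm):
            state = _random_connected_set(genes, adj, size, rng)
            idx = np.fromiter((index[g] for g in state), int)
            sub = csr[idx][:, idx]
            m = sub.nnz // 2
            scores[k] = (w[idx].sum() + sub.sum() / 2.0) / math.sqrt(len(idx) + m)
        return scores
    picks = np.empty((n_perm, size), dtype=int)
    for k in range(n_perm):
        picks[k] = rng.choice(n_nodes, size=size, replace=False)
    node_part = w[picks].sum(axis=1)
    for k in range(n_perm):
        sub = csr[picks[k]][:, picks[k]]
        m = sub.nnz // 2
        scores[k] = (node_part[k] + sub.sum() / 2.0) / math.sqrt(size + m)
    return scores


def _random_connected_set(genes, adj, size, rng) -> set[str]:
    with_edges = [g for g in genes if adj[g]]
    for _ in range(100):
        state = {with_edges[int(rng.integers(len(with_edges)))]}
        while len(state) < size:
            frontier = sorted({n for g in state for n in adj[g] if n not in state})
            if not frontier:
                break
            state.add(frontier[int(rng.integers(len(frontier)))])
        if len(state) == size:
            return state
    raise ValueError(f"could not grow a connected set of size {size}")


def permutation_adjust(
    module: CandidateModule,
    network: WeightedNetwork,
    n_perm: int = 10_000,
    seed: int | None = None,
    null_scores: np.ndarray | None = None,
) -> CandidateModule:
    """Standardise a module's score against size-matched random gene sets.

    adjusted = (S - mean_null) / sd_null, and the empirical p uses the
    add-one rule (1 + #{null >= S}) / (n_perm + 1) so it is never zero.
    A precomputed ``null_scores`` array (e.g. shared across same-size
    modules) short-circuits the resampling.
    """
    if null_scores is None:
        if n_perm < 100:
            raise ValueError("n_perm must be >= 100")
        rng = np.random.default_rng(seed)
        null_scores = null_score_distribution(network, module.n_genes, n_perm, rng)
    mu = float(null_scores.mean())
    sd = float(null_scores.std(ddof=1))
    if sd <= 0:
        raise ValueError("degenerate null: zero score variance")
    emp_p = (1.0 + float((null_scores >= module.raw_score).sum())) / (len(null_scores) + 1.0)
    return replace(
        module,
        null_mean=mu,
        null_sd=sd,
        adjusted_score=(module.raw_score - mu) / sd,
        empirical_p=emp_p,
    )


def adjust_modules(
    modules: list[CandidateModule],
    network: WeightedNetwork,
    n_perm: int = 10_000,
    seed: int | None = None,
) -> list[CandidateModule]:
    """Permutation-adjust many modules, sharing one null per module size."""
    rng = np.random.default_rng(seed)
    nulls: dict[int, np.ndarray] = {}
    out = []
    for mod in modules:
        if mod.n_genes not in nulls:
            nulls[mod.n_genes] = null_score_distribution(
                network, mod.n_genes, n_perm, rng
            )
        out.append(permutation_adjust(mod, network, null_scores=nulls[mod.n_genes]))
    return out


# ---------------------------------------------------------------------------
# merging and selection
# ---------------------------------------------------------------------------

def merge_modules(
    modules: list[CandidateModule],
    network: WeightedNetwork,
    overlap_threshold: float = 0.8,
) -> list[CandidateModule]:
    """Concurrently merge modules overlapping by more than the threshold.

    Overlap is |A intersect B| / min(|A|, |B|).  All pairs above the
    threshold are linked in a meta-graph whose connected components are
    unioned in a single pass (concurrent rather than sequential merging),
    then rescored; calibration fields are reset.
    """
    if not 0 < overlap_threshold <= 1:
        raise ValueError("overlap_threshold must lie in (0, 1]")
    if not modules:
        return []
    sets = [set(m.genes) for m in modules]
    parent = list(range(len(sets)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(sets)):
        for j in range(i + 1, len(sets)):
            inter = len(sets[i] & sets[j])
            if inter and inter / min(len(sets[i]), len(sets[j])) > overlap_threshold:
                parent[find(i)] = find(j)

    groups: dict[int, set[str]] = {}
    for i, s in enumerate(sets):
        groups.setdefault(find(i), set()).update(s)
    merged = [_make_candidate(g, network) for g in groups.values()]
    return sorted(merged, key=lambda c: (-c.raw_score, c.genes))


def select_candidates(
    modules: list[CandidateModule],
    top_fraction: float = 0.01,
    p_cutoff: float = 0.01,
) -> tuple[list[CandidateModule], float | None]:
    """Keep modules in the top score fraction with empirical p below cutoff.

    Modules are ranked by adjusted score (ties broken lexicographically on
    the gene set); the top ``ceil(top_fraction * len)`` survive the rank
    filter, then the p filter applies.  Returns the selected modules and
    the realised adjusted-score threshold (the lowest adjusted score that
    passed the rank filter), or ``None`` for empty input.
    """
    if not modules:
        return [], None
    if any(m.adjusted_score is None or m.empirical_p is None for m in modules):
        raise ValueError("modules must be permutation-adjusted before selection")
    ranked = sorted(modules, key=lambda m: (-m.adjusted_score, m.genes))
    k = max(1, math.ceil(top_fraction * len(ranked)))
    top = ranked[:k]
    threshold = top[-1].adjusted_score
    selected = [m for m in top if m.empirical_p < p_cutoff]
    return selected, float(threshold)
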