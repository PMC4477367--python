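"""Node- and edge-weighted interaction network construction.

Nodes (genes) are weighted by their survival association: the Wald
p-value p_i of a univariable Cox proportional-hazards fit is mapped
through the inverse standard-normal CDF, w_i = Phi^-1(1 - p_i), so that
under the null w_i ~ N(0,1) and smaller p means larger weight.

Edges (interactions) are weighted by differential co-expression between
longer- and shorter-survival patient strata: Pearson correlations r_L,
r_S are Fisher-Z transformed and contrasted,

    w_e = |z_L - z_S| / sqrt(1/(n_L - 3) + 1/(n_S - 3)),

which is |N(0,1)| under the null of equal correlations.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import norm

log = logging.getLogger(__name__)

_P_EPS = 1e-16
CENSORED_POLICIES = ("exclude", "shorter", "longer")


# ---------------------------------------------------------------------------
# strata
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StrataSplit:
    """Longer-/shorter-survival patient strata at a month threshold."""

    longer: tuple[str, ...]
    shorter: tuple[str, ...]
    threshold: float

    @property
    def n_longer(self) -> int:
        return len(self.longer)

    @property
    def n_shorter(self) -> int:
        return len(self.shorter)


def stratify_patients(cohort, threshold: float = 37.0, censored_policy: str = "exclude") -> StrataSplit:
    """Split patients at ``threshold`` months of overall survival.

    Patients surviving at least ``threshold`` months (event or censored)
    go to the longer stratum; deceased patients below it to the shorter
    stratum.  Censored patients with follow-up below the threshold are
    ambiguous and handled per ``censored_policy``: ``exclude`` (default),
    ``shorter`` or ``longer``.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if censored_policy not in CENSORED_POLICIES:
        raise ValueError(f"censored_policy must be one of {CENSORED_POLICIES}")
    t = cohort.os_months
    e = cohort.event
    longer = list(t.index[t >= threshold])
    shorter = list(t.index[(t < threshold) & (e == 1)])
    ambiguous = list(t.index[(t < threshold) & (e == 0)])
    if censored_policy == "shorter":
        shorter += ambiguous
    elif censored_policy == "longer":
        longer += ambiguous
    if len(longer) < 4 or len(shorter) < 4:
        raise ValueError(
            f"stratum too small for Fisher-Z (longer={len(longer)}, "
            f"shorter={len(shorter)}; need >= 4 each)"
        )
    return StrataSplit(tuple(longer), tuple(shorter), float(threshold))


# ---------------------------------------------------------------------------
# univariate Cox (vectorized Newton on the partial likelihood, Breslow ties)
# ---------------------------------------------------------------------------

def _cox_newton(x: np.ndarray, order: np.ndarray, block_start: np.ndarray,
                event_sorted: np.ndarray, max_iter: int = 50, tol: float = 1e-10):
    """Newton-Raphson for one-covariate Cox fits, vectorized over columns.

    ``x`` is (n_patients, n_genes); ``order`` sorts patients by ascending
    time; ``block_start[i]`` maps sorted position i to the first position
    sharing its time, so risk-set sums respect ties (Breslow).
    Returns (beta, se) arrays of length n_genes.
    """
    xs = x[order]
    n, g = xs.shape
    ev = event_sorted[:, None].astype(float)
    beta = np.zeros(g)
    for _ in range(max_iter):
        eta = xs * beta
        # guard against overflow in degenerate fits
        w = np.exp(np.clip(eta, -500, 500))
        s0 = np.cumsum(w[::-1], axis=0)[::-1][block_start]
        s1 = np.cumsum((w * xs)[::-1], axis=0)[::-1][block_start]
        s2 = np.cumsum((w * xs * xs)[::-1], axis=0)[::-1][block_start]
        mu = s1 / s0
        grad = np.sum(ev * (xs - mu), axis=0)
        info = np.sum(ev * (s2 / s0 - mu * mu), axis=0)
        info = np.maximum(info, 1e-12)
        step = grad / info
        step = np.clip(step, -5.0, 5.0)
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    se = 1.0 / np.sqrt(info)
    return beta, se


def cox_univariate(
    expression: pd.DataFrame, os_time: pd.Series, event: pd.Series
) -> pd.DataFrame:
    """Per-gene univariable Cox fits for a genes x patients matrix.

    Returns a frame indexed by gene with columns ``coef``, ``se``, ``z``,
    ``p``.  Genes with (near-)constant expression are returned with NaN
    statistics and a logged warning; callers drop them.
    """
    if int(event.sum()) < 2:
        raise ValueError("need at least 2 events for Cox regression")
    patients = list(expression.columns)
    t = os_time.loc[patients].to_numpy(float)
    e = event.loc[patients].to_numpy(int)
    x = expression.to_numpy(float).T  # patients x genes

    sd = x.std(axis=0)
    ok = sd > 1e-12
    if not ok.all():
        log.warning("excluding %d constant-expression genes from Cox fits", int((~ok).sum()))

    order = np.argsort(t, kind="stable")
    ts = t[order]
    block_start = np.searchsorted(ts, ts, side="left")
    beta = np.full(x.shape[1], np.nan)
    se = np.full(x.shape[1], np.nan)
    if ok.any():
        b, s = _cox_newton(x[:, ok], order, block_start, e[order])
        beta[ok] = b
        se[ok] = s
    z = beta / se
    p = 2 * norm.sf(np.abs(z))
    return pd.DataFrame(
        {"coef": beta, "se": se, "z": z, "p": p}, index=expression.index
    )


def cox_univariate_pvalue(
    gene_expression: pd.Series | np.ndarray,
    os_time: pd.Series | np.ndarray,
    event: pd.Series | np.ndarray,
) -> tuple[float, int]:
    """Wald two-sided p and coefficient sign for a single covariate."""
    x = np.asarray(gene_expression, float)
    t = pd.Series(np.asarray(os_time, float), index=range(len(x)))
    e = pd.Series(np.asarray(event, int), index=range(len(x)))
    if x.std() <= 1e-12:
        raise ValueError("expression is constant; Cox fit undefined")
    expr = pd.DataFrame([x], index=["g"], columns=range(len(x)))
    fit = cox_univariate(expr, t, e)
    p = float(fit.loc["g", "p"])
    sign = int(np.sign(fit.loc["g", "coef"]))
    return p, sign


# ---------------------------------------------------------------------------
# weight transforms
# ---------------------------------------------------------------------------

def node_weight(p: float | np.ndarray) -> float | np.ndarray:
    """w_i = Phi^-1(1 - p): standard normal under a uniform null, strictly
    decreasing in p.  p outside (0,1) is clamped to [eps, 1-eps]."""
    arr = np.asarray(p, float)
    if np.any(arr <= 0) or np.any(arr >= 1):
        log.warning("clamping Cox p-values to (0, 1) open interval")
    clamped = np.clip(arr, _P_EPS, 1 - _P_EPS)
    out = norm.ppf(1 - clamped)
    return float(out) if np.isscalar(p) else out


def pearson_r(x: np.ndarray, y: np.ndarray) -> float:
    """Sample Pearson correlation; 0 with a warning if either vector is constant."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if len(x) < 4:
        raise ValueError("need at least 4 observations per stratum")
    if x.std() <= 1e-12 or y.std() <= 1e-12:
        log.warning("constant vector in correlation; returning r=0")
        return 0.0
    return float(np.corrcoef(x, y)[0, 1])


def fisher_z(r: float | np.ndarray) -> float | np.ndarray:
    """Fisher's variance-stabilising transform z = atanh(r).

    |r| >= 1 is clamped to 1 - 1e-12 in magnitude (logged) so degenerate
    perfect correlations stay finite.
    """
    arr = np.asarray(r, float)
    if np.any(np.abs(arr) >= 1):
        log.warning("clamping |r| >= 1 before Fisher-Z")
    clamped = np.clip(arr, -1 + 1e-12, 1 - 1e-12)
    out = np.arctanh(clamped)
    return float(out) if np.isscalar(r) else out


def edge_weight(
    r_longer: float | np.ndarray,
    r_shorter: float | np.ndarray,
    n_longer: int,
    n_shorter: int,
    signed: bool = False,
) -> float | np.ndarray:
    """Differential co-expression statistic between the two strata.

    (z_L - z_S) / sqrt(1/(n_L-3) + 1/(n_S-3)); the absolute value is
    returned by default, making w_e a magnitude of co-expression change
    that is symmetric under swapping the strata.
    """
    if n_longer <= 3 or n_shorter <= 3:
        raise ValueError("both strata need more than 3 patients (Fisher variance 1/(n-3))")
    denom = np.sqrt(1.0 / (n_longer - 3) + 1.0 / (n_shorter - 3))
    stat = (fisher_z(r_longer) - fisher_z(r_shorter)) / denom
    out = stat if signed else np.abs(stat)
    return float(out) if np.isscalar(r_longer) and np.isscalar(r_shorter) else out


# ---------------------------------------------------------------------------
# interaction filtering
# ---------------------------------------------------------------------------

def filter_interactions(edges: pd.DataFrame, min_confidence: float = 0.90) -> pd.DataFrame:
    """Keep high-confidence interactions; drop self-loops and duplicate pairs.

    ``edges`` needs columns ``gene_a``, ``gene_b`` and ``confidence`` (the
    first three columns are used if names differ).  Duplicate unordered
    pairs keep their maximum confidence.
    """
    df = edges.copy()
    if not {"gene_a", "gene_b", "confidence"} <= set(df.columns):
        df = df.iloc[:, :3].set_axis(["gene_a", "gene_b", "confidence"], axis=1)
    if ((df["confidence"] < 0) | (df["confidence"] > 1)).any():
        raise ValueError("confidence scores must lie in [0, 1]")
    df = df[df["gene_a"] != df["gene_b"]]
    a = df[["gene_a", "gene_b"]].min(axis=1)
    b = df[["gene_a", "gene_b"]].max(axis=1)
    df = pd.DataFrame({"gene_a": a, "gene_b": b, "confidence": df["confidence"]})
    df = (
        df.groupby(["gene_a", "gene_b"], as_index=False)["confidence"].max()
    )
    kept = df[df["confidence"] >= min_confidence].reset_index(drop=True)
    if kept.empty:
        log.warning("no interactions pass confidence >= %s", min_confidence)
    return kept


# ---------------------------------------------------------------------------
# the weighted network
# ---------------------------------------------------------------------------

@dataclass
class WeightedNetwork:
    """Undirected simple graph with survival node weights and
    differential-co-expression edge weights."""

    node_weights: pd.Series  # gene -> w_i
    edges: pd.DataFrame  # gene_a, gene_b, weight, r_longer, r_shorter
    cox_p: pd.Series | None = None
    strata: StrataSplit | None = None
    _adjacency: dict | None = field(default=None, repr=False, compare=False)
    _index: dict | None = field(default=None, repr=False, compare=False)
    _csr: sparse.csr_matrix | None = field(default=None, repr=False, compare=False)

    @property
    def genes(self) -> list[str]:
        return list(self.node_weights.index)

    def n_nodes(self) -> int:
        return len(self.node_weights)

    def n_edges(self) -> int:
        return len(self.edges)

    @property
    def adjacency(self) -> dict[str, dict[str, float]]:
        """gene -> {neighbour: edge weight}; built lazily."""
        if self._adjacency is None:
            adj: dict[str, dict[str, float]] = {g: {} for g in self.genes}
            for a, b, w in zip(
                self.edges["gene_a"], self.edges["gene_b"], self.edges["weight"]
            ):
                adj[a][b] = float(w)
                adj[b][a] = float(w)
            self._adjacency = adj
        return self._adjacency

    def edge_weight_csr(self) -> tuple[sparse.csr_matrix, dict[str, int]]:
        """Sparse symmetric edge-weight matrix and gene -> row index map."""
        if self._csr is None:
            index = {g: i for i, g in enumerate(self.genes)}
            ia = self.edges["gene_a"].map(index).to_numpy()
            ib = self.edges["gene_b"].map(index).to_numpy()
            w = self.edges["weight"].to_numpy(float)
            n = self.n_nodes()
            mat = sparse.coo_matrix(
                (np.concatenate([w, w]), (np.concatenate([ia, ib]), np.concatenate([ib, ia]))),
                shape=(n, n),
            ).tocsr()
            self._csr = mat
            self._index = index
        return self._csr, self._index

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        nodes = pd.DataFrame({"gene": self.genes, "weight": self.node_weights.values})
        if self.cox_p is not None:
            nodes["cox_p"] = self.cox_p.loc[self.node_weights.index].values
        nodes.to_csv(outdir / "nodes.tsv", sep="\t", index=False)
        self.edges.to_csv(outdir / "edges_weighted.tsv", sep="\t", index=False)


def read_weighted_network(outdir: str | Path) -> WeightedNetwork:
    outdir = Path(outdir)
    nodes = pd.read_csv(outdir / "nodes.tsv", sep="\t")
    edges = pd.read_csv(outdir / "edges_weighted.tsv", sep="\t")
    weights = pd.Series(nodes["weight"].values, index=nodes["gene"])
    cox_p = pd.Series(nodes["cox_p"].values, index=nodes["gene"]) if "cox_p" in nodes else None
    return WeightedNetwork(node_weights=weights, edges=edges, cox_p=cox_p)


def _strata_correlations(
    expression: pd.DataFrame, pairs_a: np.ndarray, pairs_b: np.ndarray, patients: tuple[str, ...]
) -> np.ndarray:
    """Pearson r for each gene pair restricted to one patient stratum."""
    sub = expression.loc[:, list(patients)].to_numpy(float)
    centred = sub - sub.mean(axis=1, keepdims=True)
    norms = np.sqrt((centred**2).sum(axis=1))
    norms[norms <= 1e-12] = np.nan  # constant within stratum -> r undefined
    unit = centred / norms[:, None]
    r = np.einsum("ij,ij->i", unit[pairs_a], unit[pairs_b])
    return np.clip(r, -1.0, 1.0)


def build_weighted_network(
    cohort,
    edges: pd.DataFrame,
    threshold: float = 37.0,
    min_confidence: float = 0.90,
    censored_policy: str = "exclude",
    signed_edge_weights: bool = False,
) -> WeightedNetwork:
    """Compose filtering, stratification, per-gene Cox and per-edge
    differential co-expression into a :class:`WeightedNetwork`.

    Only genes present in both the expression matrix and the filtered
    interaction list become nodes; genes with undefined Cox fits are
    dropped.  Edge correlations use the supplied cohort only (weights are
    a property of the training data).
    """
    kept = filter_interactions(edges, min_confidence)
    genes = sorted(
        (set(kept["gene_a"]) | set(kept["gene_b"])) & set(cohort.genes)
    )
    if len(genes) < 2:
        raise ValueError("cohort and interaction list share fewer than 2 genes")
    kept = kept[kept["gene_a"].isin(genes) & kept["gene_b"].isin(genes)].reset_index(drop=True)

    strata = stratify_patients(cohort, threshold, censored_policy)
    expr = cohort.expression.loc[genes]

    fits = cox_univariate(expr, cohort.os_months, cohort.event)
    valid = fits["p"].notna()
    if not valid.all():
        log.warning("dropping %d genes with undefined Cox fits", int((~valid).sum()))
    genes = [g for g in genes if valid[g]]
    expr = expr.loc[genes]
    fits = fits.loc[genes]
    kept = kept[kept["gene_a"].isin(genes) & kept["gene_b"].isin(genes)].reset_index(drop=True)

    weights = pd.Series(node_weight(fits["p"].to_numpy()), index=fits.index)

    row = {g: i for i, g in enumerate(genes)}
    ia = kept["gene_a"].map(row).to_numpy()
    ib = kept["gene_b"].map(row).to_numpy()
    r_l = _strata_correlations(expr, ia, ib, strata.longer)
    r_s = _strata_correlations(expr, ia, ib, strata.shorter)
    undefined = np.isnan(r_l) | np.isnan(r_s)
    if undefined.any():
        log.warning(
            "%d edges involve a within-stratum constant gene; weight set to 0",
            int(undefined.sum()),
        )
    w = np.where(
        undefined,
        0.0,
        edge_weight(
            np.nan_to_num(r_l), np.nan_to_num(r_s),
            strata.n_longer, strata.n_shorter, signed=signed_edge_weights,
        ),
    )
    edge_table = pd.DataFrame(
        {
            "gene_a": kept["gene_a"],
            "gene_b": kept["gene_b"],
            "weight": w,
            "r_longer": np.nan_to_num(r_l),
            "r_shorter": np.nan_to_num(r_s),
        }
    )
    log.info(
        "weighted network: %d nodes, %d edges (strata %d longer / %d shorter)",
        len(genes), len(edge_table), strata.n_longer, strata.n_shorter,
    )
    return WeightedNetwork(
        node_weights=weights,
        edges=edge_table,
        cox_p=fits["p"],
        strata=strata,
    )
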