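"""Graph-theoretic metrics of windowed networks across a sparsity ladder.

Each windowed Fisher-Z matrix is binarised at every rung of a sparsity
ladder (default 0.10-0.40 in steps of 0.01, 31 rungs): the top
``floor(s * N(N-1)/2)`` edges by |Z| are kept, giving an undirected,
unweighted graph.  Six metrics are computed per rung — degree, nodal
efficiency, local efficiency, clustering coefficient, betweenness
centrality (nodal), and global efficiency — then aggregated over the ladder
by trapezoidal AUC (a threshold-free summary), and finally summarised per
subject by the *across-window sample variance* of each AUC series: the
temporal instability of network topology.

Conventions: unreachable node pairs contribute efficiency 0 (harmonic
convention); clustering is 0 for degree < 2; local efficiency of a node is
the global efficiency of the subgraph induced on its neighbours (0 with
fewer than 2 neighbours); betweenness counts all shortest paths with
multiplicity and is normalised by (N-1)(N-2)/2.
"""

from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import shortest_path
from statsmodels.stats.multitest import multipletests

from ._glm import encode_design, group_t

__all__ = [
    "SparsityLadder",
    "BinaryGraph",
    "binarize_by_sparsity",
    "graph_metrics",
    "auc_over_sparsity",
    "window_metrics_auc",
    "metric_variance",
    "variance_table",
    "compare_variance",
    "GLOBAL_METRICS",
    "NODAL_METRICS",
]

GLOBAL_METRICS = ("global_efficiency",)
NODAL_METRICS = (
    "degree",
    "nodal_efficiency",
    "local_efficiency",
    "clustering_coefficient",
    "betweenness",
)


@dataclasses.dataclass(frozen=True)
class SparsityLadder:
    """Sparsity grid for binarisation (defaults give 31 rungs, 0.10..0.40)."""

    s_min: float = 0.10
    s_max: float = 0.40
    s_step: float = 0.01

    def __post_init__(self):
        if not (0 < self.s_min < self.s_max < 1):
            raise ValueError("need 0 < s_min < s_max < 1")
        if self.s_step <= 0:
            raise ValueError("s_step must be positive")

    def values(self) -> np.ndarray:
        n = int(round((self.s_max - self.s_min) / self.s_step)) + 1
        return self.s_min + self.s_step * np.arange(n)


@dataclasses.dataclass(frozen=True)
class BinaryGraph:
    """Undirected, unweighted graph: symmetric 0/1 adjacency, zero diagonal."""

    adjacency: np.ndarray
    sparsity: float


def binarize_by_sparsity(z: np.ndarray, s: float, rank: str = "abs") -> BinaryGraph:
    """Keep the top ``floor(s * N(N-1)/2)`` edges of a symmetric matrix.

    ``rank="abs"`` orders edges by |Z| descending (strong negative coupling
    counts as connection strength); ``rank="positive"`` orders by signed Z so
    negative edges rank last.  Ties at the cut are broken by (row, col)
    lexicographic order for determinism.
    """
    z = np.asarray(z, dtype=float)
    n = z.shape[0]
    if z.shape != (n, n) or not np.allclose(z, z.T, atol=1e-10):
        raise ValueError("input must be a symmetric square matrix")
    iu = np.triu_indices(n, k=1)
    if rank == "abs":
        w = np.abs(z[iu])
    elif rank == "positive":
        w = z[iu].copy()
    else:
        raise ValueError("rank must be 'abs' or 'positive'")
    n_edges_max = w.size
    m = int(np.floor(s * n_edges_max))
    if m < 1:
        raise ValueError(f"sparsity {s} yields zero edges for N={n}")
    m = min(m, n_edges_max)
    order = np.lexsort((iu[1], iu[0], -w))  # primary: weight desc; ties: (row, col)
    keep = order[:m]
    adj = np.zeros((n, n), dtype=np.int8)
    adj[iu[0][keep], iu[1][keep]] = 1
    adj += adj.T
    return BinaryGraph(adjacency=adj, sparsity=m / n_edges_max)


def _efficiency_from_adj(adj: np.ndarray) -> tuple:
    """(nodal efficiency vector, pairwise 1/d matrix) via BFS distances."""
    n = adj.shape[0]
    d = shortest_path(csr_matrix(adj), method="D", unweighted=True)
    with np.errstate(divide="ignore"):
        inv = 1.0 / d
    inv[~np.isfinite(inv)] = 0.0
    np.fill_diagonal(inv, 0.0)
    nodal = inv.sum(axis=1) / (n - 1)
    return nodal, inv


def graph_metrics(g: BinaryGraph) -> dict:
    """All six metrics of one binary graph.

    Returns ``{"global_efficiency": float, <nodal name>: ndarray(N)}``.
    """
    adj = np.asarray(g.adjacency, dtype=np.int64)
    n = adj.shape[0]
    deg = adj.sum(axis=1)

    nodal_eff, _ = _efficiency_from_adj(adj)
    global_eff = float(nodal_eff.mean())

    tri = np.einsum("ij,jk,ki->i", adj, adj, adj) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        clus = np.where(deg >= 2, 2.0 * tri / (deg * (deg - 1)), 0.0)

    loc_eff = np.zeros(n)
    for i in range(n):
        nb = np.flatnonzero(adj[i])
        if nb.size < 2:
            continue
        sub_nodal, _ = _efficiency_from_adj(adj[np.ix_(nb, nb)])
        loc_eff[i] = sub_nodal.mean()

    graph = nx.from_numpy_array(adj)
    bet = nx.betweenness_centrality(graph, normalized=True)
    betweenness = np.array([bet[i] for i in range(n)])

    return {
        "global_efficiency": global_eff,
        "degree": deg.astype(float),
        "nodal_efficiency": nodal_eff,
        "local_efficiency": loc_eff,
        "clustering_coefficient": clus,
        "betweenness": betweenness,
    }


def auc_over_sparsity(values: np.ndarray, ladder: SparsityLadder) -> np.ndarray:
    """Trapezoidal integral over the sparsity grid (first axis = rungs)."""
    values = np.asarray(values, dtype=float)
    grid = ladder.values()
    if values.shape[0] != grid.size:
        raise ValueError(
            f"{values.shape[0]} values for {grid.size} ladder rungs"
        )
    return np.trapezoid(values, grid, axis=0)


def window_metrics_auc(
    z_stack: np.ndarray,
    ladder: SparsityLadder = SparsityLadder(),
    rank: str = "abs",
) -> dict:
    """Per-window AUC of every metric over the sparsity ladder.

    ``z_stack`` is (W, N, N).  Returns ``{"global_efficiency": (W,),
    <nodal>: (W, N)}``.
    """
    z_stack = np.asarray(z_stack)
    w, n, _ = z_stack.shape
    grid = ladder.values()
    out = {"global_efficiency": np.empty(w)}
    for name in NODAL_METRICS:
        out[name] = np.empty((w, n))
    for wi in range(w):
        per_rung = {"global_efficiency": np.empty(grid.size)}
        for name in NODAL_METRICS:
            per_rung[name] = np.empty((grid.size, n))
        for ri, s in enumerate(grid):
            m = graph_metrics(binarize_by_sparsity(z_stack[wi], s, rank=rank))
            for name, val in m.items():
                per_rung[name][ri] = val
        for name in per_rung:
            out[name][wi] = auc_over_sparsity(per_rung[name], ladder)
    return out


def metric_variance(auc_by_window: Mapping[str, np.ndarray]) -> dict:
    """Across-window sample variance (ddof=1) of each AUC series."""
    out = {}
    for name, vals in auc_by_window.items():
        vals = np.asarray(vals)
        if vals.shape[0] < 2:
            raise ValueError("variance needs at least 2 windows")
        out[name] = vals.var(axis=0, ddof=1)
    return out


def variance_table(
    variances_by_subject: Mapping[str, Mapping[str, np.ndarray]],
    region_labels: Sequence[str],
) -> pd.DataFrame:
    """Long-format table: subject_id, metric, node, variance.

    Global metrics use node = ``"global"``.
    """
    rows = []
    for sid, var in variances_by_subject.items():
        for name, vals in var.items():
            if name in GLOBAL_METRICS:
                rows.append(
                    {"subject_id": sid, "metric": name, "node": "global",
                     "variance": float(vals)}
                )
            else:
                for i, v in enumerate(np.asarray(vals)):
                    rows.append(
                        {"subject_id": sid, "metric": name,
                         "node": region_labels[i], "variance": float(v)}
                    )
    return pd.DataFrame(rows)


def compare_variance(
    table: pd.DataFrame,
    meta: pd.DataFrame,
    covariates: Sequence[str] = ("age", "sex", "education_years"),
    fdr_q: float = 0.05,
) -> pd.DataFrame:
    """Group contrast of across-window variance per node and metric.

    Same covariate-adjusted linear model as the temporal contrasts, applied
    per node; Benjamini-Hochberg correction across nodes *within each nodal
    metric family*; global metrics are tested without an FDR family (q = p).
    Returns columns metric, node, t, p, q, significant.
    """
    subjects = table["subject_id"].unique()
    sub_meta = meta[meta["subject_id"].isin(subjects)].reset_index(drop=True)
    if min((sub_meta["group"] == "patient").sum(),
           (sub_meta["group"] == "control").sum()) < 2:
        raise ValueError("need at least 2 subjects per group")
    x, _ = encode_design(sub_meta, covariates)
    order = sub_meta["subject_id"].tolist()

    results = []
    for metric, dfm in table.groupby("metric", sort=False):
        wide = dfm.pivot(index="subject_id", columns="node", values="variance")
        wide = wide.loc[order]
        y = wide.to_numpy(float)
        t, p, _ = group_t(x, y)
        nodes = list(wide.columns)
        if metric in GLOBAL_METRICS:
            q = p.copy()
        else:
            _, q, _, _ = multipletests(p, alpha=fdr_q, method="fdr_bh")
        for node, ti, pi, qi in zip(nodes, t, p, q):
            results.append(
                {"metric": metric, "node": node, "t": float(ti),
                 "p": float(pi), "q": float(qi), "significant": bool(qi < fdr_q)}
            )
    return pd.DataFrame(results)
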