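"""Correlation-weighted Markov clustering into functional modules.

Each edge of the DEG subnetwork is weighted by the absolute Pearson
correlation of its two genes' expression profiles; the Markov Cluster
algorithm (MCL) then simulates flow on the column-stochastic weight matrix,
alternating expansion (matrix power) and inflation (entrywise power followed
by column renormalization) until the flow concentrates into attractor-based
clusters. A high inflation coefficient (5.0 here by default) yields fine,
tightly connected modules. Surviving modules are those of at least
``min_size`` genes whose mean internal |r| is at least ``min_avg_corr``;
candidate genes are the hubs that fall inside the highest-correlation
module.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd

from .deg import ExpressionStudy

__all__ = [
    "MCLParams",
    "Module",
    "correlation_weights",
    "mcl_cluster",
    "module_avg_correlation",
    "filter_modules",
    "prioritize_candidates",
    "PrioritizationResult",
]


@dataclass(frozen=True)
class MCLParams:
    """Markov clustering parameters.

    inflation : entrywise power r (> 1); larger r gives finer clusters.
    expansion : matrix power e (>= 2).
    prune_threshold : flow entries below this are zeroed each iteration.
    tol : convergence tolerance on the max entrywise change.
    max_iter : iteration cap; non-convergence returns the current clustering
        with a warning.
    """

    inflation: float = 5.0
    expansion: int = 2
    prune_threshold: float = 1e-5
    tol: float = 1e-6
    max_iter: int = 200

    def __post_init__(self) -> None:
        if not self.inflation > 1:
            raise ValueError("inflation must exceed 1")
        if self.expansion < 2:
            raise ValueError("expansion power must be >= 2")
        if self.prune_threshold < 0:
            raise ValueError("prune_threshold must be >= 0")


@dataclass
class Module:
    module_id: int
    genes: tuple[str, ...]  # sorted
    avg_corr: float = float("nan")
    avg_corr_defined: bool = False

    @property
    def size(self) -> int:
        return len(self.genes)


def correlation_weights(
    graph: nx.Graph,
    expr: ExpressionStudy,
    condition: str = "tumor",
    min_samples: int = 3,
) -> nx.Graph:
    """Weight each edge by |Pearson r| of its endpoints' expression.

    Correlations are computed across the study's samples of the given
    condition (tumor by default). Edges whose endpoints are not both
    measured in at least ``min_samples`` selected samples, or whose profile
    is constant, get weight 0 and ``insufficient=True``.
    """
    cols = expr.samples(condition)
    sub = expr.values[cols]
    weighted = nx.Graph()
    weighted.add_nodes_from(graph.nodes)
    for u, v in graph.edges:
        w, flagged = 0.0, True
        if u in sub.index and v in sub.index and len(cols) >= min_samples:
            x = sub.loc[u].to_numpy(dtype=float)
            y = sub.loc[v].to_numpy(dtype=float)
            sx, sy = x.std(), y.std()
            if sx > 0 and sy > 0:
                r = float(np.corrcoef(x, y)[0, 1])
                w, flagged = abs(r), False
        weighted.add_edge(u, v, weight=w, insufficient=flagged)
    return weighted


def _mcl_matrix(m: np.ndarray, params: MCLParams) -> tuple[np.ndarray, bool]:
    """Iterate expansion/inflation on a column-stochastic matrix."""
    for _ in range(params.max_iter):
        prev = m
        m = np.linalg.matrix_power(m, params.expansion)
        m = np.power(m, params.inflation)
        m[m < params.prune_threshold] = 0.0
        colsum = m.sum(axis=0)
        # a fully pruned column would lose its node; keep its strongest entry
        dead = colsum == 0
        if dead.any():  # pragma: no cover - defensive
            idx = np.argmax(prev[:, dead], axis=0)
            m[idx, np.where(dead)[0]] = 1.0
            colsum = m.sum(axis=0)
        m = m / colsum
        if np.max(np.abs(m - prev)) < params.tol:
            return m, True
    return m, False


def mcl_cluster(graph: nx.Graph, params: MCLParams | None = None) -> list[Module]:
    """Run canonical MCL on a weighted graph; every node lands in exactly
    one cluster.

    Zero-weight edges are dropped. Each node receives a self-loop equal to
    its maximum incident edge weight (1 for isolated nodes) to damp parity
    effects. Clusters are read off the converged flow matrix through its
    attractors (nodes retaining flow on the diagonal): attractor systems
    that share a column's support are merged and every node joins the
    cluster of the attractor it sends the most flow to (ties broken by gene
    order). Modules are numbered by size descending, then by smallest
    member.
    """
    if graph.number_of_nodes() == 0:
        raise ValueError("empty graph")
    params = params or MCLParams()

    nodes = sorted(graph.nodes)
    index = {g: i for i, g in enumerate(nodes)}
    n = len(nodes)
    a = np.zeros((n, n))
    for u, v, data in graph.edges(data=True):
        w = float(data.get("weight", 1.0))
        if w > 0 and u != v:
            a[index[u], index[v]] = a[index[v], index[u]] = w
    max_w = a.max(axis=0)
    np.fill_diagonal(a, np.where(max_w > 0, max_w, 1.0))
    m = a / a.sum(axis=0)

    m, converged = _mcl_matrix(m, params)
    if not converged:
        warnings.warn("MCL did not converge within max_iter; clustering current flow")

    thr = max(params.prune_threshold, 1e-9)
    attractors = [i for i in range(n) if m[i, i] > thr]
    if not attractors:  # pragma: no cover - defensive
        attractors = list(range(n))

    parent = list(range(n))

    def find(x: int) -> int:
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    def union(x: int, y: int) -> None:
        parent[find(x)] = find(y)

    attractor_set = set(attractors)
    col_attr = []
    for j in range(n):
        support = [i for i in np.nonzero(m[:, j] > thr)[0] if i in attractor_set]
        col_attr.append(support)
        for i in support[1:]:
            union(support[0], i)

    clusters: dict[int, set[int]] = {}
    for j in range(n):
        support = col_attr[j]
        if not support:
            clusters.setdefault(j, set()).add(j)
            continue
        flows = m[support, j]
        best = support[int(np.argmax(flows))]  # argmax is first max: gene order
        clusters.setdefault(find(best), set()).add(j)
    for i in attractors:
        clusters.setdefault(find(i), set()).add(i)

    gene_sets = sorted(
        (tuple(sorted(nodes[i] for i in members)) for members in clusters.values()),
        key=lambda gs: (-len(gs), gs[0]),
    )
    return [Module(module_id=mid, genes=gs) for mid, gs in enumerate(gene_sets)]


def module_avg_correlation(module: Module, weighted_graph: nx.Graph) -> Module:
    """Mean |r| over the module's internal network edges.

    Singleton or edgeless modules get 0 with ``avg_corr_defined=False``.
    """
    genes = set(module.genes)
    weights = [
        float(d.get("weight", 0.0))
        for u, v, d in weighted_graph.edges(data=True)
        if u in genes and v in genes
    ]
    if weights:
        return Module(module.module_id, module.genes, float(np.mean(weights)), True)
    return Module(module.module_id, module.genes, 0.0, False)


def filter_modules(
    modules: list[Module], min_size: int = 3, min_avg_corr: float = 0.25
) -> list[Module]:
    """Keep modules with size >= ``min_size`` and mean internal |r| >=
    ``min_avg_corr`` (both inclusive); survivors are renumbered by size
    descending then smallest member."""
    keep = [m for m in modules if m.size >= min_size and m.avg_corr >= min_avg_corr]
    keep.sort(key=lambda m: (-m.size, m.genes[0]))
    return [Module(i, m.genes, m.avg_corr, m.avg_corr_defined) for i, m in enumerate(keep)]


@dataclass
class PrioritizationResult:
    candidates: tuple[str, ...]
    selected_module: Module
    per_module: pd.DataFrame  # module_id, size, avg_corr, n_hub_overlap, overlap


def prioritize_candidates(hubs, modules: list[Module]) -> PrioritizationResult:
    """Candidate genes = hubs intersected with the top module.

    The selected module is the one with maximal average correlation (ties:
    larger module, then lowest id); per-module hub overlaps are reported
    alongside.
    """
    if not modules:
        raise ValueError("no modules to prioritize against")
    hubs = set(hubs)
    rows = []
    for m in modules:
        overlap = tuple(sorted(hubs & set(m.genes)))
        rows.append((m.module_id, m.size, m.avg_corr, len(overlap), ",".join(overlap)))
    per_module = pd.DataFrame(
        rows, columns=["module_id", "size", "avg_corr", "n_hub_overlap", "overlap"]
    )
    selected = max(modules, key=lambda m: (m.avg_corr, m.size, -m.module_id))
    return PrioritizationResult(
        candidates=tuple(sorted(hubs & set(selected.genes))),
        selected_module=selected,
        per_module=per_module,
    )
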