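"""Eight node-centrality measures and the all-above-median consensus rule.

Core nodes of a network are defined by consensus over eight centrality
measures: degree, betweenness, closeness, eigenvector, local average
connectivity (LAC), network centrality (sum of edge clustering
coefficients), subgraph centrality and Stephenson-Zelen information
centrality.  A node is *core* when its value on every measure strictly
exceeds that measure's median across all nodes of the graph.

Definitions used here:

* betweenness is unnormalised Brandes betweenness with endpoints
  excluded;
* closeness is computed within a node's connected component as
  ``(n_c - 1) / sum of distances``;
* eigenvector centrality is the non-negative, L2-normalised principal
  eigenvector of the adjacency matrix;
* LAC(v) is the mean degree of v's neighbours inside the subgraph
  induced by those neighbours;
* the edge clustering coefficient of (v, w) is the number of triangles
  through the edge divided by ``min(deg v - 1, deg w - 1)`` (zero when
  the denominator vanishes); network centrality sums it over v's edges;
* subgraph centrality is the diagonal of the adjacency-matrix
  exponential;
* information centrality inverts ``(D - A + J)`` per connected
  component (Stephenson-Zelen), so it is finite on disconnected graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

__all__ = [
    "MEASURES",
    "CentralityProfile",
    "compute_centralities",
    "select_core",
    "select_core_ingredients",
    "profiles_frame",
]

MEASURES = (
    "degree",
    "betweenness",
    "closeness",
    "eigenvector",
    "lac",
    "network_c",
    "subgraph",
    "information",
)

#: node count above which the eigenvector switches to power iteration
_DENSE_EIG_LIMIT = 2000


@dataclass
class CentralityProfile:
    """The eight centrality values of one node."""

    node: object
    degree: float
    betweenness: float
    closeness: float
    eigenvector: float
    lac: float
    network_c: float
    subgraph: float
    information: float

    def values(self) -> np.ndarray:
        return np.array([getattr(self, m) for m in MEASURES], dtype=float)


def _check_simple_undirected(graph: nx.Graph) -> None:
    if graph.is_directed():
        raise ValueError("centralities are defined on undirected graphs")
    if graph.is_multigraph():
        raise ValueError("multigraphs are not supported; collapse parallel edges first")
    if graph.number_of_nodes() < 2:
        raise ValueError("need at least 2 nodes")
    if any(graph.has_edge(v, v) for v in graph):
        raise ValueError("self-loops are not supported")


def _eigenvector(graph: nx.Graph, nodes: Sequence) -> dict:
    """Principal-eigenvector centrality, L2-normalised and non-negative.

    Defined as the limit of power iteration on ``A + I`` started from the
    uniform vector (the shift breaks the symmetric spectrum of bipartite
    graphs; the uniform start fixes the vector when the top eigenvalue is
    degenerate, e.g. on graphs with spectrally tied components).  Below
    ``_DENSE_EIG_LIMIT`` nodes that limit is computed exactly as the
    projection of the ones vector onto the top eigenspace.
    """
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    n = len(nodes)
    ones = np.ones(n)
    if n <= _DENSE_EIG_LIMIT:
        eigvals, eigvecs = np.linalg.eigh(adj)
        lmax = eigvals[-1]
        top = eigvecs[:, eigvals > lmax - 1e-9 * max(1.0, abs(lmax))]
        vec = top @ (top.T @ ones)
        if np.linalg.norm(vec) < 1e-12:  # ones orthogonal to the eigenspace
            vec = eigvecs[:, -1]
    else:
        shifted_diag = 1.0
        vec = ones / np.linalg.norm(ones)
        for _ in range(100_000):
            nxt = adj @ vec + shifted_diag * vec
            norm = np.linalg.norm(nxt)
            if norm == 0:
                break
            nxt /= norm
            if np.linalg.norm(nxt - vec) < 1e-12:
                vec = nxt
                break
            vec = nxt
    if vec.sum() < 0:
        vec = -vec
    # Perron vector of a non-negative matrix: clip the numerical noise
    # below zero.
    vec = np.clip(vec, 0.0, None)
    norm = np.linalg.norm(vec)
    if norm > 0:
        vec = vec / norm
    return dict(zip(nodes, vec))


def _lac(graph: nx.Graph) -> dict:
    out = {}
    for v in graph:
        nbrs = list(graph[v])
        if len(nbrs) < 1:
            out[v] = 0.0
            continue
        nbr_set = set(nbrs)
        degsum = sum(
            sum(1 for u in graph[w] if u in nbr_set)
            for w in nbrs
        )
        out[v] = degsum / len(nbrs)
    return out


def _network_centrality(graph: nx.Graph) -> dict:
    deg = dict(graph.degree())
    out = {v: 0.0 for v in graph}
    for v, w in graph.edges():
        denom = min(deg[v] - 1, deg[w] - 1)
        if denom <= 0:
            continue
        tri = len(set(graph[v]) & set(graph[w]))
        ecc = tri / denom
        out[v] += ecc
        out[w] += ecc
    return out


def _subgraph_centrality(graph: nx.Graph, nodes: Sequence) -> dict:
    adj = nx.to_numpy_array(graph, nodelist=nodes)
    eigvals, eigvecs = np.linalg.eigh(adj)
    diag = (eigvecs ** 2) @ np.exp(eigvals)
    return dict(zip(nodes, diag))


def _information_centrality(graph: nx.Graph) -> dict:
    out = {}
    for comp in nx.connected_components(graph):
        comp = sorted(comp, key=str)
        n = len(comp)
        if n == 1:
            out[comp[0]] = 0.0
            continue
        adj = nx.to_numpy_array(graph, nodelist=comp)
        lap = np.diag(adj.sum(axis=1)) - adj
        cmat = np.linalg.inv(lap + np.ones((n, n)))
        trace = np.trace(cmat)
        rowsum = cmat.sum(axis=1)
        info = 1.0 / (np.diag(cmat) + (trace - 2.0 * rowsum) / n)
        out.update(zip(comp, info))
    return out


def compute_centralities(graph: nx.Graph) -> list[CentralityProfile]:
    """Compute all eight centrality measures for every node.

    Raises ``ValueError`` on directed graphs, multigraphs, self-loops or
    graphs with fewer than two nodes.  On disconnected graphs closeness
    and information centrality are computed per component and the
    eigenvector concentrates on the spectrally dominant component.
    """
    _check_simple_undirected(graph)
    nodes = list(graph.nodes())
    degree = dict(graph.degree())
    betweenness = nx.betweenness_centrality(graph, normalized=False)
    closeness = nx.closeness_centrality(graph, wf_improved=False)
    eigen = _eigenvector(graph, nodes)
    lac = _lac(graph)
    netc = _network_centrality(graph)
    subg = _subgraph_centrality(graph, nodes)
    info = _information_centrality(graph)
    return [
        CentralityProfile(
            node=v,
            degree=float(degree[v]),
            betweenness=float(betweenness[v]),
            closeness=float(closeness[v]),
            eigenvector=float(eigen[v]),
            lac=float(lac[v]),
            network_c=float(netc[v]),
            subgraph=float(subg[v]),
            information=float(info[v]),
        )
        for v in nodes
    ]


def select_core(profiles: Iterable[CentralityProfile], rule: str = "strict",
                measures: Sequence[str] = MEASURES) -> tuple[list, dict]:
    """Consensus core selection: above-the-median on every measure.

    ``rule='strict'`` requires each value to strictly exceed the median
    of that measure over all profiled nodes (``'ge'`` relaxes to >=).

    A measure that is constant across all nodes carries no ranking
    information and can never be strictly exceeded, so it is excluded
    from the consensus (reported under ``degenerate``).  This matters on
    triangle-free graphs — including layered herb-ingredient-target-
    disease networks — where LAC and network centrality vanish
    identically; keeping them would make the strict rule vacuous.  When
    every measure is constant (vertex-transitive graphs) the core is
    empty.

    Returns the core node list (input order) and a report holding the
    per-measure medians and, per node, the boolean exceedance vector.
    """
    profiles = list(profiles)
    if not profiles:
        raise ValueError("no profiles given")
    if rule not in {"strict", "ge"}:
        raise ValueError(f"unknown rule {rule!r}")
    table = np.array([[getattr(p, m) for m in measures] for p in profiles], dtype=float)
    medians = np.median(table, axis=0)
    # relative tolerance so that numerically tied eigen-based values
    # (e.g. on vertex-transitive graphs) are treated as exact ties
    tol = 1e-9 * np.maximum(np.abs(table).max(axis=0), 1.0)
    informative = (table.max(axis=0) - table.min(axis=0)) > tol
    if rule == "strict":
        exceed = table > medians + tol
    else:
        exceed = table >= medians - tol
    if informative.any():
        core_mask = exceed[:, informative].all(axis=1)
    else:
        core_mask = np.zeros(len(profiles), dtype=bool)
    report = {
        "rule": rule,
        "medians": {m: float(med) for m, med in zip(measures, medians)},
        "degenerate": [m for m, ok in zip(measures, informative) if not ok],
        "exceedance": {
            str(p.node): dict(zip(measures, map(bool, row)))
            for p, row in zip(profiles, exceed)
        },
    }
    return [p.node for p, ok in zip(profiles, core_mask) if ok], report


def select_core_ingredients(hitd: nx.Graph, rule: str = "strict") -> tuple[list, dict]:
    """Core compounds of a herb-ingredient-target-disease network.

    The consensus rule runs on the heterogeneous graph treated as an
    untyped simple graph; the resulting core set is then filtered to
    ingredient-kind nodes.
    """
    profiles = compute_centralities(hitd)
    core, report = select_core(profiles, rule=rule)
    kinds = nx.get_node_attributes(hitd, "kind")
    core_ing = [v for v in core if kinds.get(v) == "ingredient"]
    report["core_all"] = [str(v) for v in core]
    return core_ing, report


def profiles_frame(profiles: Iterable[CentralityProfile]) -> pd.DataFrame:
    """Profiles as a node x measure table."""
    profiles = list(profiles)
    return pd.DataFrame(
        [[p.node, *p.values()] for p in profiles],
        columns=["node", *MEASURES],
    )
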