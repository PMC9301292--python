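"""Construction of the pharmacology networks.

Three graphs underlie the analysis:

* the bipartite ingredient-target network linking screened compounds to
  their predicted protein targets,
* the protein-protein interaction (PPI) network over the intersection of
  drug targets and disease genes, and
* the heterogeneous herb-ingredient-target-disease (H-I-T-D) network in
  which herbs connect to their member compounds, compounds to the
  intersection targets they hit, and every retained target to a single
  disease node.

Gene symbols are uppercased and whitespace-stripped at ingestion; no
alias resolution is attempted.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

from .screening import IngredientRecord

__all__ = [
    "BipartiteTargetNet",
    "build_target_net",
    "intersect_targets",
    "build_hitd",
    "load_ppi",
    "read_edge_table",
    "hitd_summary",
    "write_sif",
]


def normalize_symbol(symbol: str) -> str:
    return str(symbol).strip().upper()


@dataclass
class BipartiteTargetNet:
    """Deduplicated ingredient -> target gene edges with both indexes."""

    edges: set[tuple[str, str]]
    ingredient_index: dict[str, set[str]] = field(default_factory=dict)
    gene_index: dict[str, set[str]] = field(default_factory=dict)

    @property
    def n_ingredients(self) -> int:
        return len(self.ingredient_index)

    @property
    def n_genes(self) -> int:
        return len(self.gene_index)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def target_counts(self) -> dict[str, int]:
        """Predicted-target count per ingredient (the 'frequency')."""
        return {ing: len(genes) for ing, genes in self.ingredient_index.items()}

    def genes(self) -> set[str]:
        return set(self.gene_index)


def read_edge_table(path: str | Path, sep: str | None = None,
                    columns: Sequence[str] = ("ingredient_id", "gene_symbol")) -> pd.DataFrame:
    """Read a two-column edge table (TSV default, CSV by extension)."""
    path = Path(path)
    if sep is None:
        sep = "," if path.suffix.lower() == ".csv" else "\t"
    frame = pd.read_csv(path, sep=sep, dtype=str)
    if not set(columns) <= set(frame.columns):
        frame = pd.read_csv(path, sep=sep, dtype=str, header=None, names=list(columns))
    return frame[list(columns)]


def build_target_net(edge_table: pd.DataFrame | Iterable[tuple[str, str]]) -> BipartiteTargetNet:
    """Build the deduplicated bipartite ingredient-target network.

    Accepts a DataFrame whose first two columns are ingredient id and
    gene symbol, or any iterable of (ingredient, gene) pairs.
    """
    if isinstance(edge_table, pd.DataFrame):
        pairs = edge_table.iloc[:, :2].itertuples(index=False, name=None)
    else:
        pairs = iter(edge_table)
    edges: set[tuple[str, str]] = set()
    ing_index: dict[str, set[str]] = {}
    gene_index: dict[str, set[str]] = {}
    for ing, gene in pairs:
        ing = str(ing).strip()
        gene = normalize_symbol(gene)
        if (ing, gene) in edges:
            continue
        edges.add((ing, gene))
        ing_index.setdefault(ing, set()).add(gene)
        gene_index.setdefault(gene, set()).add(ing)
    if not edges:
        raise ValueError("empty ingredient-target edge table")
    return BipartiteTargetNet(edges=edges, ingredient_index=ing_index, gene_index=gene_index)


def intersect_targets(drug_genes: Iterable[str], disease_genes: Iterable[str]) -> list[str]:
    """Sorted intersection of drug-target and disease gene symbols."""
    drug = {normalize_symbol(g) for g in drug_genes}
    disease = {normalize_symbol(g) for g in disease_genes}
    return sorted(drug & disease)


def build_hitd(screened: Iterable[IngredientRecord], target_net: BipartiteTargetNet,
               intersection: Iterable[str], disease: str = "disease") -> nx.Graph:
    """Assemble the herb-ingredient-target-disease network.

    Target nodes are the intersection genes; an ingredient node is kept
    only while it retains at least one edge into the intersection, and a
    herb node only while one of its member ingredients is kept (the
    network carries no dangling branches).  One disease node connects to
    every target.  Node ``kind`` attributes: herb / ingredient / target /
    disease.
    """
    inter = {normalize_symbol(g) for g in intersection}
    if not inter:
        raise ValueError("empty target intersection")
    if not inter <= target_net.genes():
        extra = sorted(inter - target_net.genes())
        raise ValueError(f"intersection genes absent from the target network: {extra[:5]}")

    graph = nx.Graph()
    graph.add_node(disease, kind="disease")
    for gene in sorted(inter):
        graph.add_node(gene, kind="target")
        graph.add_edge(gene, disease, kind="target-disease")

    by_id = {rec.ingredient_id: rec for rec in screened}
    for ing, targets in sorted(target_net.ingredient_index.items()):
        hit = sorted(t for t in targets if t in inter)
        if not hit or ing not in by_id:
            continue
        graph.add_node(ing, kind="ingredient")
        for gene in hit:
            graph.add_edge(ing, gene, kind="ingredient-target")
        for herb in sorted(by_id[ing].herbs):
            graph.add_node(herb, kind="herb")
            graph.add_edge(herb, ing, kind="herb-ingredient")
    return graph


def hitd_summary(graph: nx.Graph) -> dict:
    """Typed node and edge counts of a H-I-T-D network."""
    node_counts: dict[str, int] = {}
    for _, kind in graph.nodes(data="kind"):
        node_counts[kind] = node_counts.get(kind, 0) + 1
    edge_counts: dict[str, int] = {}
    for _, _, kind in graph.edges(data="kind"):
        edge_counts[kind] = edge_counts.get(kind, 0) + 1
    return {
        "n_nodes": graph.number_of_nodes(),
        "n_edges": graph.number_of_edges(),
        "nodes_by_kind": node_counts,
        "edges_by_kind": edge_counts,
    }


def load_ppi(edge_list: pd.DataFrame | Iterable[tuple[str, str]],
             nodes_of_interest: Iterable[str] | None = None,
             drop_isolated: bool = False) -> nx.Graph:
    """Build a simple undirected PPI graph from symbol pairs.

    Self-loops are discarded and reversed/duplicated pairs collapse into
    one undirected edge.  When ``nodes_of_interest`` is given the graph
    is restricted to those symbols (isolated members retained unless
    ``drop_isolated``).
    """
    if isinstance(edge_list, pd.DataFrame):
        pairs = edge_list.iloc[:, :2].itertuples(index=False, name=None)
    else:
        pairs = iter(edge_list)
    graph = nx.Graph()
    keep = None
    if nodes_of_interest is not None:
        keep = {normalize_symbol(g) for g in nodes_of_interest}
        graph.add_nodes_from(sorted(keep))
    for a, b in pairs:
        a, b = normalize_symbol(a), normalize_symbol(b)
        if a == b:
            continue
        if keep is not None and (a not in keep or b not in keep):
            continue
        graph.add_edge(a, b)
    if drop_isolated:
        graph.remove_nodes_from(list(nx.isolates(graph)))
    return graph


def write_sif(graph: nx.Graph, path: str | Path, relation: str = "pp") -> None:
    """Write a graph as SIF (``node relation node`` per edge)."""
    with open(path, "w") as fh:
        for a, b, kind in graph.edges(data="kind"):
            fh.write(f"{a}\t{kind or relation}\t{b}\n")
        for node in nx.isolates(graph):
            fh.write(f"{node}\n")


def export_graph(graph: nx.Graph, path: str | Path) -> None:
    """Export GraphML or SIF by extension; summary JSON alongside ``.json``."""
    path = Path(path)
    if path.suffix == ".sif":
        write_sif(graph, path)
    elif path.suffix == ".json":
        path.write_text(json.dumps(hitd_summary(graph), indent=2) + "\n")
    else:
        nx.write_graphml(graph, path)
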