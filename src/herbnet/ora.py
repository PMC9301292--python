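"""Hypergeometric over-representation analysis against GMT gene sets.

For a query gene list and a collection of gene sets, each set is scored
by the upper-tail hypergeometric probability of observing at least the
realised overlap given the background universe.  Raw p-values are
adjusted by Benjamini-Hochberg across the tested sets, and a
Storey-style q-value is attached.  A set is reported when its adjusted
p-value and q-value both clear their cutoffs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "GeneSetCollection",
    "read_gmt",
    "ora",
    "storey_qvalues",
]


@dataclass
class GeneSetCollection:
    """Named gene sets plus the background universe.

    The universe defaults to the union of all member genes; pass an
    explicit ``universe`` (e.g. all measured genes) to override.  Symbols
    are uppercased; empty sets are rejected.
    """

    sets: dict[str, frozenset[str]]
    universe: frozenset[str] = field(default=frozenset())

    def __post_init__(self) -> None:
        clean: dict[str, frozenset[str]] = {}
        for name, genes in self.sets.items():
            genes = frozenset(str(g).strip().upper() for g in genes)
            if not genes:
                raise ValueError(f"gene set {name!r} is empty")
            clean[name] = genes
        self.sets = clean
        if self.universe:
            self.universe = frozenset(str(g).strip().upper() for g in self.universe)
        else:
            self.universe = frozenset().union(*clean.values()) if clean else frozenset()


def read_gmt(path: str | Path, universe: Iterable[str] | None = None) -> GeneSetCollection:
    """Load a GMT file (set name, description, member genes per line)."""
    from gseapy import read_gmt as _read_gmt
    raw: Mapping[str, list[str]] = _read_gmt(str(path))
    return GeneSetCollection(
        sets={name: frozenset(genes) for name, genes in raw.items()},
        universe=frozenset(universe) if universe is not None else frozenset(),
    )


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w") as fh:
        for name, genes in sets.items():
            fh.write("\t".join([name, "na", *sorted(set(genes))]) + "\n")


def storey_qvalues(pvalues: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with a single-lambda pi0 estimate.

    ``pi0`` is estimated as ``#{p > lam} / ((1 - lam) m)`` capped at 1,
    then applied to the step-up adjusted p-values.
    """
    p = np.asarray(pvalues, dtype=float)
    m = p.size
    if m == 0:
        return p.copy()
    pi0 = min(1.0, float((p > lam).sum()) / ((1.0 - lam) * m))
    pi0 = max(pi0, 1.0 / m)  # guard against a degenerate zero estimate
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m * pi0 / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(ranked, 1.0)
    return q


def ora(query: Iterable[str], collection: GeneSetCollection,
        adj_p_cut: float = 0.05, q_cut: float = 0.05) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in each set.

    Per set: ``p = P[X >= k]`` for ``X ~ Hypergeom(N, K, n)`` with
    universe size N, set size K (restricted to the universe), query size
    n and overlap k.  Columns: ``set, k, K, n, N, p, p_adj, q, genes``.
    Only rows with ``p_adj < adj_p_cut`` and ``q < q_cut`` are returned,
    sorted by adjusted p (pass ``adj_p_cut=q_cut=1.01`` to keep all).
    Query genes outside the universe are dropped with a warning; a query
    fully disjoint from the universe is an error.
    """
    query = {str(g).strip().upper() for g in query}
    universe = collection.universe
    inside = query & universe
    if not inside:
        raise ValueError("query is disjoint from the background universe")
    dropped = len(query) - len(inside)
    if dropped:
        warnings.warn(f"{dropped} query gene(s) absent from the universe were dropped")

    names = sorted(collection.sets)
    big_n = len(universe)
    n = len(inside)
    rows = []
    for name in names:
        members = collection.sets[name] & universe
        k = len(members & inside)
        big_k = len(members)
        # upper tail P[X >= k]
        p = float(stats.hypergeom.sf(k - 1, big_n, big_k, n)) if big_k else 1.0
        rows.append((name, k, big_k, n, big_n, min(p, 1.0),
                     ";".join(sorted(members & inside))))
    frame = pd.DataFrame(rows, columns=["set", "k", "K", "n", "N", "p", "genes"])
    frame["p_adj"] = stats.false_discovery_control(frame["p"].to_numpy(), method="bh")
    frame["q"] = storey_qvalues(frame["p"].to_numpy())
    frame = frame[(frame["p_adj"] < adj_p_cut) & (frame["q"] < q_cut)]
    frame = frame.sort_values(["p_adj", "p", "set"], kind="stable").reset_index(drop=True)
    return frame[["set", "k", "K", "n", "N", "p", "p_adj", "q", "genes"]]
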