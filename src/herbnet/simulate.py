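"""Synthetic inputs for every pipeline stage, with planted ground truth.

Each generator emulates the statistical structure its downstream stage
assumes and emits a machine-readable truth object alongside the data:

* :func:`gen_ingredient_table` — candidate-compound tables where a
  configurable expected fraction survives the ADME cascade and a
  configurable fraction of compounds belongs to two or more herbs;
* :func:`gen_sc_counts` — two-group negative-binomial single-cell
  counts with planted differentially expressed genes, flagged
  mitochondrial genes and injected low-quality cells;
* :func:`gen_survival_cohort` — lognormal expression cohorts whose
  Weibull hazard scales with the standardized mean expression of a
  planted gene signature, under uniform random censoring;
* :func:`gen_spoiler_cohort` — a cohort carrying many weakly
  informative genes plus one strongly inversely associated "spoiler"
  gene whose inclusion dilutes the set-level enrichment signal;
* :func:`gen_graph` — preferential-attachment graphs with a planted
  clique for centrality-consensus recovery checks.

All generators run on ``numpy.random.default_rng`` (PCG64), so a fixed
seed reproduces outputs bit-identically across platforms.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .deg import LabeledExpressionMatrix
from .signature import SurvivalCohort

__all__ = [
    "SimulationConfig",
    "HERB_CODES",
    "gen_ingredient_table",
    "gen_sc_counts",
    "gen_survival_cohort",
    "gen_spoiler_cohort",
    "gen_graph",
]

HERB_CODES = ("CH", "ZQ", "CX", "CP", "XF", "BS", "GC")

#: screening thresholds; passing/failing draws straddle each one
_PASS_RANGES = {
    "OB": (31.0, 100.0), "DL": (0.19, 1.0), "MW": (100.0, 500.0),
    "Hdon": (0, 5), "Hacc": (0, 10), "iLOGP": (-2.0, 5.0),
}
_FAIL_RANGES = {
    "OB": (1.0, 30.0), "DL": (0.01, 0.18), "MW": (500.5, 900.0),
    "Hdon": (6, 10), "Hacc": (11, 16), "iLOGP": (5.5, 9.0),
}


@dataclass
class SimulationConfig:
    """All generator knobs in one place.

    Defaults mirror the scale of the study the pipeline was built for:
    1075 candidate compounds over seven herbs of which about an eighth
    survive screening; two-group single-cell comparisons of a few
    hundred cells with 50 planted DE genes at |log2 FC| = 2; survival
    cohorts of 216 patients with 63 candidate genes.
    """

    seed: int = 0
    # ingredient tables
    n_ingredients: int = 1075
    n_herbs: int = 7
    pass_fraction: float = 0.125
    shared_fraction: float = 0.04    # compounds belonging to >= 2 herbs
    # single-cell counts
    n_cells: int = 200               # per group
    n_genes: int = 500
    n_de: int = 50
    de_log2fc: float = 2.0
    nb_dispersion: float = 2.0
    n_mito: int = 10
    lowq_fraction: float = 0.02      # injected low-quality cells, per group
    # survival cohorts
    n_samples: int = 216
    n_candidates: int = 63
    n_background_genes: int = 137
    signature_size: int = 10
    signature_hazard_ratio: float = 3.0
    signature_correlation: float = 0.5   # shared-module variance fraction
    censoring_rate: float = 0.3
    weibull_shape: float = 1.5
    weibull_scale: float = 5.0
    # graphs
    graph_nodes: int = 100
    graph_attachment: int = 2
    clique_size: int = 5

    def __post_init__(self) -> None:
        if self.n_herbs > len(HERB_CODES):
            raise ValueError(f"at most {len(HERB_CODES)} herbs available")
        for name in ("pass_fraction", "shared_fraction", "censoring_rate",
                     "lowq_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.signature_size > self.n_candidates:
            raise ValueError("signature_size exceeds n_candidates")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def _draw(rng: np.random.Generator, field_name: str, passing: bool):
    lo, hi = (_PASS_RANGES if passing else _FAIL_RANGES)[field_name]
    if isinstance(lo, int):
        return int(rng.integers(lo, hi + 1))
    return float(rng.uniform(lo, hi))


def gen_ingredient_table(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate-compound table (one row per compound-herb pair) plus truth.

    Each compound independently passes with probability ``pass_fraction``;
    failing compounds violate one or more randomly chosen criteria.  With
    probability ``shared_fraction`` a compound belongs to two or three
    herbs.  Truth columns: ``ingredient_id, should_pass, n_herbs``.
    """
    rng = config.rng()
    herbs = HERB_CODES[: config.n_herbs]
    rows, truth = [], []
    for i in range(config.n_ingredients):
        rid = f"SIM{i:05d}"
        passing = bool(rng.random() < config.pass_fraction)
        props = {f: _draw(rng, f, True) for f in _PASS_RANGES}
        gi = "High"
        if not passing:
            broken = rng.choice(7, size=int(rng.integers(1, 4)), replace=False)
            for b in broken:
                if b == 6:
                    gi = "Low"
                else:
                    f = list(_PASS_RANGES)[b]
                    props[f] = _draw(rng, f, False)
        n_herb = 1
        if config.n_herbs >= 2 and rng.random() < config.shared_fraction:
            n_herb = int(rng.integers(2, min(3, config.n_herbs) + 1))
        member = rng.choice(len(herbs), size=n_herb, replace=False)
        for h in member:
            rows.append({"ingredient_id": rid, "name": f"compound-{i}",
                         "herb": herbs[h], "GI": gi, **props})
        truth.append({"ingredient_id": rid, "should_pass": passing, "n_herbs": n_herb})
    return pd.DataFrame(rows), pd.DataFrame(truth)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float,
               size: tuple[int, int]) -> np.ndarray:
    """Gamma-Poisson draws with var = mu + mu^2 / dispersion."""
    lam = rng.gamma(dispersion, mean / dispersion, size=size)
    return rng.poisson(lam)


def gen_sc_counts(config: SimulationConfig) -> tuple[LabeledExpressionMatrix, pd.DataFrame]:
    """Two-group negative-binomial counts with planted DE genes.

    Per-gene baseline means are lognormal; ``n_de`` non-mitochondrial
    genes are shifted by ``de_log2fc`` in the disease group (alternating
    sign).  ``n_mito`` genes are flagged ``MT-``.  A ``lowq_fraction``
    of extra cells per group is injected with either very few detected
    genes or a dominant mitochondrial fraction, to exercise QC.  Truth
    columns: ``gene, is_de, log2fc``.
    """
    rng = config.rng()
    n_genes, n_cells = config.n_genes, config.n_cells
    base = rng.lognormal(mean=1.0, sigma=1.0, size=n_genes)
    names = np.array(
        [f"MT-{i}" if i < config.n_mito else f"G{i:04d}" for i in range(n_genes)],
        dtype=object)
    mito = np.array([n.startswith("MT-") for n in names])

    de_idx = rng.choice(np.flatnonzero(~mito), size=config.n_de, replace=False)
    lfc = np.zeros(n_genes)
    signs = np.where(np.arange(config.n_de) % 2 == 0, 1.0, -1.0)
    lfc[de_idx] = signs * config.de_log2fc

    mean_control = np.tile(base, (n_cells, 1))
    mean_disease = np.tile(base * 2.0 ** lfc, (n_cells, 1))
    counts = np.vstack([
        _nb_counts(rng, mean_disease, config.nb_dispersion, (n_cells, n_genes)),
        _nb_counts(rng, mean_control, config.nb_dispersion, (n_cells, n_genes)),
    ])
    groups = np.array(["disease"] * n_cells + ["control"] * n_cells, dtype=object)

    n_lowq = int(round(config.lowq_fraction * n_cells))
    if n_lowq:
        lowq = _nb_counts(rng, np.tile(base, (2 * n_lowq, 1)),
                          config.nb_dispersion, (2 * n_lowq, n_genes))
        for i in range(2 * n_lowq):
            if i % 2 == 0:  # almost-empty cell: ~50 detected genes
                keep = rng.choice(n_genes, size=50, replace=False)
                mask = np.zeros(n_genes, dtype=bool)
                mask[keep] = True
                lowq[i, ~mask] = 0
                lowq[i, keep] = np.maximum(lowq[i, keep], 1)
            else:  # mito-dominated cell
                lowq[i, mito] = (lowq[i, mito] + 1) * 50
        counts = np.vstack([counts, lowq])
        groups = np.concatenate([groups,
                                 np.array(["disease", "control"] * n_lowq, dtype=object)])

    lineages = rng.choice(np.array(["HSC", "MDM", "LSEC"], dtype=object), size=len(groups))
    matrix = LabeledExpressionMatrix(
        counts=counts, gene_names=names, cell_group=groups,
        cell_lineage=lineages, mito_flag=mito)
    truth = pd.DataFrame({"gene": names, "is_de": lfc != 0, "log2fc": lfc})
    return matrix, truth


def gen_survival_cohort(config: SimulationConfig) -> tuple[SurvivalCohort, dict]:
    """Expression cohort whose hazard follows a planted gene signature.

    Log-scale expression is Gaussian (unit variance) around spread-out
    gene means.  The planted signature behaves as a co-regulated module:
    its genes share a latent factor contributing a
    ``signature_correlation`` fraction of their variance, the way the
    genes of a transcriptional program co-vary in real cohorts.  The
    latent risk per sample is the standardized mean expression of the
    signature genes; survival is Weibull with the hazard multiplied by
    ``signature_hazard_ratio`` per latent-score unit.  Censored samples
    (probability ``censoring_rate``) get a uniform fraction of their
    event time.  Truth: signature gene list and the per-sample latent
    score.
    """
    rng = config.rng()
    n = config.n_samples
    n_genes = config.n_candidates + config.n_background_genes
    gene_names = [f"CAND{i:03d}" for i in range(config.n_candidates)] + \
                 [f"BG{i:03d}" for i in range(config.n_background_genes)]
    gene_mean = rng.uniform(6.0, 12.0, size=n_genes)
    expr = gene_mean + rng.normal(0.0, 1.0, size=(n, n_genes))
    rho = config.signature_correlation
    if rho > 0 and config.signature_size:
        module = rng.normal(size=n)
        for j in range(config.signature_size):
            expr[:, j] = gene_mean[j] + np.sqrt(rho) * module + \
                np.sqrt(1.0 - rho) * rng.normal(0.0, 1.0, size=n)
    frame = pd.DataFrame(expr, columns=gene_names,
                         index=[f"S{i:03d}" for i in range(n)])

    signature = gene_names[: config.signature_size]
    score = frame[signature].mean(axis=1).to_numpy()
    z = (score - score.mean()) / score.std(ddof=0)
    theta = np.log(config.signature_hazard_ratio)
    u = rng.uniform(size=n)
    time = config.weibull_scale * (-np.log(u) / np.exp(theta * z)) ** (1.0 / config.weibull_shape)
    event = np.ones(n, dtype=int)
    censor = rng.uniform(size=n) < config.censoring_rate
    time = np.where(censor, time * rng.uniform(size=n), time)
    event[censor] = 0
    time = np.maximum(time, 1e-6)

    cohort = SurvivalCohort(expr=frame, time=time, event=event)
    truth = {"signature": list(signature), "latent_score": z.tolist()}
    return cohort, truth


def gen_spoiler_cohort(seed: int = 0, n_samples: int = 216, n_informative: int = 62,
                       n_background: int = 137, hazard_ratio: float = 3.0,
                       censoring_rate: float = 0.2, informative_noise: float = 0.3,
                       target_p: float = 1e-3) -> tuple[SurvivalCohort, dict]:
    """Cohort with 62 weakly informative genes and one signal-destroying spoiler.

    A latent risk factor u drives the hazard and, weakly, every
    informative gene; the spoiler gene tracks u strongly in the opposite
    direction, so its within-sample expression rank swings across the
    whole range and its enrichment contribution cancels the signal of
    any set that includes it.  Because the cancellation one gene can
    provide is bounded, both loadings are calibrated against the
    realised draw: the informative loading is bisected until the
    62-gene set's median-split score reaches ``target_p`` significance
    by Cox regression, and the spoiler's inverse loading is then chosen
    to maximise the full 63-gene set's p-value, i.e. to destroy that
    significance.  Truth names the spoiler, the informative genes and
    the calibrated loadings.
    """
    from .coxph import cox_fit
    from .signature import SsgseaScorer

    rng = np.random.default_rng(seed)
    n = n_samples
    u = rng.normal(size=n)
    informative = [f"CAND{i:03d}" for i in range(n_informative)]
    spoiler = "SPOILER"
    names = informative + [spoiler] + [f"BG{i:03d}" for i in range(n_background)]
    # informative genes sit in the lower expression range with small
    # within-gene noise: their rank jitter stays small, so the wide-
    # swinging spoiler retains enough leverage against their sum
    mu_inf = rng.uniform(6.5, 8.5, n_informative)
    eps = rng.normal(0.0, 1.0, (n, n_informative))
    mu_bg = rng.uniform(6.0, 12.0, n_background)
    background = {f"BG{i:03d}": mu_bg[i] + rng.normal(0.0, 1.0, n)
                  for i in range(n_background)}

    theta = np.log(hazard_ratio)
    time = 5.0 * (-np.log(rng.uniform(size=n)) / np.exp(theta * u)) ** (1.0 / 1.5)
    event = np.ones(n, dtype=int)
    censor = rng.uniform(size=n) < censoring_rate
    time = np.maximum(np.where(censor, time * rng.uniform(size=n), time), 1e-6)
    event[censor] = 0

    def frame_for(a: float, kappa: float) -> pd.DataFrame:
        cols = {g: mu_inf[j] + a * u + informative_noise * eps[:, j]
                for j, g in enumerate(informative)}
        cols.update(background)
        cols[spoiler] = 9.0 - kappa * u
        return pd.DataFrame(cols, index=[f"S{i:03d}" for i in range(n)])[names]

    def split_p(frame: pd.DataFrame, subset) -> float:
        scores = SsgseaScorer(frame).score(tuple(sorted(subset)))
        high = scores > np.median(scores)
        if high.all() or not high.any():
            return 1.0
        return float(cox_fit(time, event, high.astype(float)).p[0])

    lo, hi = 0.01, 0.30
    for _ in range(12):
        mid = 0.5 * (lo + hi)
        if split_p(frame_for(mid, 0.0), informative) > target_p:
            lo = mid
        else:
            hi = mid
    loading = hi
    best_p, best_kappa = -np.inf, 0.5
    for kappa in np.linspace(0.5, 5.0, 46):
        p = split_p(frame_for(loading, kappa), informative + [spoiler])
        if p > best_p:
            best_p, best_kappa = p, kappa

    cohort = SurvivalCohort(expr=frame_for(loading, best_kappa),
                            time=time, event=event)
    truth = {"informative": informative, "spoiler": spoiler,
             "loading": loading, "spoiler_loading": best_kappa}
    return cohort, truth


def gen_graph(config: SimulationConfig) -> tuple[nx.Graph, set]:
    """Preferential-attachment graph with a planted clique.

    A Barabasi-Albert graph on ``graph_nodes`` nodes (``graph_attachment``
    edges per newcomer) receives a planted ``clique_size`` clique.  The
    clique members are sampled with degree-proportional weights, placing
    the dense module inside the connected core of the network the way a
    disease module sits in an interactome rather than on its periphery.
    Returns the graph and the clique node set.  With
    ``graph_attachment=1`` the base graph is a tree (triangle-free when
    no clique is planted, i.e. ``clique_size <= 2``).
    """
    if config.graph_nodes < 5:
        raise ValueError("need at least 5 nodes")
    rng = config.rng()
    graph = nx.barabasi_albert_graph(
        config.graph_nodes, config.graph_attachment,
        seed=int(rng.integers(2 ** 31)))
    if config.clique_size >= 2:
        deg = np.array([graph.degree(v) for v in range(config.graph_nodes)], dtype=float)
        members = rng.choice(config.graph_nodes, size=config.clique_size,
                             replace=False, p=deg / deg.sum())
        for i, a in enumerate(members):
            for b in members[i + 1:]:
                graph.add_edge(int(a), int(b))
        planted = {int(m) for m in members}
    else:
        planted = set()
    return graph, planted
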