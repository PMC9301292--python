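"""Prognostic-signature machinery: per-gene Cox screening, stepwise
multivariate Cox risk models, single-sample GSEA scoring and the
ssGSEA-Cox combinational search.

The search couples three steps.  For a candidate gene subset S the
cohort is scored by single-sample gene-set enrichment (ssGSEA): within
each sample, genes are ranked by expression and a weighted running sum
compares the cumulative distribution of in-set genes (weights
``rank^tau``) against the uniform distribution of out-of-set genes;
the area between the two is the sample's enrichment score, rescaled
across the cohort by its range.  Samples are split at the median score
and the binary high/low indicator is tested by univariate Cox
regression.  S is *admissible* when that test is significant.  The
search returns the largest admissible subset of the candidates,
exploring leave-k-out subsets exhaustively while the level is small
enough and falling back to greedy backward elimination beyond.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field
from math import comb
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .coxph import CoxFit, ConvergenceWarning, cox_fit, kaplan_meier, logrank_test

__all__ = [
    "SurvivalCohort",
    "SsgseaScorer",
    "SignatureSearchResult",
    "RiskSplit",
    "read_cohort",
    "univariate_screen",
    "stepwise_cox",
    "risk_split_km",
    "ssgsea_score",
    "ssgsea_cox_search",
]


@dataclass
class SurvivalCohort:
    """Samples x genes expression with follow-up time and event status.

    Expression is assumed continuous on a log scale.  ``time`` must be
    positive and ``event`` binary (1 = death observed).
    """

    expr: pd.DataFrame
    time: np.ndarray
    event: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.event = np.asarray(self.event, dtype=int)
        if len(self.time) != len(self.expr) or len(self.event) != len(self.expr):
            raise ValueError("clinical annotation length mismatch")
        if np.any(self.time <= 0):
            raise ValueError("follow-up times must be positive")
        if not set(np.unique(self.event)) <= {0, 1}:
            raise ValueError("event indicator must be 0/1")
        if self.expr.isna().any().any():
            raise ValueError("expression contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.expr)

    @property
    def genes(self) -> list[str]:
        return list(self.expr.columns)


def read_cohort(expr_path: str | Path, clinical_path: str | Path,
                duplicate_genes: str = "first") -> SurvivalCohort:
    """Load an expression CSV (samples x genes) and a clinical TSV.

    The clinical table needs columns ``sample, time, event`` and is
    joined to the expression matrix on sample id.  Duplicated gene
    columns are collapsed by keeping the first occurrence
    (``duplicate_genes='first'``) or the highest-mean copy (``'max_mean'``).
    """
    expr = pd.read_csv(expr_path, index_col=0)
    if expr.columns.duplicated().any():
        if duplicate_genes == "first":
            expr = expr.loc[:, ~expr.columns.duplicated()]
        elif duplicate_genes == "max_mean":
            means = expr.mean(axis=0)
            keep = (
                pd.DataFrame({"gene": expr.columns, "mean": means.to_numpy(),
                              "pos": range(expr.shape[1])})
                .sort_values(["gene", "mean"], ascending=[True, False])
                .drop_duplicates("gene")["pos"]
                .sort_values()
            )
            expr = expr.iloc[:, list(keep)]
        else:
            raise ValueError(f"unknown duplicate_genes policy {duplicate_genes!r}")
    clin = pd.read_csv(clinical_path, sep="\t").set_index("sample")
    clin = clin.loc[expr.index]
    return SurvivalCohort(expr=expr, time=clin["time"].to_numpy(),
                          event=clin["event"].to_numpy())


# ---------------------------------------------------------------------------
# Cox-based screening


def univariate_screen(cohort: SurvivalCohort, genes: list[str] | None = None,
                      alpha: float = 0.05) -> pd.DataFrame:
    """Single-gene Cox screen.

    Fits one Cox model per gene and returns a table with hazard ratio,
    confidence bounds and Wald p, flagging genes with ``p < alpha``.
    Genes that cannot be fitted (constant expression, non-convergence)
    are skipped with a warning.
    """
    genes = list(genes) if genes is not None else cohort.genes
    rows = []
    for gene in genes:
        if gene not in cohort.expr.columns:
            warnings.warn(f"gene {gene} not measured in the cohort; skipped")
            continue
        x = cohort.expr[gene].to_numpy(dtype=float)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                fit = cox_fit(cohort.time, cohort.event, x, [gene])
        except (ValueError, ConvergenceWarning) as exc:
            warnings.warn(f"gene {gene} skipped in the univariate screen: {exc}")
            continue
        lo, hi = fit.ci
        rows.append((gene, float(fit.beta[0]), float(fit.hr[0]),
                     float(lo[0]), float(hi[0]), float(fit.p[0])))
    frame = pd.DataFrame(rows, columns=["gene", "beta", "hr", "ci_low", "ci_high", "p"])
    frame["significant"] = frame["p"] < alpha
    return frame.sort_values("p", kind="stable").reset_index(drop=True)


def stepwise_cox(cohort: SurvivalCohort, candidates: list[str]) -> tuple[CoxFit, list[dict]]:
    """Backward stepwise Cox model selection by AIC.

    Starts from the full candidate model and repeatedly removes the
    covariate whose removal most lowers the AIC, stopping when no single
    removal improves it.  The empty (null) model is a legal endpoint
    when even a single remaining covariate fails to beat it.  Returns
    the final fit and the elimination trace.
    """
    current = list(candidates)
    if not current:
        raise ValueError("no candidate covariates")

    def fit_for(genes: list[str]) -> CoxFit:
        X = cohort.expr[genes].to_numpy(dtype=float)
        return cox_fit(cohort.time, cohort.event, X, genes)

    fit = fit_for(current)
    null_aic = -2.0 * fit.loglik_null
    trace = [{"model": list(current), "aic": fit.aic, "removed": None}]
    while current:
        best_candidate: tuple[float, str | None, CoxFit | None] = (fit.aic, None, None)
        for gene in current:
            reduced = [g for g in current if g != gene]
            if reduced:
                trial = fit_for(reduced)
                aic = trial.aic
            else:
                trial = None
                aic = null_aic
            if aic < best_candidate[0] - 1e-10:
                best_candidate = (aic, gene, trial)
        aic, removed, trial = best_candidate
        if removed is None:
            break
        current = [g for g in current if g != removed]
        trace.append({"model": list(current), "aic": aic, "removed": removed})
        if trial is None:  # null model preferred over the last covariate
            fit = CoxFit(covariates=[], beta=np.zeros(0), se=np.zeros(0),
                         loglik=fit.loglik_null, loglik_null=fit.loglik_null,
                         n=fit.n, n_events=fit.n_events, converged=True, n_iter=0,
                         information=np.zeros((0, 0)))
            break
        fit = trial
    return fit, trace


@dataclass
class RiskSplit:
    """Median split of the model risk score with survival statistics."""

    risk: np.ndarray
    high: np.ndarray            # boolean; risk strictly above the median
    logrank_stat: float
    logrank_p: float
    km_high: tuple[np.ndarray, np.ndarray]
    km_low: tuple[np.ndarray, np.ndarray]


def risk_split_km(cohort: SurvivalCohort, fit: CoxFit) -> RiskSplit:
    """Median split of the Cox linear predictor with Kaplan-Meier curves.

    The risk score is ``sum(beta * x)`` over the fitted covariates;
    samples at or below the median are assigned to the low-risk group.
    Raises ``ValueError`` when the score is constant (single group).
    """
    if not fit.covariates:
        raise ValueError("fit has no covariates")
    X = cohort.expr[fit.covariates].to_numpy(dtype=float)
    risk = fit.linear_predictor(X)
    high = risk > np.median(risk)
    if high.all() or not high.any():
        raise ValueError("risk score constant: cannot split at the median")
    stat, p = logrank_test(cohort.time, cohort.event, high)
    return RiskSplit(
        risk=risk, high=high, logrank_stat=stat, logrank_p=p,
        km_high=kaplan_meier(cohort.time[high], cohort.event[high]),
        km_low=kaplan_meier(cohort.time[~high], cohort.event[~high]),
    )


# ---------------------------------------------------------------------------
# ssGSEA


class SsgseaScorer:
    """Precomputed per-sample rankings for repeated gene-set scoring.

    Ranking each sample once makes scoring thousands of gene subsets of
    the same cohort cheap (ranks do not depend on the set).
    """

    def __init__(self, expr: pd.DataFrame, tau: float = 0.25):
        self.genes = np.asarray(expr.columns, dtype=object)
        self.tau = float(tau)
        values = expr.to_numpy(dtype=float)
        # ascending ranks, average over ties: highest expression -> rank N
        self.ranks = np.apply_along_axis(stats.rankdata, 1, values)
        # descending-expression ordering (stable, deterministic for ties)
        self.order = np.argsort(-values, axis=1, kind="stable")
        self._col = {g: i for i, g in enumerate(self.genes)}

    def score(self, gene_set, rescale: bool = True) -> np.ndarray:
        """Enrichment score of ``gene_set`` for every sample."""
        members = [g for g in gene_set if g in self._col]
        n_genes = len(self.genes)
        if len(members) != len(set(members)):
            raise ValueError("gene set contains duplicates")
        m = len(members)
        if m == 0:
            raise ValueError("gene set has no overlap with the measured genes")
        if m >= n_genes:
            raise ValueError("gene set covers all measured genes; "
                             "the out-of-set distribution is undefined")
        if m == 1:
            warnings.warn("gene set overlaps a single measured gene")
        mask = np.zeros(n_genes, dtype=bool)
        mask[[self._col[g] for g in members]] = True

        n_samples = self.ranks.shape[0]
        scores = np.empty(n_samples)
        for i in range(n_samples):
            order = self.order[i]
            in_sorted = mask[order]
            w = np.where(in_sorted, self.ranks[i, order] ** self.tau, 0.0)
            p_in = np.cumsum(w)
            p_in /= p_in[-1]
            p_out = np.cumsum(~in_sorted) / (n_genes - m)
            scores[i] = np.sum(p_in - p_out)
        if rescale:
            span = scores.max() - scores.min()
            if span > 0:
                scores = scores / span
        return scores


def ssgsea_score(expr: pd.DataFrame, gene_set, tau: float = 0.25,
                 rescale: bool = True) -> np.ndarray:
    """Single-sample GSEA scores of one gene set (see :class:`SsgseaScorer`).

    Per sample, genes are ranked by expression (average ranks on ties);
    walking the genes in descending expression order, the running sum of
    normalised in-set weights ``rank^tau`` minus the uniform out-of-set
    running sum is accumulated over all positions.  With ``rescale`` the
    cohort's scores are divided by their range (max - min).
    """
    return SsgseaScorer(expr, tau=tau).score(gene_set, rescale=rescale)


# ---------------------------------------------------------------------------
# ssGSEA-Cox combinational search


@dataclass
class SignatureSearchResult:
    """Outcome of the ssGSEA-Cox search."""

    genes: list[str]
    found: bool
    scores: np.ndarray | None
    high: np.ndarray | None
    cox_p: float | None
    logrank_stat: float | None
    logrank_p: float | None
    trace: list[dict] = field(default_factory=list)

    @property
    def n_tested(self) -> int:
        return len(self.trace)


#: exhaustive leave-k-out enumeration is used while C(n, k) stays below this
EXHAUSTIVE_LIMIT = 10_000


def _score_split_test(scorer: SsgseaScorer, subset: tuple[str, ...],
                      time: np.ndarray, event: np.ndarray):
    """ssGSEA score, median split and Cox/log-rank tests for one subset."""
    scores = scorer.score(subset)
    high = scores > np.median(scores)
    if high.all() or not high.any():
        return scores, high, 1.0, 0.0, 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        fit = cox_fit(time, event, high.astype(float), ["high_score"])
    cox_p = float(fit.p[0]) if fit.converged else 1.0
    lr_stat, lr_p = logrank_test(time, event, high)
    return scores, high, cox_p, lr_stat, lr_p


def ssgsea_cox_search(cohort: SurvivalCohort, candidates: list[str],
                      alpha: float = 0.05, tau: float = 0.25) -> SignatureSearchResult:
    """Search for the largest gene subset whose enrichment score predicts survival.

    A subset is admissible when the Cox Wald p of its median-split score
    indicator is below ``alpha``.  The full candidate set is tested
    first; failing that, leave-k-out subsets are tested for k = 1, 2, ...
    exhaustively while ``C(n, k)`` is at most ``EXHAUSTIVE_LIMIT``, then
    by greedy backward elimination (dropping the gene whose removal
    yields the smallest p) down to subsets of three genes.  Among equally
    sized admissible subsets the smallest Cox p wins, then lexicographic
    gene order.  Returns an explicit not-found result when no admissible
    subset exists in the explored lattice.
    """
    candidates = sorted(set(candidates))
    if len(candidates) < 3:
        raise ValueError("need at least 3 candidate genes")
    missing = [g for g in candidates if g not in cohort.expr.columns]
    if missing:
        raise ValueError(f"candidate genes not measured: {missing[:5]}")
    scorer = SsgseaScorer(cohort.expr, tau=tau)
    trace: list[dict] = []

    def test(subset: tuple[str, ...]):
        scores, high, cox_p, lr_stat, lr_p = _score_split_test(
            scorer, subset, cohort.time, cohort.event)
        admissible = cox_p < alpha
        trace.append({"genes": list(subset), "size": len(subset),
                      "cox_p": cox_p, "logrank_p": lr_p,
                      "admissible": bool(admissible)})
        return scores, high, cox_p, lr_stat, lr_p, admissible

    def result_for(subset, scores, high, cox_p, lr_stat, lr_p) -> SignatureSearchResult:
        return SignatureSearchResult(
            genes=list(subset), found=True, scores=scores, high=high,
            cox_p=cox_p, logrank_stat=lr_stat, logrank_p=lr_p, trace=trace)

    full = tuple(candidates)
    outcome = test(full)
    if outcome[-1]:
        return result_for(full, *outcome[:-1])

    n = len(candidates)
    current_best = full  # smallest-p subset seen at the last explored level
    k = 1
    while n - k >= 3 and comb(n, k) <= EXHAUSTIVE_LIMIT:
        level: list[tuple[float, tuple[str, ...], tuple]] = []
        for drop in itertools.combinations(range(n), k):
            keep = tuple(g for i, g in enumerate(candidates) if i not in set(drop))
            outcome = test(keep)
            level.append((outcome[2], keep, outcome))
        admissible = [(p, s, o) for p, s, o in level if o[-1]]
        if admissible:
            p, subset, outcome = min(admissible, key=lambda t: (t[0], t[1]))
            return result_for(subset, *outcome[:-1])
        current_best = min(level, key=lambda t: (t[0], t[1]))[1]
        k += 1

    # greedy backward elimination from the best subset of the last level
    current = list(current_best)
    while len(current) > 3:
        level = []
        for gene in current:
            keep = tuple(g for g in current if g != gene)
            outcome = test(keep)
            level.append((outcome[2], keep, outcome))
        p, subset, outcome = min(level, key=lambda t: (t[0], t[1]))
        if outcome[-1]:
            return result_for(subset, *outcome[:-1])
        current = list(subset)

    return SignatureSearchResult(genes=[], found=False, scores=None, high=None,
                                 cox_p=None, logrank_stat=None, logrank_p=None,
                                 trace=trace)
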