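"""Quality control and Wilcoxon differential expression for labelled
single-cell count matrices.

The disease-gene list of the pipeline comes from comparing disease
(cirrhotic) against control (healthy) non-parenchymal liver cells.  The
module operates downstream of integration and clustering: it takes a
cells x genes count matrix whose cells already carry a ``disease`` /
``control`` group label and a lineage label.

Quality control keeps genes detected in at least 10 cells and cells
with at least 200 detected genes and below 30 % mitochondrial counts.
Differential expression is a per-gene two-sided Wilcoxon rank-sum test
on log-normalised expression (counts scaled to 10,000 per cell, then
``log1p``), gated on the fraction of expressing cells and on the log2
fold-change of group means.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from scipy.io import mmread

__all__ = [
    "LabeledExpressionMatrix",
    "DEGResult",
    "EmptyMatrixError",
    "qc_filter",
    "wilcoxon_deg",
    "lognormalize",
    "read_matrix",
]


class EmptyMatrixError(ValueError):
    """All cells or all genes removed by filtering."""


@dataclass
class LabeledExpressionMatrix:
    """Cells x genes counts with per-cell group/lineage labels.

    ``counts`` may be dense or ``scipy.sparse``; rows are cells.
    ``mito_flag`` marks mitochondrial genes (used for the QC fraction).
    """

    counts: np.ndarray | sp.spmatrix
    gene_names: np.ndarray
    cell_group: np.ndarray     # per cell: "disease" or "control"
    cell_lineage: np.ndarray   # per cell lineage label
    mito_flag: np.ndarray      # per gene bool

    def __post_init__(self) -> None:
        self.gene_names = np.asarray(self.gene_names, dtype=object)
        self.cell_group = np.asarray(self.cell_group, dtype=object)
        self.cell_lineage = np.asarray(self.cell_lineage, dtype=object)
        self.mito_flag = np.asarray(self.mito_flag, dtype=bool)
        n_cells, n_genes = self.counts.shape
        if len(self.gene_names) != n_genes or len(self.mito_flag) != n_genes:
            raise ValueError("gene annotation length mismatch")
        if len(self.cell_group) != n_cells or len(self.cell_lineage) != n_cells:
            raise ValueError("cell annotation length mismatch")
        if len(set(self.gene_names)) != n_genes:
            raise ValueError("gene names must be unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    def dense_counts(self) -> np.ndarray:
        if sp.issparse(self.counts):
            return np.asarray(self.counts.todense(), dtype=float)
        return np.asarray(self.counts, dtype=float)


@dataclass
class DEGResult:
    """Per-gene differential-expression outcome."""

    gene: str
    log_fc: float         # log2 fold-change disease vs control
    pct_disease: float    # fraction of disease cells expressing
    pct_control: float
    p_value: float
    direction: str        # "up" (disease-high) or "down"


def read_matrix(matrix_path: str | Path, meta_path: str | Path,
                genes_path: str | Path | None = None,
                mito_prefix: str = "MT-") -> LabeledExpressionMatrix:
    """Load a counts matrix plus cell metadata.

    ``matrix_path`` may be MatrixMarket triplets (genes x cells, the
    sparse-matrix convention of single-cell pipelines, with a gene-name
    sidecar file) or a dense CSV with cells as rows and a header of gene
    names.  Metadata TSV needs columns ``barcode, group, lineage``.
    """
    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        if genes_path is None:
            raise ValueError("MTX input requires a gene-name sidecar file")
        counts = sp.csr_matrix(mmread(matrix_path)).T  # -> cells x genes
        gene_names = np.loadtxt(genes_path, dtype=str, ndmin=1)
    else:
        frame = pd.read_csv(matrix_path, index_col=0)
        counts = frame.to_numpy(dtype=float)
        gene_names = frame.columns.to_numpy(dtype=object)
    meta = pd.read_csv(meta_path, sep="\t")
    return LabeledExpressionMatrix(
        counts=counts,
        gene_names=gene_names,
        cell_group=meta["group"].to_numpy(dtype=object),
        cell_lineage=meta["lineage"].to_numpy(dtype=object),
        mito_flag=np.array([g.startswith(mito_prefix) for g in gene_names]),
    )


def qc_filter(matrix: LabeledExpressionMatrix, min_cells: int = 10,
              min_genes: int = 200, max_mito_frac: float = 0.30) -> LabeledExpressionMatrix:
    """Apply the gene-then-cell quality filters, once each.

    Genes detected (count > 0) in at least ``min_cells`` cells are kept;
    then cells detecting at least ``min_genes`` of the surviving genes
    with a mitochondrial count fraction strictly below ``max_mito_frac``
    are kept.  Raises :class:`EmptyMatrixError` when either step empties
    the matrix.
    """
    counts = matrix.counts
    detected = counts > 0
    if sp.issparse(detected):
        gene_cells = np.asarray(detected.sum(axis=0)).ravel()
    else:
        gene_cells = detected.sum(axis=0)
    gene_keep = gene_cells >= min_cells
    if not gene_keep.any():
        raise EmptyMatrixError("no gene detected in enough cells")

    counts = counts[:, gene_keep]
    mito = matrix.mito_flag[gene_keep]
    detected = counts > 0
    if sp.issparse(counts):
        genes_per_cell = np.asarray(detected.sum(axis=1)).ravel()
        total = np.asarray(counts.sum(axis=1)).ravel()
        mito_total = np.asarray(counts[:, mito].sum(axis=1)).ravel() if mito.any() else np.zeros(counts.shape[0])
    else:
        genes_per_cell = detected.sum(axis=1)
        total = counts.sum(axis=1)
        mito_total = counts[:, mito].sum(axis=1) if mito.any() else np.zeros(counts.shape[0])
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(total > 0, mito_total / np.maximum(total, 1), 1.0)
    cell_keep = (genes_per_cell >= min_genes) & (mito_frac < max_mito_frac)
    if not cell_keep.any():
        raise EmptyMatrixError("no cell passes the QC thresholds")

    return LabeledExpressionMatrix(
        counts=counts[cell_keep],
        gene_names=matrix.gene_names[gene_keep],
        cell_group=matrix.cell_group[cell_keep],
        cell_lineage=matrix.cell_lineage[cell_keep],
        mito_flag=mito,
    )


def lognormalize(counts, scale: float = 1e4) -> np.ndarray:
    """Counts-per-``scale`` per cell followed by ``log1p`` (dense output)."""
    if sp.issparse(counts):
        counts = np.asarray(counts.todense(), dtype=float)
    else:
        counts = np.asarray(counts, dtype=float)
    totals = counts.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    return np.log1p(counts / totals * scale)


def _rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p, tie-corrected with continuity correction."""
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.pvalue)


def wilcoxon_deg(matrix: LabeledExpressionMatrix, min_pct: float = 0.25,
                 min_abs_logfc: float = 0.7, pseudocount: float = 1.0,
                 log_base: float = 2.0, per_lineage: bool = False,
                 disease_label: str = "disease",
                 control_label: str = "control") -> list[DEGResult]:
    """Per-gene Wilcoxon rank-sum differential expression.

    Expression is log-normalised before testing.  The fold-change is
    ``log_b(mean_disease + pseudocount) - log_b(mean_control + pseudocount)``
    on normalised values.  A gene is reported when either group expresses
    it in at least ``min_pct`` of its cells and ``|log_fc|`` reaches
    ``min_abs_logfc``.  With ``per_lineage=True``, testing runs inside
    each lineage and the per-lineage hit lists are unioned (a gene keeps
    the record of its most significant lineage).
    """
    if per_lineage:
        hits: dict[str, DEGResult] = {}
        for lineage in pd.unique(matrix.cell_lineage):
            mask = matrix.cell_lineage == lineage
            sub = LabeledExpressionMatrix(
                counts=matrix.counts[mask],
                gene_names=matrix.gene_names,
                cell_group=matrix.cell_group[mask],
                cell_lineage=matrix.cell_lineage[mask],
                mito_flag=matrix.mito_flag,
            )
            if (sub.cell_group == disease_label).sum() < 2 or \
               (sub.cell_group == control_label).sum() < 2:
                continue
            for res in wilcoxon_deg(sub, min_pct, min_abs_logfc, pseudocount,
                                    log_base, False, disease_label, control_label):
                if res.gene not in hits or res.p_value < hits[res.gene].p_value:
                    hits[res.gene] = res
        return sorted(hits.values(), key=lambda r: r.p_value)

    in_disease = matrix.cell_group == disease_label
    in_control = matrix.cell_group == control_label
    if in_disease.sum() < 2 or in_control.sum() < 2:
        raise ValueError("both groups need at least 2 cells")

    raw = matrix.dense_counts()
    norm = lognormalize(raw)
    # group means (and the fold change) live on the counts-per-10k scale;
    # the rank-sum test runs on the log1p values
    totals = raw.sum(axis=1, keepdims=True)
    totals[totals == 0] = 1.0
    cp10k = raw / totals * 1e4
    log = np.log(log_base)

    results: list[DEGResult] = []
    for j, gene in enumerate(matrix.gene_names):
        x = norm[in_disease, j]
        y = norm[in_control, j]
        pct_d = float((raw[in_disease, j] > 0).mean())
        pct_c = float((raw[in_control, j] > 0).mean())
        if max(pct_d, pct_c) < min_pct:
            continue
        log_fc = float((np.log(cp10k[in_disease, j].mean() + pseudocount)
                        - np.log(cp10k[in_control, j].mean() + pseudocount)) / log)
        if abs(log_fc) < min_abs_logfc:
            continue
        both = np.concatenate([x, y])
        if np.ptp(both) == 0:
            warnings.warn(f"gene {gene}: zero variance in both groups, excluded")
            continue
        results.append(DEGResult(
            gene=str(gene), log_fc=log_fc, pct_disease=pct_d, pct_control=pct_c,
            p_value=_rank_sum_p(x, y), direction="up" if log_fc > 0 else "down",
        ))
    results.sort(key=lambda r: r.p_value)
    return results


def deg_frame(results: list[DEGResult]) -> pd.DataFrame:
    """Tabulate DEG results for TSV export."""
    return pd.DataFrame(
        {
            "gene": [r.gene for r in results],
            "log_fc": [r.log_fc for r in results],
            "pct_disease": [r.pct_disease for r in results],
            "pct_control": [r.pct_control for r in results],
            "p_value": [r.p_value for r in results],
            "direction": [r.direction for r in results],
        }
    )
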