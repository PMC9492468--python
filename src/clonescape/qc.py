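"""Cell/gene quality filters, immunophenotype gating of malignant cells,
and one-vs-rest marker detection.

Filtering rules: a cell is kept when it carries at least ``min_umis`` UMIs
over at least ``min_genes`` detected genes and its mitochondrial+ribosomal
count fraction does not exceed ``max_mito_ribo_fraction``; afterwards a
gene is kept when it is expressed (count > 0) in strictly more than
``min_cells_per_gene`` of the retained cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix

__all__ = [
    "QcThresholds",
    "filter_cells_genes",
    "gate_malignant",
    "normalize_log1p",
    "find_markers",
    "bh_adjust",
    "DEFAULT_POSITIVE_GATE",
    "DEFAULT_NEGATIVE_GATE",
]

# CD38+ CD56+ CD138+ / CD19- CD20-  (gene symbols)
DEFAULT_POSITIVE_GATE = ("CD38", "NCAM1", "SDC1")
DEFAULT_NEGATIVE_GATE = ("CD19", "MS4A1")


@dataclass
class QcThresholds:
    min_umis: int = 1000
    min_genes: int = 200
    min_cells_per_gene: int = 3  # strict greater-than
    max_mito_ribo_fraction: float = 0.10  # strict greater-than removal
    separate_mito_ribo: bool = False

    def __post_init__(self):
        if min(self.min_umis, self.min_genes, self.min_cells_per_gene) < 0:
            raise ValueError("thresholds must be non-negative")
        if not (0 <= self.max_mito_ribo_fraction <= 1):
            raise ValueError("max_mito_ribo_fraction must lie in [0, 1]")


def filter_cells_genes(
    m: CountMatrix, t: QcThresholds | None = None
) -> tuple[CountMatrix, pd.DataFrame]:
    """Apply cell then gene QC.  Returns (filtered matrix, removal report).

    The report has one row per removed cell or gene with columns
    ``kind`` (cell/gene), ``id`` and ``reason``.
    """
    t = t or QcThresholds()
    umis = m.umis_per_cell()
    ngenes = m.genes_per_cell()

    report_rows = []
    if t.separate_mito_ribo:
        mito_mask = m.gene_flags["is_mitochondrial"].to_numpy()
        ribo_mask = m.gene_flags["is_ribosomal"].to_numpy()
        totals = umis.astype(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            fm = np.where(totals > 0, np.asarray(m.counts[mito_mask].sum(axis=0)).ravel() / totals, 0)
            fr = np.where(totals > 0, np.asarray(m.counts[ribo_mask].sum(axis=0)).ravel() / totals, 0)
        frac_fail = (fm > t.max_mito_ribo_fraction) | (fr > t.max_mito_ribo_fraction)
    else:
        frac = m.mito_ribo_fraction()
        frac_fail = frac > t.max_mito_ribo_fraction

    keep_cell = (umis >= t.min_umis) & (ngenes >= t.min_genes) & ~frac_fail
    for i, cid in enumerate(m.cell_ids):
        if keep_cell[i]:
            continue
        reasons = []
        if umis[i] < t.min_umis:
            reasons.append(f"umis<{t.min_umis}")
        if ngenes[i] < t.min_genes:
            reasons.append(f"genes<{t.min_genes}")
        if frac_fail[i]:
            reasons.append(f"mito_ribo>{t.max_mito_ribo_fraction}")
        report_rows.append({"kind": "cell", "id": cid, "reason": ";".join(reasons)})

    cells_kept = m.subset(cell_mask=keep_cell)
    # gene filter on the retained population
    prevalence = np.asarray((cells_kept.counts > 0).sum(axis=1)).ravel()
    keep_gene = prevalence > t.min_cells_per_gene
    for j, gid in enumerate(m.subset(cell_mask=keep_cell).gene_ids):
        if not keep_gene[j]:
            report_rows.append(
                {"kind": "gene", "id": gid, "reason": f"cells<={t.min_cells_per_gene}"}
            )
    out = cells_kept.subset(gene_mask=keep_gene)
    if out.shape[0] == 0 or out.shape[1] == 0:
        warnings.warn("QC removed everything: result is empty", stacklevel=2)
    report = pd.DataFrame(report_rows, columns=["kind", "id", "reason"])
    return out, report


def gate_malignant(
    m: CountMatrix,
    positive: tuple = DEFAULT_POSITIVE_GATE,
    negative: tuple = DEFAULT_NEGATIVE_GATE,
) -> pd.Series:
    """Immunophenotype gate: malignant iff every positive gene has count > 0
    and every negative gene has count == 0."""
    pos_idx = m.gene_index(positive)
    neg_idx = m.gene_index(negative)
    dense_pos = m.counts[pos_idx].toarray() > 0
    dense_neg = m.counts[neg_idx].toarray() > 0
    call = dense_pos.all(axis=0) & ~dense_neg.any(axis=0)
    return pd.Series(call, index=pd.Index(m.cell_ids, name="cell"), name="malignant")


def normalize_log1p(m: CountMatrix, scale: float = 1e4) -> np.ndarray:
    """Counts-per-``scale`` then log1p.  Returns a dense genes x cells array."""
    totals = m.umis_per_cell().astype(float)
    totals[totals == 0] = 1.0
    dense = m.counts.toarray().astype(float)
    return np.log1p(dense / totals * scale)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p, float)
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(n)
    out[order] = np.minimum(ranked, 1.0)
    return out


def find_markers(
    m: CountMatrix,
    labels,
    mode: str = "one_vs_rest",
    pseudocount: float = 1.0,
    method: str = "auto",
) -> pd.DataFrame:
    """One-vs-rest Wilcoxon rank-sum markers per cluster.

    Tests every gene's normalized expression in each cluster against all
    other cells (two-sided, mid-ranks; exact enumeration for small
    tie-free groups, normal approximation with continuity correction
    otherwise).  logFC is log2(mean + pseudocount) in-cluster minus the
    same in the rest; p_adj is BH within each cluster.  Rows are sorted by
    cluster then ascending p_adj.
    """
    if mode != "one_vs_rest":
        raise ValueError(f"unsupported mode {mode!r}")
    labels = np.asarray(labels)
    if labels.size != len(m.cell_ids):
        raise ValueError("labels length must equal number of cells")
    clusters = sorted(set(labels.tolist()))
    if len(clusters) < 2:
        raise ValueError("need at least two clusters")
    counts_per = {c: int((labels == c).sum()) for c in clusters}
    small = [c for c, n in counts_per.items() if n < 3]
    if small:
        raise ValueError(f"clusters with fewer than 3 cells: {small}")

    norm = normalize_log1p(m)  # genes x cells
    rows = []
    for cl in clusters:
        in_mask = labels == cl
        x = norm[:, in_mask]
        y = norm[:, ~in_mask]
        res = stats.mannwhitneyu(x, y, axis=1, alternative="two-sided", method=method)
        pvals = np.atleast_1d(res.pvalue)
        mean_in = x.mean(axis=1)
        mean_out = y.mean(axis=1)
        logfc = np.log2(mean_in + pseudocount) - np.log2(mean_out + pseudocount)
        padj = bh_adjust(pvals)
        pct_in = (x > 0).mean(axis=1)
        pct_out = (y > 0).mean(axis=1)
        for g_i, gene in enumerate(m.gene_ids):
            rows.append(
                {
                    "gene": gene,
                    "cluster": cl,
                    "logFC": logfc[g_i],
                    "p_value": pvals[g_i],
                    "p_adj": padj[g_i],
                    "pct_in": pct_in[g_i],
                    "pct_out": pct_out[g_i],
                    "significant": pvals[g_i] < 0.05,
                }
            )
    df = pd.DataFrame(rows)
    return df.sort_values(["cluster", "p_adj", "gene"], kind="stable").reset_index(drop=True)
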