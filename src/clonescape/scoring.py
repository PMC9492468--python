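"""Rank-based single-unit gene-signature scoring and the stemness index.

The signature score is a signed Kolmogorov-Smirnov-style running-sum
statistic over a unit's expression-ranked gene list: walking from the
highest-expressed gene down, the sum gains ``1/|S|`` at member genes and
loses ``1/(G-|S|)`` at non-members; the score is the deviation of maximal
magnitude (positive = members concentrated among highly expressed genes).
A Gaussian-KDE preprocessing step can optionally drop the zero-inflation
mode before ranking; it never alters ranks of the retained genes.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, GeneSet
from .qc import normalize_log1p

__all__ = [
    "ks_walk_score",
    "signature_score",
    "stemness_index",
    "cell_cycle_score",
]


def ks_walk_score(values: np.ndarray, member_mask: np.ndarray) -> float:
    """Signed KS running-sum score for one unit.

    ``values``: expression over all genes; ``member_mask``: boolean mask of
    signature members.  Ties are broken by original gene order (stable),
    so any strictly monotone transform of ``values`` leaves the score
    unchanged.
    """
    values = np.asarray(values, float)
    member_mask = np.asarray(member_mask, bool)
    g = values.size
    n_mem = int(member_mask.sum())
    if n_mem == 0:
        raise ValueError("no signature gene present")
    if n_mem == g:
        raise ValueError("signature covers every gene; score undefined")
    order = np.argsort(-values, kind="stable")
    steps = np.where(member_mask[order], 1.0 / n_mem, -1.0 / (g - n_mem))
    walk = np.cumsum(steps)
    i = int(np.argmax(np.abs(walk)))
    return float(walk[i])


def _as_unit_by_gene(data) -> pd.DataFrame:
    """Coerce input to a units x genes expression frame."""
    if isinstance(data, CountMatrix):
        norm = normalize_log1p(data)  # genes x cells
        return pd.DataFrame(norm.T, index=data.cell_ids, columns=data.gene_ids)
    if isinstance(data, pd.DataFrame):
        return data
    raise TypeError("expected CountMatrix or units x genes DataFrame")


def _kde_zero_mode_mask(values: np.ndarray) -> np.ndarray:
    """Mask of genes outside the lowest-density-supported zero mode.

    Gaussian KDE (Silverman bandwidth) over the unit's expression; genes
    below the first local density minimum are treated as the
    zero-inflation mode and dropped.  Falls back to keeping everything
    when no interior minimum exists.
    """
    vals = np.asarray(values, float)
    if np.ptp(vals) == 0:
        return np.ones(vals.size, bool)
    kde = stats.gaussian_kde(vals, bw_method="silverman")
    grid = np.linspace(vals.min(), vals.max(), 256)
    dens = kde(grid)
    interior = np.where((dens[1:-1] < dens[:-2]) & (dens[1:-1] <= dens[2:]))[0]
    if interior.size == 0:
        return np.ones(vals.size, bool)
    cutoff = grid[interior[0] + 1]
    mask = vals > cutoff
    if mask.sum() < 3:  # degenerate split, keep all
        return np.ones(vals.size, bool)
    return mask


def signature_score(
    data,
    signature: GeneSet,
    kde_filter: bool = False,
) -> pd.DataFrame:
    """Score every unit (cell or sample) against one signature.

    Returns a DataFrame indexed by unit with columns ``signature``,
    ``raw`` and ``scaled`` (cohort min-max to [0, 1]).
    """
    expr = _as_unit_by_gene(data)
    members = np.array([g in signature.genes for g in expr.columns])
    if not members.any():
        raise ValueError(f"no gene of signature {signature.name!r} present")
    raws = np.empty(len(expr))
    mat = expr.to_numpy(float)
    for i in range(mat.shape[0]):
        vals, mask = mat[i], members
        if np.ptp(vals) == 0:
            raise ValueError(f"unit {expr.index[i]!r} has all-equal expression")
        if kde_filter:
            keep = _kde_zero_mode_mask(vals)
            keep |= mask  # members always stay rankable
            vals, mask = vals[keep], mask[keep]
        raws[i] = ks_walk_score(vals, mask)
    lo, hi = raws.min(), raws.max()
    if hi > lo:
        scaled = (raws - lo) / (hi - lo)
    else:
        warnings.warn("degenerate cohort: all raw scores equal", stacklevel=2)
        scaled = np.full_like(raws, 0.5)
    return pd.DataFrame(
        {"signature": signature.name, "raw": raws, "scaled": scaled},
        index=pd.Index(expr.index, name="unit"),
    )


def stemness_index(data, weights: GeneSet) -> pd.DataFrame:
    """Spearman correlation of each unit's expression with signature weights.

    Returns DataFrame with ``raw`` in [-1, 1] and ``scaled`` (cohort
    min-max).  Requires >= 3 weighted genes present.
    """
    if weights.weights is None:
        raise ValueError("stemness signature requires per-gene weights")
    expr = _as_unit_by_gene(data)
    genes = [g for g in expr.columns if g in weights.weights]
    if len(genes) < 3:
        raise ValueError(f"only {len(genes)} weighted genes present; need >= 3")
    w = np.array([weights.weights[g] for g in genes], float)
    sub = expr[genes].to_numpy(float)
    raws = np.array([stats.spearmanr(sub[i], w).statistic for i in range(sub.shape[0])])
    lo, hi = raws.min(), raws.max()
    if hi > lo:
        scaled = (raws - lo) / (hi - lo)
    else:
        warnings.warn("degenerate cohort: all stemness indices equal", stacklevel=2)
        scaled = np.full_like(raws, 0.5)
    return pd.DataFrame(
        {"raw": raws, "scaled": scaled}, index=pd.Index(expr.index, name="unit")
    )


def cell_cycle_score(m: CountMatrix, cycle_sets: list) -> pd.DataFrame:
    """Per-cell signature scores for each provided cycle gene set (long format)."""
    frames = [signature_score(m, s) for s in cycle_sets]
    return pd.concat(frames).rename_axis("unit").reset_index()
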