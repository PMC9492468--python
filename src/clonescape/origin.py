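"""Malignant-origin abundance scoring, dominance, and four-class typing.

Per sample, abundance of the type-I and type-IX progenitor signatures is
computed with the rank/KS scorer; the dominance score is exactly
``abundance_I - abundance_IX``; positivity of each abundance against a
cohort threshold yields one of four classes: double_positive,
double_negative, I_only, IX_only.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import GeneSet
from .scoring import signature_score

__all__ = ["extract_origin_markers", "type_origin"]

CLASSES = ("double_positive", "double_negative", "I_only", "IX_only")


def extract_origin_markers(
    markers: pd.DataFrame,
    type_i_cluster: str,
    type_ix_cluster: str,
    logfc_min: float = 1.0,
    padj_max: float = 0.05,
) -> tuple[GeneSet, GeneSet]:
    """Marker gene sets of the two origin clusters (logFC strictly > logfc_min,
    p_adj < padj_max).  Overlapping genes are allowed but reported."""
    sets = []
    for cl, name in ((type_i_cluster, "type_I"), (type_ix_cluster, "type_IX")):
        sub = markers[markers["cluster"] == cl]
        if len(sub) == 0:
            raise ValueError(f"cluster {cl!r} absent from marker table")
        genes = set(sub[(sub["logFC"] > logfc_min) & (sub["p_adj"] < padj_max)]["gene"])
        if not genes:
            raise ValueError(f"no marker of {cl!r} passes logFC > {logfc_min}")
        sets.append(GeneSet(name, frozenset(genes)))
    overlap = sets[0].genes & sets[1].genes
    if overlap:
        import warnings

        warnings.warn(f"{len(overlap)} genes shared between origin marker sets")
    return sets[0], sets[1]


def _positivity_threshold(values: np.ndarray, rule: str, q: float) -> float:
    if rule == "cohort_median":
        return float(np.median(values))
    if rule == "zero":
        return 0.0
    if rule == "quantile":
        return float(np.quantile(values, q))
    raise ValueError(f"unknown positivity rule {rule!r}")


def type_origin(
    cohort_expr: pd.DataFrame,
    set_i: GeneSet,
    set_ix: GeneSet,
    positivity: str = "cohort_median",
    quantile: float = 0.5,
) -> pd.DataFrame:
    """Per-sample origin scores and class.

    ``cohort_expr`` is samples x genes.  Positivity means strictly above
    the per-set cohort threshold.  Returns a DataFrame indexed by sample
    with abundance_I, abundance_IX, dominance, positive_I, positive_IX,
    origin_class, and the thresholds used.
    """
    if positivity == "cohort_median" and len(cohort_expr) < 2:
        raise ValueError("median positivity rule needs a cohort of >= 2 samples")
    ab_i = signature_score(cohort_expr, set_i)["raw"].to_numpy()
    ab_ix = signature_score(cohort_expr, set_ix)["raw"].to_numpy()
    thr_i = _positivity_threshold(ab_i, positivity, quantile)
    thr_ix = _positivity_threshold(ab_ix, positivity, quantile)
    pos_i = ab_i > thr_i
    pos_ix = ab_ix > thr_ix
    cls = np.where(
        pos_i & pos_ix, "double_positive",
        np.where(~pos_i & ~pos_ix, "double_negative",
                 np.where(pos_i, "I_only", "IX_only")),
    )
    return pd.DataFrame(
        {
            "abundance_I": ab_i,
            "abundance_IX": ab_ix,
            "dominance": ab_i - ab_ix,
            "positive_I": pos_i,
            "positive_IX": pos_ix,
            "origin_class": cls,
            "threshold_I": thr_i,
            "threshold_IX": thr_ix,
        },
        index=pd.Index(cohort_expr.index, name="sample"),
    )
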