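"""Three-detector consensus framework for ligand-receptor communication.

Detectors:

1. ``detect_joint_expression`` -- permutation test on joint ligand/receptor
   expression between an ordered cluster pair (label-shuffling null).
2. ``detect_deg_match`` -- deterministic matching of marker/highly-expressed
   genes through the ligand-receptor database.
3. ``detect_crosstalk_hyper`` -- per cluster pair, an upper-tail
   hypergeometric test of the overlap between ligand-positive and
   receptor-positive database pairs, gated jointly with an empirical null
   built from degree-preserving rewirings of the bipartite
   ligand-receptor network.

An event reported by at least two detectors is a high-confidence
(consensus) communication event.  Cluster pairs are ordered: the ligand
comes from the source cluster, the receptor from the target; autocrine
(source == target) pairs are included.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import CountMatrix, LigandReceptorDB, LRPair
from .qc import bh_adjust, normalize_log1p

__all__ = [
    "hypergeom_upper_tail",
    "ClusterExpressionProfile",
    "build_profiles",
    "detect_joint_expression",
    "detect_deg_match",
    "randomize_lr_network",
    "detect_crosstalk_hyper",
    "consensus",
]

EVENT_KEY = ["source", "target", "ligand", "receptor"]


def hypergeom_upper_tail(k: int, N: int, K: int, n: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n); the convention used by the
    crosstalk detector (k = 0 gives 1 exactly)."""
    if k <= 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


@dataclass
class ClusterExpressionProfile:
    cluster: str
    mean_expr: pd.Series  # gene -> mean normalized expression
    expr_fraction: pd.Series  # gene -> fraction of cells with count > 0
    expressed_genes: set = field(default_factory=set)
    deg_genes: set = field(default_factory=set)

    @property
    def gene_list(self) -> set:
        """Union list used by the DEG-match and hypergeometric detectors."""
        return self.deg_genes | self.expressed_genes


def build_profiles(
    m: CountMatrix,
    labels,
    markers: pd.DataFrame | None = None,
    deg_padj: float = 0.05,
    deg_logfc: float = 0.25,
    highly_expressed: str = "top_decile",
    expr_fraction_gate: float = 0.10,
) -> dict:
    """Build one expression profile per cluster.

    ``highly_expressed`` selects the gate for the expressed-gene list:
    ``top_decile`` (top 10% of the cluster's mean normalized expression),
    ``expr_fraction`` (expressed in >= ``expr_fraction_gate`` of cells) or
    ``union`` of both.
    """
    labels = np.asarray(labels)
    norm = normalize_log1p(m)
    profiles = {}
    for cl in sorted(set(labels.tolist())):
        mask = labels == cl
        mean_expr = pd.Series(norm[:, mask].mean(axis=1), index=m.gene_ids)
        frac = pd.Series(
            np.asarray((m.counts[:, mask] > 0).mean(axis=1)).ravel(), index=m.gene_ids
        )
        by_decile = set(mean_expr[mean_expr >= mean_expr.quantile(0.9)].index)
        by_frac = set(frac[frac >= expr_fraction_gate].index)
        if highly_expressed == "top_decile":
            expressed = by_decile
        elif highly_expressed == "expr_fraction":
            expressed = by_frac
        elif highly_expressed == "union":
            expressed = by_decile | by_frac
        else:
            raise ValueError(f"unknown highly_expressed mode {highly_expressed!r}")
        deg = set()
        if markers is not None:
            sub = markers[
                (markers["cluster"] == cl)
                & (markers["p_adj"] < deg_padj)
                & (markers["logFC"] > deg_logfc)
            ]
            deg = set(sub["gene"])
        profiles[cl] = ClusterExpressionProfile(cl, mean_expr, frac, expressed, deg)
    return profiles


def _receptor_strength(pair: LRPair, mean_expr: pd.Series) -> float:
    """Receptor-side expression; multi-subunit complexes use the weakest subunit."""
    return min(float(mean_expr.get(g, 0.0)) for g in pair.receptor_genes)


def _pair_strength(pair: LRPair, source: ClusterExpressionProfile,
                   target: ClusterExpressionProfile) -> float:
    return 0.5 * (
        float(source.mean_expr.get(pair.ligand, 0.0))
        + _receptor_strength(pair, target.mean_expr)
    )


# ---------------------------------------------------------------------------
# Detector 1: joint-expression permutation test
# ---------------------------------------------------------------------------

def detect_joint_expression(
    m: CountMatrix,
    labels,
    db: LigandReceptorDB,
    n_perm: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
    min_expr_fraction: float = 0.10,
    bh: bool = True,
    min_cells: int = 3,
) -> pd.DataFrame:
    """Permutation test on summed ligand+receptor mean expression.

    A (source, target, ligand, receptor) candidate is tested only when the
    ligand is expressed in >= ``min_expr_fraction`` of source cells and
    every receptor subunit in >= the same fraction of target cells.  The
    null shuffles cluster labels ``n_perm`` times;
    p = (1 + #{null >= observed}) / (n_perm + 1).  Returns all tested
    candidates; rows with ``selected`` are the emitted events.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    labels = np.asarray(labels)
    sizes = pd.Series(labels).value_counts()
    small = sizes[sizes < min_cells].index.tolist()
    if small:
        warnings.warn(f"excluding clusters with fewer than {min_cells} cells: {small}")
    clusters = sorted(c for c in sizes.index if c not in small)
    keep = np.isin(labels, clusters)
    labels = labels[keep]
    sub = m.subset(cell_mask=keep)

    measured = set(sub.gene_ids)
    pairs = [
        p for p in db.pairs
        if p.ligand in measured and all(g in measured for g in p.receptor_genes)
    ]
    needed = sorted({p.ligand for p in pairs} | {g for p in pairs for g in p.receptor_genes})
    if not needed:
        return pd.DataFrame(columns=EVENT_KEY + ["statistic", "p_joint", "p_joint_adj",
                                                 "mean_strength", "selected"])
    gidx = sub.gene_index(needed)
    gpos = {g: i for i, g in enumerate(needed)}
    norm = normalize_log1p(sub)[gidx, :]  # needed genes x cells
    detected = (sub.counts[gidx, :] > 0).toarray()

    lab_codes = pd.Categorical(labels, categories=clusters).codes
    n_cells, n_cl = labels.size, len(clusters)
    onehot = np.zeros((n_cells, n_cl))
    onehot[np.arange(n_cells), lab_codes] = 1.0
    onehot /= onehot.sum(axis=0, keepdims=True)
    means = norm @ onehot  # gene x cluster mean normalized expression
    fracs = detected @ onehot

    rows = []
    for p in pairs:
        li = gpos[p.ligand]
        ridx = [gpos[g] for g in p.receptor_genes]
        for si, s in enumerate(clusters):
            if fracs[li, si] < min_expr_fraction:
                continue
            for ti, t in enumerate(clusters):
                if any(fracs[r, ti] < min_expr_fraction for r in ridx):
                    continue
                stat = means[li, si] + min(means[r, ti] for r in ridx)
                strength = 0.5 * (means[li, si] + min(means[r, ti] for r in ridx))
                rows.append((s, t, p.ligand, p.receptor, li, tuple(ridx), si, ti,
                             stat, strength))
    if not rows:
        return pd.DataFrame(columns=EVENT_KEY + ["statistic", "p_joint", "p_joint_adj",
                                                 "mean_strength", "selected"])

    rng = np.random.default_rng(seed)
    exceed = np.zeros(len(rows))
    obs = np.array([r[8] for r in rows])
    perm = np.arange(n_cells)
    for _ in range(n_perm):
        rng.shuffle(perm)
        pm = norm @ onehot[perm]
        null = np.array(
            [pm[r[4], r[6]] + min(pm[j, r[7]] for j in r[5]) for r in rows]
        )
        exceed += null >= obs
    pvals = (1.0 + exceed) / (n_perm + 1.0)
    padj = bh_adjust(pvals) if bh else pvals
    df = pd.DataFrame(
        {
            "source": [r[0] for r in rows],
            "target": [r[1] for r in rows],
            "ligand": [r[2] for r in rows],
            "receptor": [r[3] for r in rows],
            "statistic": obs,
            "p_joint": pvals,
            "p_joint_adj": padj,
            "mean_strength": [r[9] for r in rows],
        }
    )
    df["selected"] = df["p_joint_adj"] < alpha
    return df.sort_values(EVENT_KEY, kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Detector 2: DEG / highly-expressed matching
# ---------------------------------------------------------------------------

def detect_deg_match(profiles: dict, db: LigandReceptorDB) -> pd.DataFrame:
    """Emit every DB pair whose ligand sits in the source cluster's
    DEG-or-highly-expressed list and whose receptor (all subunits) sits in
    the target's.  Deterministic; ranked by mean_strength descending with a
    lexicographic tiebreak on the event key."""
    if len(db) == 0:
        raise ValueError("empty ligand-receptor database")
    rows = []
    for s, sp in profiles.items():
        s_list = sp.gene_list
        for t, tp in profiles.items():
            t_list = tp.gene_list
            for p in db.pairs:
                if p.ligand in s_list and all(g in t_list for g in p.receptor_genes):
                    rows.append(
                        {
                            "source": s, "target": t,
                            "ligand": p.ligand, "receptor": p.receptor,
                            "mean_strength": _pair_strength(p, sp, tp),
                            "selected": True,
                        }
                    )
    df = pd.DataFrame(rows, columns=EVENT_KEY + ["mean_strength", "selected"])
    df = df.sort_values(
        ["mean_strength"] + EVENT_KEY, ascending=[False, True, True, True, True],
        kind="stable",
    )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# Detector 3: hypergeometric test against randomized networks
# ---------------------------------------------------------------------------

def randomize_lr_network(
    db: LigandReceptorDB, R: int = 1000, seed: int = 0, swaps_per_edge: int = 10
) -> list:
    """Degree-preserving rewirings of the ligand->receptor bipartite graph.

    Each replicate applies ``swaps_per_edge * |pairs|`` attempted double-edge
    swaps ((l1,r1),(l2,r2) -> (l1,r2),(l2,r1)), rejecting any swap that
    would duplicate an existing edge.  Every ligand keeps its out-degree
    and every receptor its in-degree, exactly.
    """
    edges0 = [p.key() for p in db.pairs]
    if len(edges0) < 2:
        raise ValueError("need at least two ligand-receptor pairs to rewire")
    rng = np.random.default_rng(seed)
    n_attempts = swaps_per_edge * len(edges0)
    out = []
    for _ in range(R):
        edges = list(edges0)
        present = set(edges)
        successes = 0
        idx = rng.integers(0, len(edges), size=(n_attempts, 2))
        for i, j in idx:
            if i == j:
                continue
            (l1, r1), (l2, r2) = edges[i], edges[j]
            if r1 == r2 or l1 == l2:
                continue
            e1, e2 = (l1, r2), (l2, r1)
            if e1 in present or e2 in present:
                continue
            present.discard(edges[i])
            present.discard(edges[j])
            present.add(e1)
            present.add(e2)
            edges[i], edges[j] = e1, e2
            successes += 1
        if successes == 0:
            warnings.warn("no valid double-edge swap found; replicate equals input")
        out.append(LigandReceptorDB([LRPair(l, r) for l, r in edges]))
    return out


def detect_crosstalk_hyper(
    profiles: dict,
    db: LigandReceptorDB,
    randomized: list,
    alpha: float = 0.05,
    bh: bool = True,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Hypergeometric + empirical-network test per ordered cluster pair.

    For a cluster pair (s, t) the universe is the N database pairs with
    both sides measured; K pairs have their ligand in s's gene list, n
    have their receptor in t's list, k have both.  p_hyper is the
    upper-tail P(X >= k); p_empirical is the +1-corrected fraction of
    randomized networks whose mapped-pair count reaches k.  The pair's k
    mapped events are emitted iff both p-values (BH-adjusted across
    cluster pairs when ``bh``) fall below ``alpha``.

    Returns (events, per-pair test records).
    """
    clusters = sorted(profiles)
    some = profiles[clusters[0]]
    measured = set(some.mean_expr.index)
    pairs = [
        p for p in db.pairs
        if p.ligand in measured and all(g in measured for g in p.receptor_genes)
    ]
    gene_code = {g: i for i, g in enumerate(sorted(measured))}
    memb = {
        c: np.isin(np.arange(len(gene_code)), [gene_code[g] for g in profiles[c].gene_list])
        for c in clusters
    }
    lig_code = np.array([gene_code[p.ligand] for p in pairs], int)
    # complexes: receptor membership requires every subunit; encode via per-pair check
    rec_ok = {
        c: np.array(
            [all(memb[c][gene_code[g]] for g in p.receptor_genes) for p in pairs], bool
        )
        for c in clusters
    }

    # randomized replicates as rectangular code matrices (single-gene receptors)
    R = len(randomized)
    if R:
        lig_mat = np.full((R, len(db.pairs)), -1, int)
        rec_mat = np.full((R, len(db.pairs)), -1, int)
        for ri, rdb in enumerate(randomized):
            for ei, p in enumerate(rdb.pairs):
                lig_mat[ri, ei] = gene_code.get(p.ligand, -1)
                rec_mat[ri, ei] = gene_code.get(p.receptor, -1)

    recs, event_rows = [], []
    for s in clusters:
        lig_in = memb[s][lig_code]
        for t in clusters:
            both = lig_in & rec_ok[t]
            N = len(pairs)
            K = int(lig_in.sum())
            n = int(rec_ok[t].sum())
            k = int(both.sum())
            if K == 0 or n == 0 or N == 0:
                p_hyper, p_emp = 1.0, 1.0
            else:
                p_hyper = hypergeom_upper_tail(k, N, K, n)
                if R:
                    ms, mt = memb[s], memb[t]
                    valid = (lig_mat >= 0) & (rec_mat >= 0)
                    mapped = valid & ms[np.clip(lig_mat, 0, None)] & mt[np.clip(rec_mat, 0, None)]
                    k_rand = mapped.sum(axis=1)
                    p_emp = float((1 + (k_rand >= k).sum()) / (R + 1))
                else:
                    p_emp = 1.0
            recs.append(
                {"source": s, "target": t, "N": N, "K": K, "n": n, "k": k,
                 "p_hyper": p_hyper, "p_empirical": p_emp, "R": R}
            )
            event_rows.append((s, t, both))
    records = pd.DataFrame(recs)
    ph = bh_adjust(records["p_hyper"].to_numpy()) if bh else records["p_hyper"].to_numpy()
    pe = (
        bh_adjust(records["p_empirical"].to_numpy()) if bh
        else records["p_empirical"].to_numpy()
    )
    records["p_hyper_adj"] = ph
    records["p_empirical_adj"] = pe
    records["selected"] = (ph < alpha) & (pe < alpha)

    events = []
    for (s, t, both), sel, rec in zip(event_rows, records["selected"], recs):
        if not sel:
            continue
        sp, tp = profiles[s], profiles[t]
        for p, hit in zip(pairs, both):
            if hit:
                events.append(
                    {
                        "source": s, "target": t,
                        "ligand": p.ligand, "receptor": p.receptor,
                        "p_hyper": rec["p_hyper"], "p_empirical": rec["p_empirical"],
                        "mean_strength": _pair_strength(p, sp, tp),
                        "selected": True,
                    }
                )
    events_df = pd.DataFrame(
        events,
        columns=EVENT_KEY + ["p_hyper", "p_empirical", "mean_strength", "selected"],
    )
    return events_df, records


# ---------------------------------------------------------------------------
# Consensus
# ---------------------------------------------------------------------------

DETECTOR_NAMES = ("joint_expression", "deg_match", "crosstalk_hyper")


def consensus(
    joint_events: pd.DataFrame,
    deg_events: pd.DataFrame,
    hyper_events: pd.DataFrame,
) -> pd.DataFrame:
    """Merge the three detectors; consensus = detected by at least two.

    Input frames must carry the event key columns and may carry
    ``selected`` (rows with selected == False are ignored) plus detector
    statistics and ``mean_strength``.  Output is sorted by consensus then
    mean_strength, both descending.
    """
    by_detector = {}
    for name, df in zip(DETECTOR_NAMES, (joint_events, deg_events, hyper_events)):
        if df is None or len(df) == 0:
            by_detector[name] = df.iloc[0:0] if df is not None else pd.DataFrame(columns=EVENT_KEY)
            continue
        d = df[df["selected"]] if "selected" in df.columns else df
        by_detector[name] = d

    merged: dict[tuple, dict] = {}
    for name, df in by_detector.items():
        for _, row in df.iterrows():
            key = tuple(row[c] for c in EVENT_KEY)
            ev = merged.setdefault(
                key,
                {c: v for c, v in zip(EVENT_KEY, key)} | {"detected_by": set(),
                                                          "mean_strength": np.nan},
            )
            ev["detected_by"].add(name)
            for col in ("p_joint", "p_hyper", "p_empirical"):
                if col in row.index and pd.notna(row[col]):
                    ev[col] = row[col]
            if pd.notna(row.get("mean_strength", np.nan)):
                ev["mean_strength"] = row["mean_strength"]
    rows = []
    for ev in merged.values():
        ev = dict(ev)
        ev["n_detectors"] = len(ev["detected_by"])
        ev["consensus"] = ev["n_detectors"] >= 2
        ev["detected_by"] = ",".join(sorted(ev["detected_by"]))
        rows.append(ev)
    cols = EVENT_KEY + ["detected_by", "n_detectors", "consensus",
                        "p_joint", "p_hyper", "p_empirical", "mean_strength"]
    df = pd.DataFrame(rows)
    for c in cols:
        if c not in df.columns:
            df[c] = np.nan
    df = df[cols]
    return df.sort_values(
        ["consensus", "mean_strength"] + EVENT_KEY,
        ascending=[False, False, True, True, True, True],
        kind="stable",
    ).reset_index(drop=True)
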