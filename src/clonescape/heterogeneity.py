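"""Patient-heterogeneity measures: the Pi significance-effect matrix, a
Kohonen self-organizing map over it, and a PC-embedding diversity score."""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import CountMatrix
from .qc import normalize_log1p

__all__ = [
    "compute_pi_matrix",
    "SomModel",
    "train_som",
    "pca_embedding",
    "diversity_score",
]


def compute_pi_matrix(
    markers: pd.DataFrame, epsilon: float = 1e-300
) -> pd.DataFrame:
    """Genes x clusters matrix of Pi = -log10(p_adj) * logFC.

    p_adj is floored at ``epsilon`` before the log so entries stay finite;
    genes absent from a cluster's table are 0.
    """
    df = markers.copy()
    df["pi"] = -np.log10(np.maximum(df["p_adj"].to_numpy(float), epsilon)) * df[
        "logFC"
    ].to_numpy(float)
    pi = df.pivot_table(index="gene", columns="cluster", values="pi", fill_value=0.0)
    pi.index.name = "gene"
    pi.columns.name = "cluster"
    return pi


@dataclass
class SomModel:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols) x n_features
    grid: np.ndarray  # (rows*cols) x 2 integer coordinates
    assignment: pd.DataFrame  # gene -> unit, unit_row, unit_col
    epochs: int
    seed: int

    def bmu(self, x: np.ndarray) -> int:
        d = ((self.codebook - x) ** 2).sum(axis=1)
        return int(np.argmin(d))

    def quantization_error(self, data: np.ndarray) -> float:
        d = np.sqrt(
            (
                (data[:, None, :] - self.codebook[None, :, :]) ** 2
            ).sum(axis=2)
        )
        return float(d.min(axis=1).mean())


def train_som(
    pi: pd.DataFrame,
    rows: int = 10,
    cols: int = 10,
    epochs: int = 100,
    seed: int = 0,
    lr: tuple = (0.5, 0.02),
    sigma: tuple = None,
) -> SomModel:
    """Online Kohonen training with linearly decaying learning rate and a
    Gaussian neighborhood on the (rows x cols) grid.  Deterministic under
    ``seed``; identical input rows map to the same best-matching unit."""
    if rows * cols < 2:
        raise ValueError("grid must have at least 2 units")
    if epochs < 1:
        raise ValueError("epochs must be >= 1")
    data = pi.to_numpy(float)
    if not data.any():
        warnings.warn("all-zero Pi matrix: map is trivial")
    n, d = data.shape
    rng = np.random.default_rng(seed)
    grid = np.array([(r, c) for r in range(rows) for c in range(cols)], float)
    n_units = rows * cols
    codebook = data[rng.integers(0, n, n_units)] + rng.normal(0, 1e-6, (n_units, d))
    sigma0, sigma1 = sigma or (max(rows, cols) / 2.0, 0.5)
    lr0, lr1 = lr
    total = epochs * n
    step = 0
    for _ in range(epochs):
        for i in rng.permutation(n):
            frac = step / max(total - 1, 1)
            eta = lr0 + (lr1 - lr0) * frac
            sig = sigma0 + (sigma1 - sigma0) * frac
            x = data[i]
            bmu = int(np.argmin(((codebook - x) ** 2).sum(axis=1)))
            gd2 = ((grid - grid[bmu]) ** 2).sum(axis=1)
            h = np.exp(-gd2 / (2 * sig**2))
            codebook += eta * h[:, None] * (x - codebook)
            step += 1
    units = np.argmin(
        ((data[:, None, :] - codebook[None, :, :]) ** 2).sum(axis=2), axis=1
    )
    assignment = pd.DataFrame(
        {
            "unit": units,
            "unit_row": grid[units, 0].astype(int),
            "unit_col": grid[units, 1].astype(int),
        },
        index=pi.index,
    )
    return SomModel(rows, cols, codebook, grid.astype(int), assignment, epochs, seed)


def pca_embedding(
    data, d: int = 30, labels=None
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA of normalized expression; returns (cells x d coordinates,
    explained-variance ratios).  ``d`` is capped at min(cells - 1, genes)
    with a warning."""
    if isinstance(data, CountMatrix):
        mat = normalize_log1p(data).T  # cells x genes
        index = pd.Index(data.cell_ids, name="cell")
    else:
        mat = np.asarray(data, float)
        index = pd.RangeIndex(mat.shape[0], name="cell")
        if isinstance(data, pd.DataFrame):
            index = data.index
            mat = data.to_numpy(float)
    cap = min(mat.shape[0] - 1, mat.shape[1])
    if d > cap:
        warnings.warn(f"reducing requested components from {d} to {cap}")
        d = cap
    pca = PCA(n_components=d, svd_solver="full")
    coords = pca.fit_transform(mat)
    cols = [f"PC{i + 1}" for i in range(d)]
    return pd.DataFrame(coords, index=index, columns=cols), pca.explained_variance_ratio_


def diversity_score(coords: pd.DataFrame, patient_labels) -> pd.DataFrame:
    """Per-patient mean Euclidean distance of cells to their centroid in the
    embedding.  Patients with a single cell get NaN and are flagged."""
    labels = np.asarray(patient_labels)
    if labels.size != len(coords):
        raise ValueError("patient_labels length must match embedding rows")
    mat = coords.to_numpy(float)
    rows = []
    for p in sorted(set(labels.tolist())):
        sub = mat[labels == p]
        if sub.shape[0] < 2:
            rows.append({"patient": p, "score": np.nan, "n_cells": sub.shape[0],
                         "d": mat.shape[1]})
            continue
        centroid = sub.mean(axis=0)
        score = float(np.sqrt(((sub - centroid) ** 2).sum(axis=1)).mean())
        rows.append({"patient": p, "score": score, "n_cells": sub.shape[0],
                     "d": mat.shape[1]})
    return pd.DataFrame(rows).set_index("patient")
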