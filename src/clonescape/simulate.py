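"""Synthetic data generators mirroring the statistical structure the
pipeline stages assume: negative-binomial counts over clusters with planted
marker programs and ligand-receptor links, controllable mitochondrial
fractions, origin-signature gradients across samples, and variant tables
with configurable subclone sharing and substitution spectrum."""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .io import CountMatrix, VariantRecord, VariantSet, flag_genes

__all__ = [
    "SimulationConfig",
    "simulate_counts",
    "simulate_variants",
    "simulate_origin_cohort",
]

SPECTRUM_CLASSES = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}


@dataclass
class SimulationConfig:
    n_clusters: int = 2
    cells_per_cluster: int | list = 100
    n_genes: int = 200
    baseline_mean: float = 1.0
    nb_dispersion: float = 0.5
    marker_spec: dict = field(default_factory=dict)  # cluster -> [(gene, fold)]
    mito_fraction: float = 0.0
    n_mito_genes: int = 5
    planted_links: list = field(default_factory=list)  # (src, tgt, lig, rec, fold)
    n_samples: int = 1  # cells assigned round-robin to samples
    variant_spec: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self):
        if self.n_clusters < 1:
            raise ValueError("n_clusters must be >= 1")
        if not (0 <= self.mito_fraction < 1):
            raise ValueError("mito_fraction must lie in [0, 1)")
        if self.baseline_mean <= 0 or self.nb_dispersion <= 0:
            raise ValueError("baseline_mean and nb_dispersion must be positive")
        for cl, specs in self.marker_spec.items():
            for gene, fold in specs:
                if fold <= 0:
                    raise ValueError(f"non-positive fold for marker {gene} in {cl}")
        if np.isscalar(self.cells_per_cluster):
            self.cells_per_cluster = [int(self.cells_per_cluster)] * self.n_clusters
        if len(self.cells_per_cluster) != self.n_clusters:
            raise ValueError("cells_per_cluster length must equal n_clusters")

    def rng(self, stage: str) -> np.random.Generator:
        """Per-stage derived substream so stages re-run independently."""
        tag = zlib.crc32(stage.encode())  # stable across processes
        ss = np.random.SeedSequence(self.seed, spawn_key=(tag,))
        return np.random.default_rng(ss)


def cluster_names(n: int) -> list:
    return [f"C{i}" for i in range(n)]


def gene_names(config: SimulationConfig) -> list:
    """Regular genes G0000.. plus a trailing mitochondrial block (MT- prefix)."""
    n_reg = config.n_genes
    names = [f"G{i:04d}" for i in range(n_reg)]
    if config.mito_fraction > 0:
        names += [f"MT-S{i}" for i in range(config.n_mito_genes)]
    return names


def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    """Gamma-Poisson mixture: mean mu, variance mu + dispersion * mu^2."""
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def simulate_counts(config: SimulationConfig) -> tuple[CountMatrix, pd.DataFrame]:
    """Draw a clustered NB count matrix; returns (matrix, truth table).

    The truth table lists every planted effect with columns
    ``effect`` (marker/link_ligand/link_receptor), ``cluster``, ``gene``,
    ``fold`` and, for links, ``partner_cluster``/``partner_gene``.
    """
    rng = config.rng("counts")
    genes = gene_names(config)
    gene_idx = {g: i for i, g in enumerate(genes)}
    clusters = cluster_names(config.n_clusters)
    truth_rows = []

    # per-cluster mean vectors
    base = np.full(len(genes), config.baseline_mean, float)
    n_mito = config.n_mito_genes if config.mito_fraction > 0 else 0
    if n_mito:
        # scale mito block so its expected share of the cell total is mito_fraction
        non_mito_total = config.baseline_mean * config.n_genes
        mito_total = non_mito_total * config.mito_fraction / (1 - config.mito_fraction)
        base[config.n_genes:] = mito_total / n_mito

    means = {cl: base.copy() for cl in clusters}
    for cl, specs in config.marker_spec.items():
        for gene, fold in specs:
            if gene not in gene_idx:
                raise ValueError(f"marker gene {gene} not among simulated genes")
            means[cl][gene_idx[gene]] *= fold
            truth_rows.append(
                {"effect": "marker", "cluster": cl, "gene": gene, "fold": fold,
                 "partner_cluster": "", "partner_gene": ""}
            )
    for src, tgt, lig, rec, fold in config.planted_links:
        for g in (lig, rec):
            if g not in gene_idx:
                raise ValueError(f"planted link gene {g} not among simulated genes")
        means[src][gene_idx[lig]] *= fold
        means[tgt][gene_idx[rec]] *= fold
        truth_rows.append(
            {"effect": "link_ligand", "cluster": src, "gene": lig, "fold": fold,
             "partner_cluster": tgt, "partner_gene": rec}
        )
        truth_rows.append(
            {"effect": "link_receptor", "cluster": tgt, "gene": rec, "fold": fold,
             "partner_cluster": src, "partner_gene": lig}
        )

    blocks, labels = [], []
    for cl, n_cells in zip(clusters, config.cells_per_cluster):
        mean_mat = np.tile(means[cl], (n_cells, 1))
        blocks.append(_nb_draw(rng, mean_mat, config.nb_dispersion))
        labels += [cl] * n_cells
    counts = np.concatenate(blocks, axis=0).T  # genes x cells
    cell_ids = [f"cell{i:05d}" for i in range(counts.shape[1])]
    samples = [f"S{(i % max(config.n_samples, 1)) + 1}" for i in range(len(cell_ids))]
    meta = pd.DataFrame(
        {"sample": samples, "cluster": labels}, index=pd.Index(cell_ids, name="cell")
    )
    m = CountMatrix(
        sp.csr_matrix(counts), genes, cell_ids, meta, flag_genes(genes)
    )
    truth = pd.DataFrame(
        truth_rows,
        columns=["effect", "cluster", "gene", "fold", "partner_cluster", "partner_gene"],
    )
    return m, truth


def _spectrum_alleles(rng: np.random.Generator, cls: str) -> tuple[str, str]:
    """Pick ref/alt realizing a pyrimidine class, randomly strand-flipped."""
    ref, alt = cls.split(">")
    if rng.random() < 0.5:
        ref, alt = _COMPLEMENT[ref], _COMPLEMENT[alt]
    return ref, alt


def simulate_variants(config: SimulationConfig) -> tuple[VariantSet, pd.DataFrame]:
    """Generate bulk + per-subclone variant tables.

    ``variant_spec`` keys: ``n_samples`` (default 1), ``n_subclones``,
    ``n_shared``, ``n_private`` (per subclone), ``spectrum`` (dict over the
    six pyrimidine classes, default uniform), ``genome_size_mb``.
    Bulk is the union of subclones; shared variants appear in every
    subclone.  Returns (VariantSet, truth table with columns sample,
    chrom, pos, ref, alt, shared, subclones).
    """
    spec = config.variant_spec
    rng = config.rng("variants")
    n_samples = int(spec.get("n_samples", 1))
    n_sub = int(spec.get("n_subclones", 2))
    if n_sub < 1:
        raise ValueError("need at least one subclone")
    n_shared = int(spec.get("n_shared", 2))
    n_private = int(spec.get("n_private", 3))
    genome_mb = float(spec.get("genome_size_mb", 3000.0))
    spectrum = spec.get("spectrum") or {c: 1 / 6 for c in SPECTRUM_CLASSES}
    classes = list(spectrum)
    probs = np.array([spectrum[c] for c in classes], float)
    probs = probs / probs.sum()

    records, truth_rows = [], []
    for s in range(n_samples):
        sample = f"P{s + 1}"
        used_pos = set()

        def new_site():
            while True:
                chrom = f"chr{rng.integers(1, 23)}"
                pos = int(rng.integers(1, 10_000_000))
                if (chrom, pos) not in used_pos:
                    used_pos.add((chrom, pos))
                    return chrom, pos

        subclones = [f"s{j + 1}" for j in range(n_sub)]
        for _ in range(n_shared):
            cls = classes[rng.choice(len(classes), p=probs)]
            ref, alt = _spectrum_alleles(rng, cls)
            chrom, pos = new_site()
            for sub in subclones:
                records.append(VariantRecord(chrom, pos, ref, alt, sample, f"subclone:{sub}"))
            records.append(VariantRecord(chrom, pos, ref, alt, sample, "bulk"))
            truth_rows.append(
                {"sample": sample, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                 "shared": True, "subclones": ",".join(subclones)}
            )
        for sub in subclones:
            for _ in range(n_private):
                cls = classes[rng.choice(len(classes), p=probs)]
                ref, alt = _spectrum_alleles(rng, cls)
                chrom, pos = new_site()
                records.append(VariantRecord(chrom, pos, ref, alt, sample, f"subclone:{sub}"))
                records.append(VariantRecord(chrom, pos, ref, alt, sample, "bulk"))
                truth_rows.append(
                    {"sample": sample, "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                     "shared": False, "subclones": sub}
                )
    truth = pd.DataFrame(
        truth_rows, columns=["sample", "chrom", "pos", "ref", "alt", "shared", "subclones"]
    )
    return VariantSet(records, genome_mb), truth


def simulate_origin_cohort(
    n_samples: int = 100,
    n_genes: int = 300,
    set_size: int = 20,
    gradient: tuple = (1.0, 4.0),
    noise_dispersion: float = 0.3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Sample x gene expression cohort with planted origin-signature gradients.

    Two disjoint signature blocks (type I and type IX) get per-sample
    multipliers drawn uniformly from ``gradient`` (independently per type).
    Returns (expression DataFrame, truth DataFrame with the multipliers,
    dict of the two gene lists).
    """
    rng = np.random.default_rng(seed)
    genes = [f"G{i:04d}" for i in range(n_genes)]
    set_i = genes[:set_size]
    set_ix = genes[set_size: 2 * set_size]
    lo, hi = gradient
    mult_i = rng.uniform(lo, hi, n_samples)
    mult_ix = rng.uniform(lo, hi, n_samples)
    base = np.full(n_genes, 10.0)
    expr = np.empty((n_samples, n_genes))
    for s in range(n_samples):
        mean = base.copy()
        mean[:set_size] *= mult_i[s]
        mean[set_size: 2 * set_size] *= mult_ix[s]
        expr[s] = _nb_draw(rng, mean, noise_dispersion)
    samples = [f"S{i + 1:03d}" for i in range(n_samples)]
    df = pd.DataFrame(expr, index=pd.Index(samples, name="sample"), columns=genes)
    truth = pd.DataFrame(
        {"multiplier_I": mult_i, "multiplier_IX": mult_ix},
        index=pd.Index(samples, name="sample"),
    )
    return df, truth, {"type_I": set_i, "type_IX": set_ix}
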