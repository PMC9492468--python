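"""Readers/writers for the on-disk formats shared by every pipeline stage.

All tabular outputs are plain TSV with a header; sparse count matrices use
the MatrixMarket triplet convention (matrix.mtx + barcodes.tsv +
features.tsv) or a dense genes-by-cells TSV.  Matrices are always indexed
by identifier, never by file order.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

__all__ = [
    "CountMatrix",
    "GeneSet",
    "LRPair",
    "LigandReceptorDB",
    "VariantRecord",
    "VariantSet",
    "read_count_matrix",
    "write_count_matrix",
    "read_gene_sets",
    "read_lr_database",
    "write_lr_database",
    "read_variants",
    "write_variants",
]

DEFAULT_MITO_PREFIXES = ("MT-",)
DEFAULT_RIBO_PREFIXES = ("RPS", "RPL")


@dataclass
class CountMatrix:
    """Gene x cell UMI count matrix with cell metadata and gene flags.

    ``counts`` is stored sparse (CSR) with genes as rows, cells as columns.
    ``cell_meta`` is indexed by cell id; ``gene_flags`` by gene id with
    boolean columns ``is_mitochondrial`` and ``is_ribosomal``.
    """

    counts: sp.csr_matrix
    gene_ids: list[str]
    cell_ids: list[str]
    cell_meta: pd.DataFrame = None
    gene_flags: pd.DataFrame = None

    def __post_init__(self) -> None:
        self.counts = sp.csr_matrix(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.cell_ids, name="cell"))
        if self.gene_flags is None:
            self.gene_flags = flag_genes(self.gene_ids)
        self.validate()

    def validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if n_genes != len(self.gene_ids) or n_cells != len(self.cell_ids):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise ValueError("duplicate gene identifiers")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            raise ValueError("duplicate cell identifiers")
        data = self.counts.data
        if data.size and (data < 0).any():
            raise ValueError("negative counts")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("non-integer counts")
        if list(self.gene_flags.index) != self.gene_ids:
            self.gene_flags = self.gene_flags.reindex(self.gene_ids)
            if self.gene_flags.isna().any().any():
                raise ValueError("gene_flags missing for some genes")
        if not self.cell_meta.index.equals(pd.Index(self.cell_ids)):
            self.cell_meta = self.cell_meta.reindex(self.cell_ids)

    # -- convenience views -------------------------------------------------
    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    def gene_index(self, genes: Iterable[str]) -> np.ndarray:
        lookup = {g: i for i, g in enumerate(self.gene_ids)}
        missing = [g for g in genes if g not in lookup]
        if missing:
            raise KeyError(f"genes not in matrix: {missing}")
        return np.array([lookup[g] for g in genes], dtype=int)

    def umis_per_cell(self) -> np.ndarray:
        return np.asarray(self.counts.sum(axis=0)).ravel()

    def genes_per_cell(self) -> np.ndarray:
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    def mito_ribo_fraction(self) -> np.ndarray:
        """Per-cell fraction of counts on mitochondrial or ribosomal genes."""
        totals = self.umis_per_cell().astype(float)
        mask = (
            self.gene_flags["is_mitochondrial"] | self.gene_flags["is_ribosomal"]
        ).to_numpy()
        flagged = np.asarray(self.counts[mask, :].sum(axis=0)).ravel()
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(totals > 0, flagged / totals, 0.0)
        return frac

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        gm = np.ones(len(self.gene_ids), bool) if gene_mask is None else np.asarray(gene_mask)
        cm = np.ones(len(self.cell_ids), bool) if cell_mask is None else np.asarray(cell_mask)
        return CountMatrix(
            counts=self.counts[gm][:, cm],
            gene_ids=[g for g, k in zip(self.gene_ids, gm) if k],
            cell_ids=[c for c, k in zip(self.cell_ids, cm) if k],
            cell_meta=self.cell_meta.loc[cm].copy(),
            gene_flags=self.gene_flags.loc[gm].copy(),
        )


def flag_genes(
    gene_ids: Sequence[str],
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    ribo_prefixes: Sequence[str] = DEFAULT_RIBO_PREFIXES,
    mito_override: Iterable[str] = (),
    ribo_override: Iterable[str] = (),
) -> pd.DataFrame:
    """Prefix-based mito/ribo flags with explicit override lists."""
    mito_override = set(mito_override)
    ribo_override = set(ribo_override)
    is_mito = [
        g in mito_override or any(g.upper().startswith(p) for p in mito_prefixes)
        for g in gene_ids
    ]
    is_ribo = [
        g in ribo_override or any(g.upper().startswith(p) for p in ribo_prefixes)
        for g in gene_ids
    ]
    return pd.DataFrame(
        {"is_mitochondrial": is_mito, "is_ribosomal": is_ribo},
        index=pd.Index(gene_ids, name="gene"),
    )


@dataclass(frozen=True)
class GeneSet:
    name: str
    genes: frozenset
    weights: dict | None = None

    def __post_init__(self):
        object.__setattr__(self, "genes", frozenset(self.genes))
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")
        if self.weights is not None:
            if set(self.weights) != set(self.genes):
                raise ValueError(
                    f"weights of {self.name!r} must cover exactly the member genes"
                )
            vals = np.array(list(self.weights.values()), float)
            if not np.all(np.isfinite(vals)):
                raise ValueError(f"non-finite weights in {self.name!r}")


@dataclass(frozen=True)
class LRPair:
    ligand: str
    receptor: str
    subunits: tuple = ()
    source: str = ""

    def __post_init__(self):
        object.__setattr__(self, "subunits", tuple(self.subunits))

    @property
    def receptor_genes(self) -> tuple:
        """All genes that must be expressed on the receiving side."""
        return self.subunits if self.subunits else (self.receptor,)

    def key(self) -> tuple:
        return (self.ligand, self.receptor)


@dataclass
class LigandReceptorDB:
    """Directed ligand -> receptor interaction universe."""

    pairs: list

    def __post_init__(self):
        seen = {}
        for p in self.pairs:
            if p.key() in seen:
                raise ValueError(f"duplicate ligand-receptor record {p.key()}")
            if p.subunits is not None and len(p.subunits) == 0 and p.subunits != ():
                raise ValueError("empty subunit list")
            seen[p.key()] = p
        self.pairs = [seen[k] for k in sorted(seen)]

    def __len__(self):
        return len(self.pairs)

    def keys(self) -> set:
        return {p.key() for p in self.pairs}

    def genes(self) -> set:
        out = set()
        for p in self.pairs:
            out.add(p.ligand)
            out.update(p.receptor_genes)
        return out


@dataclass(frozen=True, order=True)
class VariantRecord:
    chrom: str
    pos: int
    ref: str
    alt: str
    sample: str
    level: str  # "bulk" or "subclone:<id>"

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError(f"position must be >= 1, got {self.pos}")
        if self.ref == self.alt:
            raise ValueError(f"ref equals alt at {self.chrom}:{self.pos}")

    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class VariantSet:
    records: list
    genome_size_mb: float

    def __post_init__(self):
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be positive")
        full = [(r.chrom, r.pos, r.ref, r.alt, r.sample, r.level) for r in self.records]
        if len(set(full)) != len(full):
            raise ValueError("duplicate variant records")
        self.records = sorted(self.records)

    def samples(self) -> list:
        return sorted({r.sample for r in self.records})

    def subclones(self, sample: str) -> list:
        return sorted(
            {
                r.level.split(":", 1)[1]
                for r in self.records
                if r.sample == sample and r.level.startswith("subclone:")
            }
        )


# ---------------------------------------------------------------------------
# Count matrices
# ---------------------------------------------------------------------------

def read_count_matrix(
    path,
    dialect: str = "mtx_triplet",
    mito_prefixes: Sequence[str] = DEFAULT_MITO_PREFIXES,
    ribo_prefixes: Sequence[str] = DEFAULT_RIBO_PREFIXES,
    mito_override: Iterable[str] = (),
    ribo_override: Iterable[str] = (),
) -> CountMatrix:
    """Read a gene x cell count matrix.

    ``mtx_triplet`` expects a directory holding ``matrix.mtx``,
    ``barcodes.tsv`` and ``features.tsv`` (10x layout, genes as matrix
    rows).  ``dense_tsv`` expects a single TSV with genes as rows and a
    header row of cell barcodes.
    """
    path = Path(path)
    if dialect == "mtx_triplet":
        mat = sp.csr_matrix(scipy.io.mmread(path / "matrix.mtx"))
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        features = pd.read_csv(path / "features.tsv", sep="\t", header=None)[0].tolist()
        if mat.shape != (len(features), len(barcodes)):
            raise ValueError(
                f"matrix shape {mat.shape} does not match features/barcodes "
                f"({len(features)}, {len(barcodes)})"
            )
        gene_ids, cell_ids = features, barcodes
        meta_path = path / "cell_meta.tsv"
        cell_meta = (
            pd.read_csv(meta_path, sep="\t", index_col=0) if meta_path.exists() else None
        )
    elif dialect == "dense_tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        mat = sp.csr_matrix(df.to_numpy())
        gene_ids = df.index.tolist()
        cell_ids = df.columns.tolist()
        cell_meta = None
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    flags = flag_genes(gene_ids, mito_prefixes, ribo_prefixes, mito_override, ribo_override)
    return CountMatrix(mat.astype(np.int64), gene_ids, cell_ids, cell_meta, flags)


def write_count_matrix(m: CountMatrix, path, dialect: str = "mtx_triplet") -> None:
    path = Path(path)
    if dialect == "mtx_triplet":
        path.mkdir(parents=True, exist_ok=True)
        scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts))
        pd.Series(m.cell_ids).to_csv(path / "barcodes.tsv", sep="\t", header=False, index=False)
        pd.Series(m.gene_ids).to_csv(path / "features.tsv", sep="\t", header=False, index=False)
        if len(m.cell_meta.columns):
            m.cell_meta.to_csv(path / "cell_meta.tsv", sep="\t")
    elif dialect == "dense_tsv":
        df = pd.DataFrame(
            m.counts.toarray(), index=pd.Index(m.gene_ids, name="gene"), columns=m.cell_ids
        )
        df.to_csv(path, sep="\t")
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# Gene sets
# ---------------------------------------------------------------------------

def read_gene_sets(path) -> dict:
    """Read gene sets from GMT or long TSV.

    GMT: one set per line, ``name<TAB>description<TAB>gene1<TAB>gene2...``.
    Long TSV: header ``set<TAB>gene[<TAB>weight]``.
    """
    path = Path(path)
    text = path.read_text().strip()
    if not text:
        raise ValueError(f"empty gene set file {path}")
    first = text.splitlines()[0].split("\t")
    sets: dict[str, GeneSet] = {}
    if first[0] in {"set", "signature", "name"} and "gene" in first:
        df = pd.read_csv(path, sep="\t")
        name_col, gene_col = first[0], "gene"
        for name, grp in df.groupby(name_col, sort=True):
            weights = None
            if "weight" in grp.columns and grp["weight"].notna().all():
                weights = dict(zip(grp[gene_col], grp["weight"].astype(float)))
            sets[name] = GeneSet(name, frozenset(grp[gene_col]), weights)
    else:  # GMT
        for line in text.splitlines():
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line!r}")
            sets[parts[0]] = GeneSet(parts[0], frozenset(g for g in parts[2:] if g))
    return sets


# ---------------------------------------------------------------------------
# Ligand-receptor database
# ---------------------------------------------------------------------------

def read_lr_database(path) -> LigandReceptorDB:
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    if len(df) == 0:
        raise ValueError(f"empty ligand-receptor table {path}")
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise ValueError(f"ligand-receptor table missing column {col!r}")
    pairs, seen = [], set()
    for _, row in df.iterrows():
        subunits: tuple = ()
        if "subunits" in df.columns and isinstance(row.get("subunits"), str) and row["subunits"]:
            subunits = tuple(s for s in row["subunits"].split(",") if s)
        source = str(row["source"]) if "source" in df.columns and pd.notna(row.get("source")) else ""
        pair = LRPair(str(row["ligand"]), str(row["receptor"]), subunits, source)
        if pair.key() in seen:
            continue
        seen.add(pair.key())
        pairs.append(pair)
    return LigandReceptorDB(pairs)


def write_lr_database(db: LigandReceptorDB, path) -> None:
    rows = [
        {
            "ligand": p.ligand,
            "receptor": p.receptor,
            "subunits": ",".join(p.subunits),
            "source": p.source,
        }
        for p in db.pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Variants
# ---------------------------------------------------------------------------

_VARIANT_COLUMNS = ["chrom", "pos", "ref", "alt", "sample", "level"]


def read_variants(path, genome_size_mb: float) -> VariantSet:
    """Read a six-column variant TSV or a minimal VCF subset.

    VCF rows are split into one record per alternate allele; the sample id
    is taken from a ``SAMPLE`` info-style 8th column or defaults to the
    file stem, level defaults to ``bulk``.
    """
    if genome_size_mb <= 0:
        raise ValueError("genome_size_mb must be positive")
    path = Path(path)
    lines = path.read_text().splitlines()
    records: list[VariantRecord] = []
    errors: list[str] = []
    if any(l.startswith("##fileformat=VCF") for l in lines[:5]):
        for ln, line in enumerate(lines, 1):
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                errors.append(f"line {ln}: too few columns")
                continue
            chrom, pos_s, _id, ref, alts = f[0], f[1], f[2], f[3], f[4]
            sample = f[7] if len(f) > 7 and f[7] not in {".", ""} else path.stem
            try:
                pos = int(pos_s)
                for alt in alts.split(","):
                    records.append(VariantRecord(chrom, pos, ref, alt, sample, "bulk"))
            except (ValueError, TypeError) as exc:
                errors.append(f"line {ln}: {exc}")
    else:
        df = pd.read_csv(path, sep="\t")
        missing = [c for c in _VARIANT_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"variant table missing columns {missing}")
        for ln, row in enumerate(df.itertuples(index=False), 2):
            try:
                records.append(
                    VariantRecord(
                        str(row.chrom), int(row.pos), str(row.ref), str(row.alt),
                        str(row.sample), str(row.level),
                    )
                )
            except (ValueError, TypeError) as exc:
                errors.append(f"line {ln}: {exc}")
    if errors:
        raise ValueError("unparseable variant rows: " + "; ".join(errors))
    return VariantSet(records, genome_size_mb)


def write_variants(v: VariantSet, path) -> None:
    rows = [
        {"chrom": r.chrom, "pos": r.pos, "ref": r.ref, "alt": r.alt,
         "sample": r.sample, "level": r.level}
        for r in v.records
    ]
    pd.DataFrame(rows, columns=_VARIANT_COLUMNS).to_csv(path, sep="\t", index=False)
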