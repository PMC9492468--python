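"""Stage orchestration behind a single YAML configuration.

Each stage reads the shared input matrix (plus any upstream stage TSVs),
writes its own TSV outputs into the run directory, and contributes to a
JSON manifest recording parameters, per-stage seeds and input digests.
Reruns with an identical config and seed reproduce identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import crosstalk as ct
from . import heterogeneity as het
from . import io as cio
from . import origin as org
from . import qc as cqc
from . import variants as var

STAGES = ("qc", "markers", "crosstalk", "origin", "heterogeneity", "burden")
_DEPENDENCIES = {
    "crosstalk": ("markers",),
    "origin": ("markers",),
    "heterogeneity": ("markers",),
}


@dataclass
class PipelineConfig:
    counts_path: str
    out_dir: str
    counts_dialect: str = "mtx_triplet"
    lr_db_path: str | None = None
    variants_path: str | None = None
    genome_size_mb: float = 3000.0
    cluster_column: str = "cluster"
    patient_column: str = "sample"
    qc: dict = field(default_factory=dict)
    detectors: dict = field(default_factory=dict)
    origin: dict = field(default_factory=dict)
    heterogeneity: dict = field(default_factory=dict)
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        try:
            return cls(**raw)
        except TypeError as exc:
            raise ValueError(f"invalid config field: {exc}") from exc

    def validate(self) -> None:
        if not Path(self.counts_path).exists():
            raise FileNotFoundError(f"counts_path not found: {self.counts_path}")
        for name in ("lr_db_path", "variants_path"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"{name} not found: {p}")
        if self.genome_size_mb <= 0:
            raise ValueError("genome_size_mb must be positive")

    def stage_seed(self, stage: str) -> int:
        return int(
            np.random.default_rng(
                np.random.SeedSequence(self.seed, spawn_key=(zlib.crc32(stage.encode()),))
            ).integers(0, 2**31)
        )


def _digest(path: Path) -> str:
    h = hashlib.sha256()
    if path.is_dir():
        for p in sorted(path.rglob("*")):
            if p.is_file():
                h.update(p.name.encode())
                h.update(p.read_bytes())
    else:
        h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: PipelineConfig, stages=STAGES) -> dict:
    """Run the requested stages in order; returns the manifest dict."""
    config.validate()
    stages = list(stages)
    ran: set[str] = set()
    for s in stages:
        if s not in STAGES:
            raise ValueError(f"unknown stage {s!r}")
        for dep in _DEPENDENCIES.get(s, ()):
            if dep not in ran and dep not in stages[: stages.index(s)]:
                raise ValueError(f"stage {s!r} requires {dep!r} to run first")
        ran.add(s)

    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "stages": stages,
        "inputs": {"counts": _digest(Path(config.counts_path))},
        "parameters": {},
        "outputs": {},
    }
    if config.lr_db_path:
        manifest["inputs"]["lr_db"] = _digest(Path(config.lr_db_path))
    if config.variants_path:
        manifest["inputs"]["variants"] = _digest(Path(config.variants_path))

    m = cio.read_count_matrix(config.counts_path, dialect=config.counts_dialect)
    markers = None
    filtered = m

    if "qc" in stages:
        thresholds = cqc.QcThresholds(**config.qc)
        filtered, report = cqc.filter_cells_genes(m, thresholds)
        report.to_csv(out / "qc_report.tsv", sep="\t", index=False)
        manifest["parameters"]["qc"] = vars(thresholds)
        manifest["outputs"]["qc"] = ["qc_report.tsv"]

    labels = filtered.cell_meta[config.cluster_column].to_numpy()

    if "markers" in stages:
        markers = cqc.find_markers(filtered, labels)
        markers.to_csv(out / "markers.tsv", sep="\t", index=False)
        manifest["outputs"]["markers"] = ["markers.tsv"]

    if "crosstalk" in stages:
        if config.lr_db_path is None:
            raise ValueError("crosstalk stage requires lr_db_path")
        if markers is None:
            markers = pd.read_csv(out / "markers.tsv", sep="\t")
        det = dict(config.detectors)
        n_perm = int(det.get("n_perm", 1000))
        n_random = int(det.get("n_random", 1000))
        alpha = float(det.get("alpha", 0.05))
        db = cio.read_lr_database(config.lr_db_path)
        seed = config.stage_seed("crosstalk")
        profiles = ct.build_profiles(filtered, labels, markers)
        joint = ct.detect_joint_expression(
            filtered, labels, db, n_perm=n_perm, alpha=alpha, seed=seed
        )
        deg = ct.detect_deg_match(profiles, db)
        randomized = ct.randomize_lr_network(db, R=n_random, seed=seed + 1)
        hyper, records = ct.detect_crosstalk_hyper(profiles, db, randomized, alpha=alpha)
        events = ct.consensus(joint, deg, hyper)
        events.to_csv(out / "events.tsv", sep="\t", index=False)
        records.to_csv(out / "pair_tests.tsv", sep="\t", index=False)
        manifest["parameters"]["crosstalk"] = {
            "n_perm": n_perm, "n_random": n_random, "alpha": alpha, "seed": seed
        }
        manifest["outputs"]["crosstalk"] = ["events.tsv", "pair_tests.tsv"]

    if "origin" in stages:
        if markers is None:
            markers = pd.read_csv(out / "markers.tsv", sep="\t")
        o = dict(config.origin)
        cl_i = o.get("cluster_i")
        cl_ix = o.get("cluster_ix")
        if cl_i is None or cl_ix is None:
            raise ValueError("origin stage requires origin.cluster_i and origin.cluster_ix")
        set_i, set_ix = org.extract_origin_markers(
            markers, cl_i, cl_ix, logfc_min=float(o.get("logfc_min", 1.0))
        )
        norm = cqc.normalize_log1p(filtered)
        expr = pd.DataFrame(norm.T, index=filtered.cell_ids, columns=filtered.gene_ids)
        expr[config.patient_column] = filtered.cell_meta[config.patient_column].to_numpy()
        cohort = expr.groupby(config.patient_column).mean()
        scores = org.type_origin(
            cohort, set_i, set_ix, positivity=o.get("positivity", "cohort_median")
        )
        scores.to_csv(out / "origin_scores.tsv", sep="\t")
        manifest["parameters"]["origin"] = o
        manifest["outputs"]["origin"] = ["origin_scores.tsv"]

    if "heterogeneity" in stages:
        if markers is None:
            markers = pd.read_csv(out / "markers.tsv", sep="\t")
        h = dict(config.heterogeneity)
        pi = het.compute_pi_matrix(markers)
        pi.to_csv(out / "pi_matrix.tsv", sep="\t")
        som = het.train_som(
            pi,
            rows=int(h.get("som_rows", 10)),
            cols=int(h.get("som_cols", 10)),
            epochs=int(h.get("epochs", 100)),
            seed=config.stage_seed("heterogeneity"),
        )
        som.assignment.to_csv(out / "som_assignments.tsv", sep="\t")
        coords, _ = het.pca_embedding(filtered, d=int(h.get("pcs", 30)))
        patients = filtered.cell_meta[config.patient_column].to_numpy()
        div = het.diversity_score(coords, patients)
        div.to_csv(out / "diversity.tsv", sep="\t")
        manifest["parameters"]["heterogeneity"] = h
        manifest["outputs"]["heterogeneity"] = [
            "pi_matrix.tsv", "som_assignments.tsv", "diversity.tsv"
        ]

    if "burden" in stages:
        if config.variants_path is None:
            raise ValueError("burden stage requires variants_path")
        vs = cio.read_variants(config.variants_path, config.genome_size_mb)
        var.compute_tmb(vs).to_csv(out / "tmb.tsv", sep="\t", index=False)
        var.substitution_spectrum(vs).to_csv(out / "spectrum.tsv", sep="\t", index=False)
        share_rows = []
        for sample in vs.samples():
            if len(vs.subclones(sample)) < 2:
                continue
            part = var.partition_sharing(vs, sample)
            part["presence"].to_csv(out / f"presence_{sample}.tsv", sep="\t")
            for key in sorted(part["shared"]):
                share_rows.append({"sample": sample, "variant": key, "bucket": "shared"})
            for sub, keys in sorted(part["restricted"].items()):
                for key in sorted(keys):
                    share_rows.append(
                        {"sample": sample, "variant": key, "bucket": f"restricted:{sub}"}
                    )
        pd.DataFrame(share_rows, columns=["sample", "variant", "bucket"]).to_csv(
            out / "sharing.tsv", sep="\t", index=False
        )
        manifest["parameters"]["burden"] = {"genome_size_mb": config.genome_size_mb}
        manifest["outputs"]["burden"] = ["tmb.tsv", "spectrum.tsv", "sharing.tsv"]

    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, default=str)
    return manifest
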