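# clonescape

Single-cell clonal-evolution analysis toolkit: quality control and marker
detection, rank-based (KS running-sum) gene-signature scoring, a
three-detector consensus framework for ligand–receptor cell–cell
communication (joint-expression permutation test, DEG matching, and a
hypergeometric test gated by degree-preserving randomizations of the
ligand–receptor network), malignant-origin dominance scoring and typing,
SOM-based heterogeneity contribution, a PC-embedding intratumor diversity
score, and tumor-mutational-burden / shared-variant analysis at bulk and
subclone level. A synthetic-data module generates fixtures with planted
structure so the whole pipeline is testable offline.

## Layout

| module                      | contents |
|-----------------------------|----------|
| `clonescape.io`             | CountMatrix / GeneSet / LigandReceptorDB / VariantSet types; MatrixMarket+barcodes/features, dense TSV, GMT, LR-TSV, variant TSV / minimal VCF readers and writers |
| `clonescape.simulate`       | negative-binomial cluster simulator with planted markers, mito fractions and ligand–receptor links; variant tables with configurable subclone sharing and substitution spectrum; origin-gradient cohorts |
| `clonescape.qc`             | cell/gene filters (UMIs ≥ 1000, genes ≥ 200, mito+ribo ≤ 10%, gene in > 3 cells), immunophenotype gating, one-vs-rest Wilcoxon markers with BH correction |
| `clonescape.scoring`        | signed KS running-sum signature scores, optional KDE zero-mode filter, Spearman-weight stemness index |
| `clonescape.crosstalk`      | the three detectors, bipartite double-edge-swap network randomization, hypergeometric pair tests, any-two-detectors consensus |
| `clonescape.origin`         | origin marker extraction (logFC > 1), abundance, dominance = abundance_I − abundance_IX, four-class typing |
| `clonescape.heterogeneity`  | Pi = −log10(p_adj)·logFC matrix, Kohonen SOM, PCA embedding + per-patient diversity score |
| `clonescape.variants`       | TMB (variants per megabase), six-class pyrimidine substitution spectrum, shared vs subclone-restricted partition |
| `clonescape.pipeline`       | YAML-configured stage orchestration with per-stage seeds and a JSON run manifest |

## CLI

```bash
clonescape simulate  --config sim.yaml --out simdata
clonescape qc        --counts simdata/counts --out qcout \
                     --min-umis 1000 --min-genes 200 --max-mito 0.10
clonescape markers   --counts simdata/counts --labels clusters.tsv --out markers.tsv
clonescape score     --counts simdata/counts --signatures sets.gmt --out scores.tsv
clonescape crosstalk --counts simdata/counts --labels clusters.tsv \
                     --markers markers.tsv --db lr.tsv \
                     --n-random 1000 --alpha 0.05 --seed 7 --out ctout
clonescape run       --config run.yaml \
                     --stages qc,markers,crosstalk,origin,heterogeneity,burden
```

`run.yaml` fields mirror `clonescape.pipeline.PipelineConfig`
(counts_path, out_dir, lr_db_path, variants_path, qc/detectors/origin/
heterogeneity sections, genome_size_mb, seed).

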