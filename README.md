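# gcaqtl

Simulation and QTL dissection of **general combining ability (GCA)** in
RIL × tester (North Carolina Design II) mating designs.

The package covers the full analysis chain for a biparental RIL panel
crossed to a set of testers and evaluated in multi-environment trials:

1. **`gcaqtl.simdata`** — RIL genome simulation (explicit meioses under the
   Haldane model, single-seed descent), NCII crossing tables, and
   multi-environment phenotype generation with known truth (per-line GCA,
   genetic variances, QTL positions).
2. **`gcaqtl.genmap`** — genetic maps (cM + Mb), genotype matrices,
   ancestry probabilities at markers and pseudomarkers, and file I/O
   (rotated cross CSV, map TSV).
3. **`gcaqtl.quantgen`** — per-entry adjusted means (BLUEs by fixed-effect
   least squares), ANOVA method-of-moments variance components,
   broad-sense heritability (entry-mean formula), testcross gain and
   correlations with significance stars.
4. **`gcaqtl.combining`** — GCA/SCA effect estimation from the hybrid cell
   means, the combined NCII ANOVA with the σ²GCA/σ²SCA ratio, and
   per-line GCA response vectors for QTL mapping.
5. **`gcaqtl.qtlscan`** — regression (Haley–Knott) interval mapping and
   composite interval mapping with stepwise cofactor selection,
   permutation-based genome-wide LOD thresholds, 1.5-LOD support
   intervals, PVE and signed additive effects, QTL calling.
6. **`gcaqtl.compare`** — cross-environment QTL consolidation,
   co-localization (interval overlap or peaks ≤ 20 Mb apart),
   per se vs GCA classification, and pleiotropy grouping by transitive
   closure.
7. **`gcaqtl.pipeline`** — a configuration-driven, fully deterministic
   end-to-end runner with checksummed output manifests.

## Tests

```sh
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance criteria, including the
simulation-based calibration checks (permutation threshold type-I error,
paper-scale parameter recovery); the whole suite runs on one CPU in a few
minutes.

## CLI

```sh
gcaqtl run-all --config config.yaml        # simulate -> analyse -> compare
gcaqtl simulate --seed 1 --n-lines 328 --out cross.csv
gcaqtl blue --pheno phenotypes.csv --trait kt --out blues.csv
gcaqtl gca  --pheno phenotypes.csv --trait kt --out gca.csv
gcaqtl scan --cross cross.csv --response kt --threshold 3.0 --out scan.tsv
gcaqtl perm --cross cross.csv --response kt --n-perm 1000
gcaqtl compare --perse perse_qtl.tsv --gca gca_qtl.tsv --out classes.tsv
```

`run-all` writes scan curves, GCA/SCA tables, heritability estimates,
consolidated QTL, classification tables, a truth-vs-found recovery
summary and a `manifest.json` with SHA-256 checksums; identical
config + seed reproduces every file byte-for-byte.

Example YAML config:

```yaml
seed: 1
n_lines: 328
testers: [T1, T2]
locations: [loc1, loc2]
years: [y1, y2]
reps_per_env: 2
markers_per_chrom: 30
n_chromosomes: 10
chrom_length_cm: 150.0
n_cofactors: 3
window_cm: 10.0
lod_threshold: 3.0
out_dir: run1
```

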