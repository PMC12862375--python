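# imodkit

Modularize a bulk RNA-seq compendium into **iModulons** — independently
modulated gene sets — and analyze the resulting transcriptional regulatory
network (TRN) structure.

Large single-protocol expression compendia (hundreds of samples over diverse
growth conditions) contain statistically independent transcriptional signals
that map onto the organism's regulatory machinery. `imodkit` extracts these
signals with robust independent component analysis and provides the full
downstream toolchain used in iModulon studies of bacterial transcriptomes:

- **compendium I/O and QC** — log2(TPM) matrices, metadata, mapped-read and
  replicate-correlation gates, per-project reference-condition centering;
- **robust ICA** (`ica_core`) — the centered matrix **X** (genes × samples)
  is decomposed as **X ≈ M·A**, where columns of **M** are gene-weight
  signatures and rows of **A** their activities. FastICA restarts are pooled
  and clustered (distance 1 − |Pearson r|, DBSCAN) so only reproducible
  components survive; the dimensionality is chosen by a grid scan that
  maximizes the count of reproducible multi-gene components;
- **membership** — per-component weight thresholds from the iterative
  D'Agostino K² normality test turn **M** into a binarized gene-membership
  matrix;
- **enrichment** — Fisher exact (hypergeometric) tests of memberships
  against a regulon table, BH-corrected over single regulators and pairwise
  regulator combinations; categorization into Regulatory / Biological /
  Technical / Uncharacterized;
- **activities** — differential iModulon activation (DiMA) against a
  replicate-derived log-normal null, stimulon clustering of activity rows,
  and sample-profile clustering of replicate-averaged activity columns;
- **crosscompare** — matching iModulon structures from two datasets by
  gene-weight correlation, with per-gene differential membership (DiMM)
  tables;
- **synthetic_data** — a generator of compendia with planted **M**, **A**,
  replicate/project design, stimulon structure, and a concordant regulon
  table, so every stage is testable against known ground truth.

## Worked example

```python
import imodkit as ik

spec = ik.SyntheticSpec(seed=1)          # 1000 genes, 10 modules, 120 samples
truth, expr = ik.simulate(spec)

dec = ik.robust_decompose(expr, dimension=10, n_runs=12, seed=1)
membership, thresholds = ik.binarize_m(dec.M)

print(f"robust components: {dec.n_components}")
print(f"explained variance: {ik.explained_variance(expr, dec.M, dec.A):.3f}")

stats = ik.membership_stats(membership)
print(f"genes in >=1 iModulon: {stats.n_genes_in_any}/{stats.n_genes_universe}")
print(f"median iModulon size: {stats.median_size:.0f}")

report = ik.recovery_report(truth, dec.M, membership)
print(f"median |r| vs planted modules: {report['max_abs_r'].median():.3f}")
print(f"median membership Jaccard:     {report['best_jaccard'].median():.3f}")

table = ik.build_imodulon_table(membership, dec.M, truth.trn)
print(table["category"].value_counts().to_string())
```

Output:

```
robust components: 10
explained variance: 0.918
genes in >=1 iModulon: 163/1000
median iModulon size: 16
median |r| vs planted modules: 0.992
median membership Jaccard:     1.000
category
Regulatory    10
```

All 10 planted modules are recovered as reproducible components (weight
correlation 0.99 with the planted signatures, exact gene membership), the
decomposition captures ~92% of expression variance (10% of variance is
injected noise), and with an error-free regulon table every component is
annotated as a Regulatory iModulon enriched for its own planted regulator.

## Command line

A thin CLI wraps the library:

```bash
imodkit simulate  --seed 1 --outdir bundle/
imodkit qc        --config config.yaml
imodkit center    --config config.yaml
imodkit decompose --config config.yaml
imodkit annotate  --config config.yaml
imodkit activities --config config.yaml
imodkit compare   --config config.yaml --other-m other_M.tsv
imodkit report    --config config.yaml
```

Every command logs all resolved parameters and appends a `run_log.yaml`
(config echo + SHA-256 hash, seeds, wall time) to the output directory, so
any run can be reproduced from its outputs.

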