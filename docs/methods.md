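# Methods

## Model

A reference-centered log2(TPM) compendium **X** (genes × samples) is modeled
as a linear mixture of statistically independent transcriptional signals,

    X ≈ M · A,

where **M** (genes × k) holds each signal's gene weights and **A**
(k × samples) its activity per sample. Independent component analysis is the
estimator: it is appropriate here because regulatory signals are sparse and
heavy-tailed in gene space (a regulator touches a small gene set strongly),
which is exactly the non-Gaussianity ICA exploits. An *iModulon* is one
component together with the gene set that survives its weight threshold; its
activity row quantifies how strongly that gene set is modulated in each
sample relative to the project's reference condition.

## Quality control and centering

Two numeric gates are applied per sample: a minimum number of reads mapped
to coding sequences (default 500 000, strict `<` comparison so the boundary
value passes) and replicate agreement (default Pearson r ≥ 0.95 on log2(TPM)
within a replicate group; samples without any replicate are dropped). For
groups larger than two, a sample is kept when its *best* correlation to any
group member clears the bar — the pairwise criterion generalized without
penalizing one bad member's partners. Further upstream gates (e.g. FastQC
verdicts) are accepted as boolean metadata columns rather than recomputed,
since raw reads are out of scope.

Batch effects are removed by subtracting, within every project, the per-gene
arithmetic mean of the project's reference-condition samples. Projects
without an internal reference declare a fallback project whose reference is
used instead. The mean (rather than a single designated sample) is used
because it is the lower-variance estimate of the reference state; the choice
is configurable. Centering is idempotent: re-centering a centered matrix is
a no-op up to 1e-9.

## Robust ICA

FastICA (scikit-learn) is restarted `n_runs` times (default 100; tests and
the acceptance script use 10–12, which is sufficient at the synthetic scale)
with seeds derived from one base seed. Gene-weight columns are unit-L2
normalized, oriented so the largest-|weight| gene is positive (a stable sign
convention), and pooled across converged runs; non-converged runs are
dropped rather than failing the decomposition. Pooled components are
clustered with DBSCAN on the precomputed distance 1 − |Pearson r|
(eps 0.1); a cluster is retained when it contains components from at least
`min_frequency` (default 50%) of the runs, and is represented by its
centrotype — the member with maximal mean |r| to the rest. Activities are
recomputed by pseudoinverse projection, A = M⁺X, so X ≈ M·A holds for the
retained set; this also makes explained variance monotone in the component
subset.

Dimensionality is selected by a grid scan: at each candidate dimension a
robust decomposition is computed, each robust component is classified as
single-gene (≤1 gene survives binarization) or multi-gene, and the smallest
dimension maximizing the multi-gene count wins. Under-decomposition merges
modules (fewer multi-gene components); over-decomposition splits variance
into irreproducible or single-gene directions, so the multi-gene census
plateaus at the intrinsic dimensionality.

Explained variance of a component subset S is
1 − ‖X − M_S·A_S‖²_F / ‖X‖²_F with A_S refit by projection, clipped to
[0, 1]; the empty subset is 0 by definition.

## Membership thresholds

Within one component most genes form a near-Gaussian background; members sit
in the tails. The threshold is found by iteratively peeling the
largest-|weight| gene (ties peeled together, making the procedure
order-independent) and re-testing the remainder with D'Agostino's K²
omnibus normality statistic. Removal stops once K² falls below the cutoff
*and stays below it* for a stability window (default 5) of further
removals. The window matters because K² is not monotone along the peeling
path — deleting one extreme gene can transiently cancel the skewness term
while strong outliers remain — and a first-crossing stop would truncate
memberships; on monotone paths the two rules coincide. The reported
threshold is the largest non-member |weight|, so membership is exactly
{genes with |weight| > threshold}. A component whose weights pass the
normality gate immediately (including the degenerate all-equal case) has
empty membership.

The K² cutoff (default 550) is scale-dependent: the statistic grows with the
number of genes, so a cutoff tuned for compendium-scale weight vectors
(thousands of genes) is too strict for small matrices. The package ships
`calibrate_k2_cutoff`, which sweeps cutoffs on data with known modules and
picks the one maximizing mean F1 — the recommended way to set the cutoff for
a new gene universe.

## Enrichment and categorization

Membership sets are tested for regulon over-representation with the
one-sided hypergeometric tail (Fisher exact test for enrichment). The
candidate family per component is every single regulon with at least one
member overlap plus the pairwise intersections and unions of those
regulators; bounding combinations at pairs (configurable) keeps the BH
family from exploding combinatorially. p-values are Benjamini-Hochberg
adjusted within the family; the winner is the lowest q, ties broken by
highest F1; nothing is reported when the best q misses the threshold
(default 1e-5). The gene universe defaults to the genes in the expression
matrix — the population actually testable — not all genes ever curated.

Categories are assigned with fixed precedence: **Regulatory** (significant
enrichment) → **Technical** (a single member, or a top weight dominating the
runner-up by ≥5×: such components typically capture noise in one gene) →
**Biological** (a manual functional annotation exists) → **Uncharacterized**.

## Differential iModulon activation (DiMA)

The null for each component is built from biology's own repeats: absolute
activity differences over all within-replicate-group sample pairs across the
compendium (pooling across components is available when pairs are scarce),
plus a 1e-6 floor to tolerate identical replicates, fitted with a
two-parameter log-normal (location 0). For a comparison of two condition
groups, Δ = |mean activity difference|, p = the null's upper tail at Δ, q =
BH across components (the family is the component set of one comparison,
matching how per-comparison results are read), and a call requires both
Δ > `min_delta` (default 5 activity units — a practical-relevance floor) and
q < α (default 0.05).

The log-normal is a deliberately heavy-tailed model of replicate noise: on
Gaussian replicate noise (half-normal differences) its fitted 95th
percentile overshoots the empirical one by roughly two-thirds, making the
p-values conservative. The calibration tests assert exactly this —
conservative, within 2× — and verify tail self-consistency on genuinely
log-normal differences. Stable fits need on the order of hundreds of
replicate pairs; with only ~200 pairs the fitted tail varies enough that a
borderline q can straddle α.

Stimulons are found by average-linkage hierarchical clustering of activity
rows on 1 − r with a configurable cut; sample-profile clustering applies the
same procedure to replicate-averaged activity columns. Constant rows or
columns (undefined correlation) are excluded with a warning.

## Cross-structure comparison

Two weight matrices are aligned on their shared genes (sorted intersection);
every cross pair gets a Pearson r on that set. A component "has a match"
when its best partner exceeds `min_r` (default 0.5) — a census of matched
components, not a one-to-one assignment. Signed r is the default, matching
how matches are usually counted; |r| matching is available because sign
conventions differ between independently fit decompositions. DiMM tables
classify each shared gene as a member of both, either, or neither component
of a pair, using each side's own threshold.

## Synthetic compendium

The generator plants the structure the pipeline assumes, with defaults
chosen once as the study conditions for all tests:

| parameter | default | rationale |
|---|---|---|
| genes | 1000 | large enough for a stable K² background, small enough for fast tests |
| modules | 10, sizes 8–25 | spans the typical iModulon size range around a median of ~10 genes |
| design | 10 projects × 3 conditions × 4 replicates (120 samples) | project/replicate block structure at ~1/5 compendium scale |
| activity scale | 10 | condition effects well above replicate noise, as in real compendia |
| replicate noise sd | 1 | high replicate correlation, matching tight biological replicates |
| expression noise | 10% of signal variance | planted decomposition explains ~90% of variance |
| weights | sign ± (floor 0.25 + Exp(0.5)), unit-norm columns | heavy-tailed sources — the non-Gaussianity ICA needs — with a magnitude floor separating members from background |

Each project's first condition is its reference with condition-level
activity 0, so the generated matrix is already in centered coordinates.
Stimulon groups add a shared per-condition latent factor scaled by a mixing
coefficient — the simplest mechanism producing correlated activities without
shared genes. The regulon table has one regulator per module with
controllable false-negative (member dropout) and false-positive (random
addition) rates. All stages draw from per-stage streams derived from one
seed, so identical specs reproduce bit-identical data.

What the generator does **not** emulate: count-level RNA-seq noise (negative
binomial reads), library-size and normalization artifacts, correlated
(batch-structured) expression noise, overlapping regulon hierarchies, and
condition-dependent module membership. Passing tests therefore demonstrate
correctness of the algorithms under the stated statistical model, not
end-to-end performance on raw sequencing data.

## Numerical choices and limitations

- FastICA runs with tol 1e-6 and max_iter 1000; non-convergence is flagged
  and the run excluded. At dimensions well above the intrinsic one, all runs
  may fail to converge; the scan treats that dimension as contributing no
  robust components.
- Component order is deterministic: larger clusters first, ties by pool
  position; component ids are C01, C02, ….
- Weight-threshold ties are removed in one step; thresholds are strict
  inequalities, so rescaling a column never changes membership.
- Degenerate inputs: empty robust decompositions return empty matrices with
  a warning (not an exception); constant activity rows are excluded from
  clustering; identical replicates produce a near-zero but valid DiMA null.
- The DiMA "threshold > 5" is interpreted in activity units on Δ, and the
  null from within-replicate-group |differences| per component; both are the
  implemented interpretation of a procedure whose exact recipe is commonly
  cited rather than restated, and both are configurable.
- Tests and the acceptance script run the ICA stages at reduced problem
  sizes (10–12 restarts, ≤1000 genes, ≤120 samples) — the package's own
  choice of desk-scale study conditions; production analyses should use the
  100-restart default and a dimension grid spanning the expected intrinsic
  dimensionality.
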