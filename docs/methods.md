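# Methods

## Featurization

Compounds are described by presence/absence of named substructures given
as SMARTS patterns in an ordered catalog; the catalog position defines the
feature index (1-based in the serialized format). SMILES are parsed and
aromaticity-perceived once with RDKit's default model, so kekulized and
aromatic notations of the same molecule featurize identically — a
precondition for deduplication and featurization to agree.

The shipped default catalog (`src/ocscreen/data/functional_groups.tsv`,
77 entries) is a curated stand-in covering the common organic functional
groups plus drug-relevant metals (Pt, Au, Fe, Ru, As, Ti, Gd, …). All
behavior is parameterized on the catalog, which is a swappable two-column
TSV input; nothing in the code assumes a particular catalog size. Patterns
never observed in a training set are pruned (they carry no information for
the classifier), with an old→new index map returned for audit.

Unparseable SMILES are skipped with a logged warning in batch mode and
fatal in single-compound mode: large public libraries contain malformed
records and a screen must not die on them, while interactive use should
fail loudly.

## Activity classifier

`sklearn.svm.SVC` with an RBF kernel. Cross-validation folds are
stratified by label and shuffled under an explicit seed; stratification
stabilizes accuracy estimates on imbalanced libraries (the convention is a
package choice — plain k-fold is equally defensible). Grid search
evaluates every cell of exponentially growing (C, γ) sequences; the
default coarse grid is C = 2⁻⁵…2¹⁵ × γ = 2⁻¹⁵…2³ (399 cells) and the fine
grid C = 2⁻¹…2⁶ × γ = 2⁻⁵…2⁰ in quarter-exponent steps. Ties are broken
toward smaller C, then smaller γ, preferring smoother models. When no grid
search is run, the reference optimum C = 2^1.5, γ = 2^−1.5 is used.

Class labels are {1, 0} end to end. Prediction is chunked (default
100,000 compounds per block, configurable); chunked and unchunked runs
are label-identical by construction and by test. The persisted model
artifact stores the SHA-256 of the training catalog and the feature
count, and refuses vectors of any other width.

## Evaluation statistics

Sensitivity TP/(TP+FN), specificity TN/(TN+FP) and accuracy
(TP+TN)/total are computed in exact rational arithmetic
(`fractions.Fraction`) and rendered at 9 decimal places, making reported
values bit-stable. The published benchmark table these are checked
against prints two specificity cells that are inconsistent with
TN/(TN+FP) applied to its own printed counts; the implementation follows
the definition and the tests assert the exact ratios, documenting rather
than reproducing the discrepancy.

## Target profiles and deduplication

Interaction records keep only the `experimental` and `database` evidence
channels (the curated, most reliable sources); bioassay records associate
a target when the assay value normalized to micromolar is ≤ 1 μM,
boundary inclusive, with unit dialects resolved on the first letter
('u…'/micro-sign → μM, 'n…' → nM, case-insensitive) to mirror free-text
unit columns in public databases. Protein-to-gene identifier translation
is a generic de-duplicated two-column join; unmapped records are dropped
and counted.

Duplicate detection uses RDKit path fingerprints (linear/branched paths
up to 7 bonds hashed into 1024 bits) — a documented stand-in convention,
since duplicate semantics at Tanimoto = 1 depend on the fingerprint
family. Tanimoto 1 on equal-length bit vectors is bit equality, so
grouping hashes fingerprint bytes instead of an O(n²) scan; the partition
is the transitive closure (union-find), resolving pairwise phrasing into
a well-defined equivalence. Each group collapses to its first-seen
member's id and SMILES, targets are unioned, and every member id is kept
in a `merged_from` audit column. Whether flat/stereo isomer pairs merge
is a property of the fingerprint (which ignores chirality here), not of
the algorithm; callers needing stereo-aware behavior can substitute a
chiral fingerprint.

## PLS target weights and OC_Score

The training matrix holds one row per (compound, indication-class)
instance: class 1 if any indication code is an oral-cavity neoplasm
(ICD10 C00–C06), class 0 for any other C-chapter code, class −1 for
compounds with no cancer indication. A compound active against oral and
other cancers emits two rows (classes 1 and 0) — never 1 and −1 — so
neither signal is lost. Optional prior-knowledge target profiles append
as extra class-1 rows.

The fit is PLS1 with one component: response and predictor columns are
mean-centered, **not** variance-scaled, and the extracted weights are the
first loading-weight vector, unit Euclidean norm, sign along the centered
cross-covariance Xᶜᵀyᶜ. This is the convention of the standard R `pls`
kernel algorithm with default settings, and it is pinned down testably by
a closed-form oracle (w ∝ Xᶜᵀyᶜ) at 1e-10 and cross-checked against
scikit-learn's PLSRegression up to its sign convention. The weight
computation is authored in-package rather than delegated to
scikit-learn because sklearn's singular-vector sign flip can negate the
weight vector wholesale, and the sign of each weight is semantically
load-bearing for the score. Leave-one-out RMSEP is computed for
reporting; weights always come from the full-data fit. All-zero target
columns get weight 0 with a warning; a constant response is an error.

OC_Score is the sum of fitted weights over a compound's target set;
targets without weights contribute 0 and are tallied as unmapped. The
screening cutoff is the mean score of the class-1 training compounds
rounded half-away-from-zero to 2 decimals (a mean of 0.6699 yields the
conventional 0.67 cutoff; the rounding precision is a flag). Selection
is inclusive (score ≥ cutoff). Distribution summaries use R type-7
quantile interpolation, matching R's `summary()`.

## Annotation

Physicochemical properties come from RDKit: molecular weight, Crippen
atom-contribution logP, Lipinski donor/acceptor counts, Ertl
fragment-contribution TPSA, rotatable bonds. Property values are
method-dependent conventions; no published per-compound property value is
treated as a reference quantity. Rule-of-five violations require strict
excess (HBD > 5, HBA > 10, MW > 500, logP > 5), so threshold values
themselves pass; the TPSA poor-absorption flag is inclusive at ≥ 140 Å².
GI50 activity is value ≤ 50 μM (≡ 50,000 nM), inclusive, with the same
unit-dialect rule as above. The undesirable-functional-group screen is
entirely defined by the supplied SMARTS catalog; the shipped default
(20 reactive/promiscuous motifs: acyl halides, epoxides, Michael
acceptors, azo/diazonium, peroxides, …) is a small editable file, and
'MedChem friendly' semantics follow whatever catalog is given.
Unparseable structures are conservatively tagged 'N'.

## Synthetic data: what it emulates, and what it does not

Molecules are assembled from a fixed internal fragment library — an
alkane backbone (3–8 carbons) with functional-group branches attached to
distinct sp3 carbons — rather than random SMILES, so the true feature
vector is exact by construction. The ten fragments are mutually
orthogonal against the generator's catalog (no fragment's molecule
matches another fragment's pattern; asserted by test), and a compound's
activity label is a deterministic function of its features (presence of
any of three designated groups), making classifier test sets separable by
design. One global seed drives independent per-generator streams
(seed, stream-id), so adding a generator never perturbs the others.

Training-matrix defaults are the study conditions: 33 class-1 rows, 100
class-0, 100 class-(−1), 50 targets of which 5 are planted signal,
signal strength 0.9, background presence rate 0.05 (exposed as a
parameter, since no reference value exists for it; 0.05 ≈ 2.5 targets per
compound over 50 targets). An optional extra class-1 row carrying all
signal targets mirrors prior-knowledge augmentation. The interaction
generator plants a configurable fraction (default 0.1) of the compound
universe with experimental-channel interactions covering every signal
protein, giving the end-to-end screen a recoverable ground truth; the
bioassay generator draws values log-uniformly on either side of the
relevant activity cutoff and stores the construction-time flag.

What passing these tests shows: the mechanics — featurization,
CV/grid-search bookkeeping, weight extraction, merging, thresholds —
are correct, and the statistical machinery recovers planted structure at
realistic sample sizes. What it does not show: performance on real
chemistry. Generated molecules are far simpler and less diverse than
drug space, functional groups are independent rather than correlated,
interaction scores carry no confidence-calibration structure, and class
boundaries in real libraries are not feature-deterministic. Published
large-scale counts (tens of millions screened, hundreds selected) depend
on external databases and are out of desk scale by design.

## Numerical choices and degenerate inputs

- Exact rational arithmetic for evaluation metrics; half-away-from-zero
  rendering at 9 decimals.
- PLS oracle tolerance 1e-10 (float64 matvec error at 100×50 is orders
  of magnitude smaller).
- Zero cross-covariance between predictors and response is an error (no
  direction to normalize); all-zero columns get weight 0 with a warning.
- Empty catalogs load with a warning (not an error); an all-zero feature
  matrix prunes to an empty catalog with a warning.
- Tanimoto of two empty fingerprints is defined as 1.0 (identical
  absence of features), so feature-free molecules merge.
- Sparse-format reader enforces 1-based strictly ascending indices.
- Grid-search problem sizes in the tests (dozens of compounds, ≤ 12
  cells) are chosen to exercise every code path at sub-second cost;
  production grids are the 399-cell coarse and 609-cell fine defaults.

## Known limitations

- The default SMARTS catalog is curated for coverage of common chemistry,
  not equivalent to any particular published pattern list; results are
  catalog-relative throughout.
- One PLS component only; no component-count selection. The score is
  linear in targets, so correlated-target redundancy is not modelled.
- Probability calibration, non-RBF kernels and ROC analysis are out of
  scope.
- Stereochemistry is invisible to the default fingerprint, so
  enantiomers merge during deduplication.
- Literature-evidence counting requires network access and is accepted
  only as pre-computed input.
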