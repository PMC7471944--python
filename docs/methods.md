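# Methods

## Problem and model

`mirnaloc` treats subcellular localization of a mature miRNA as eight
independent binary classification problems, one per compartment (axon,
circulating, cytoplasm, exosome, extracellular vesicle, microvesicle,
mitochondrion, nucleus). A sequence may genuinely occupy several
compartments, so the one-vs-rest decomposition with an independent
probability per compartment — rather than a single multi-class softmax — is
the modelling assumption, and predicted probability rows deliberately do
not sum to one. The negative set for each compartment is the pool of
training sequences not annotated there ("rest-of-localizations" design);
a fixed background negative pool is a documented alternative the training
API does not currently implement.

All features derive from overlapping dinucleotides. This is a deliberate
restriction: mature miRNAs are too short (18–25 nt) for alignment-profile
or secondary-structure features to be reliable, while dinucleotide
composition and its physico-chemical summary are well defined at any
length ≥ λ + 2.

## Feature encodings

**DiPro.** The embedded property table
(`src/mirnaloc/data/rna_dinucleotide_properties.tsv`) holds 15 values per
dinucleotide covering 11 distinct properties; hydrophilicity, enthalpy,
entropy and free energy appear in two published determinations each
(`_1`/`_2`; the mapping of determination to suffix is this package's
convention, documented in the asset header, with sources listed there).
The encoder averages **raw** property values over the sequence's L−1
dinucleotides — an average of means with natural units (degrees, Å,
kcal/mol, cal/(mol·K)).

**PseDNC.** The correlation R(d₁, d₂) inside the tier factors uses the
**standardized** table (z-scores over the 16 dinucleotides, population
divisor 16), so that no single property's units dominate the squared
differences; raw-value mode is available behind
`PseDncConfig(use_raw_properties=True)` for sensitivity checks. The
frequency block is normalized as count/(L−1), which makes Σg = 1 and hence
the whole vector sum to exactly 1 after division by Z. The second branch of
the piecewise definition is taken to cover τ = 17 … 16+λ (τ = 16 belongs
to the frequency branch). λ = 0 is allowed and reduces the encoding to
plain dinucleotide frequencies, which the tests exploit.

Tunable parameters:

| parameter | default | meaning |
|---|---|---|
| λ | 2 | number of tier-correlation pseudo components; fixes the combined width at 33 |
| w | 0.1 | weight of the pseudo components relative to the frequencies |
| K | 5 | SMOTE nearest-neighbour pool size (classic default) |
| target ratio | 1.0 | minority size after SMOTE as a fraction of the majority |
| skip threshold | 1.5 | imbalance ratio below which SMOTE is not applied |
| threshold | 0.5 | probability above which a localization is called |
| (γ, C) | per-localization table | RBF width and soft-margin cost; re-derivable via `gridsearch` |

λ = 2 is the default because with the 15 DiPro and 16 frequency features it
yields the 33-predictor layout the rest of the pipeline (and the published
optima) assume; w = 0.1 is the conventional default of pseudo-composition
encoders. Both are exposed in `PseDncConfig` and the CLI.

## Principal-component step

PCA is a re-coordinatization here, not a reduction: all 33 components are
kept, so the SVM sees an orthogonal rotation of the centered features.
Numerical conventions: covariance PCA (no column scaling) with the n−1
divisor; component sign fixed by requiring the largest-magnitude loading
entry of each component to be positive, so serialized models are stable
across platforms; fitting happens inside each training fold during
cross-validation (leakage-free) and on the full training set when fitting a
deployable model. Correlation-mode PCA (unit-variance columns) was
considered and not adopted: the PseDNC block is already on a common
probability scale and the RBF γ absorbs the overall scale of the scores.

## SMOTE

Implemented from the three-step description: difference to a neighbour,
multiplication by u ~ Uniform[0, 1), addition to the base point. Details
fixed for determinism: neighbour search among minority rows only, Euclidean
distance, ties broken by row index; base points cycle through the minority
rows in index order, one synthetic point each, until the target count is
reached; the RNG is seeded per call. An audit trail of (base, neighbour, u)
triples can be captured and replayed exactly, which is how the tests verify
the generator. Synthetic points are convex combinations of minority pairs
and therefore stay inside the minority per-feature envelope.

## SVM and calibration

Binary classifiers are RBF-kernel SVMs (scikit-learn `SVC`). Probabilities
come from a Platt-style sigmoid fitted on internal cross-validated decision
values of the balanced training set
(`CalibratedClassifierCV(..., method="sigmoid", ensemble=False)`), which is
deterministic given the data. Calibration is fitted after SMOTE balancing.
No class weights are used — balancing is SMOTE's job. The grid search
enumerates γ ∈ {2⁻¹⁵ … 2³} (19 values) × C ∈ {2¹⁵ … 2⁻⁵} (21 values),
scores each pair by mean stratified fivefold misclassification error, and
breaks ties toward smaller C then smaller γ (prefer the simpler model);
the selection is therefore invariant to enumeration order.

The per-localization default (γ, C) table is kept verbatim from its source,
including the exosome entry γ = 0.065 — close to, but not exactly, the
grid point 2⁻⁴ = 0.0625. It is preserved rather than silently corrected;
either value can be set through the run-config file.

## Evaluation harness

Repeated stratified k-fold cross-validation (k = 5): each repeat draws a
fresh stratified split with seed = base seed + repeat index; within a fold
the entire preprocessing stack (PCA, SMOTE) is refitted on the training
part only. Metrics are computed per fold, averaged within a repeat, and
reported as mean ± standard error (sd/√repeats, ddof = 1) across repeats.
Fold scores for ROC/PR areas are SVM decision values; any monotone
calibration leaves the areas unchanged. The PR area uses the step-wise
convention (Σ precision × recall increment, no linear interpolation).
Metrics with a zero denominator are reported as NaN and flagged, never
silently coerced to 0; within-repeat averaging ignores NaN folds.
Multi-label scoring counts a localization as correct only when it is in
both the truth and the prediction, and tabulates a (true count × correct
count) matrix over sequences.

## Synthetic data

The generator emulates exactly one property of real data: class-dependent
dinucleotide composition, via first-order Markov chains whose transition
matrices blend uniform with fixed class-specific biased matrices
(`(1−s)·U + s·B_c`). The B_c are hard-coded permutation-concentrated
matrices (85% mass on a class-specific base-to-base map) whose dominant
dinucleotide sets are pairwise distinct — so the signal lives precisely in
the feature space the encoders span. Default conditions: 8 classes × 200
sequences of 18–25 nt. It does **not** emulate biogenesis, secondary
structure, expression-dependent annotation bias, family-level sequence
redundancy, or realistic multi-label co-occurrence (the multilabel option
adds a deterministic neighbour-class second label). Passing the
signal-recovery tests therefore shows the pipeline recovers
dinucleotide-level class signal without leakage and stays at chance on an
exchangeable null — not that real localization data carries such signal.

Problem sizes in the tests and the acceptance script (8 × 200 sequences,
10 repeats of fivefold CV) are the package's standard desk-scale
experiment; the harness accepts larger values.

## Known limitations

- Training data at realistic scale (curated localization databases) is out
  of scope; redundancy removal (e.g. 80%-identity clustering) is a
  recommended external preprocessing step the package does not perform.
- The fixed-background negative design and alternative classifiers are not
  implemented.
- Sequences shorter than λ + 2 cannot be encoded; prediction reports them
  as missing rows rather than failing the batch.
- Ambiguity codes (N, R, …) are rejected or dropped, never imputed.
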