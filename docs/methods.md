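# Methods

## Problem and model

Somatic missense mutations that fall on functionally critical protein
regions — allosteric sites (regions topologically distinct from the primary
functional site whose perturbation propagates to it) and orthosteric sites —
are enriched for cancer drivers. The package treats driver identification as
a two-step problem: a deterministic *mapping* step that assigns every
mutation to one of four mutually exclusive areas (experimental allosteric,
predicted allosteric, orthosteric, other), and a supervised *scoring* step
applied only to site-mapped mutations. Proteins are then ranked per sample
by their best-scoring driver mutation.

Site annotations are consumed as residue sets in 1-based UniProt sequence
coordinates. No pocket detection, structure parsing, or coordinate
computation happens here: predicted allosteric sites represent upstream
pocket predictions taken as given data, and the per-residue structural
attributes (relative solvent accessibility, flexibility) arrive as an input
table. PDB identifiers are carried as annotation only.

### Area assignment

A position belonging to several overlapping sites is resolved with
precedence ORTHO > ALLO_EXP > ALLO_PRED. No published rule exists for this
case; orthosteric membership is the more specific functional claim, the
rule keeps the four-area accounting a true partition, and it is exposed as
a parameter (`precedence=` in `map_mutation`). In allosteric-only mapping
mode orthosteric records are inactive, so an orthosteric-only position maps
to "other", consistent with the user's chosen mapping area.

Reference-residue mismatches against the supplied FASTA default to
skip-with-warning rather than hard error, because clinical MAFs routinely
carry isoform-numbering drift; mismatched mutations are demoted to the
"other" bin (kept in frequency profiles, excluded from scoring). Duplicate
identical mutations within a sample are scored once, but their multiplicity
feeds the frequency profiles.

## Feature schema (v1)

The 11-feature descriptor is this package's declared stand-in for a full
structural/dynamic feature set; it is versioned so an alternative schema can
be introduced without invalidating stored models, and all model code is
schema-agnostic.

| feature | meaning | source |
|---|---|---|
| is_allo_exp, is_allo_pred, is_ortho | one-hot site-type flags (sum to 1) | mapping |
| rsa | relative solvent accessibility, [0, 1] | residue table |
| flex | z-scored flexibility proxy (e.g. normalized B-factor) | residue table |
| d_hydropathy | Kyte–Doolittle (1982) index, alt − ref | embedded table |
| d_volume | residue volume (Zamyatnin 1972, Å³), alt − ref | embedded table |
| d_charge | formal side-chain charge at pH 7 (His neutral), alt − ref | embedded table |
| blosum62 | BLOSUM62 substitution score ref→alt | biopython |
| pro_introduced, gly_lost | backbone-geometry-breaking flags | derived |

Property deltas are antisymmetric by construction. Featurization is total
on its domain: it either yields a fully finite vector or fails naming the
offending (protein, position).

## Class rebalancing and the ensemble

Driver/passenger training data are imbalanced at roughly 0.12 positives per
negative. SMOTE oversamples the minority class before fitting: each
synthetic point is x + u·(x_nn − x) with u uniform on [0, 1] and x_nn one of
the k = 5 nearest minority neighbors (Euclidean); the minority is grown to
parity with the majority (`target_ratio` 1.0, canonical SMOTE defaults).
Majority rows pass through bit-identical. k is clipped to minority − 1 with
a warning when the minority is tiny.

Two learners are fitted on the rebalanced data and averaged:

- **Random forest** — 130 trees, maximum depth 4, feature fraction 0.4 per
  split, on raw (unstandardized) features; tree splits are scale-invariant.
- **Multi-layer perceptron** — hidden layers of 20 and 15 ReLU units,
  sigmoid output, trained by full-batch gradient descent with learning rate
  0.1 and momentum 0.8 on z-standardized features (standardization fitted
  post-SMOTE on training rows only; constant features scale as no-ops).
  These learning-rate/momentum values belong to the classic full-batch
  backprop regime; small mini-batches at this learning rate produce noisy,
  saturated probability estimates whose confidently wrong outputs dominate
  the ensemble mean, so full batches are the default (`mlp_batch=None`).
  Training runs at most 200 epochs with validation-based early stopping
  (validation fraction 0.15, patience 20), which keeps the output
  probabilities calibrated rather than pinned at 0/1. The early-stopping
  configuration was selected by mean cross-validated sensitivity over eight
  generator seeds of the synthetic protocol, tie-broken by worst seed.

The driver score is the unweighted arithmetic mean of the two class-1
probabilities — the simplest symmetric combination rule; both branch outputs
are exposed (`score_components`) so the mean identity is testable to machine
precision. A mutation is called a driver when its score is **strictly**
greater than 0.5; a tie at exactly 0.5 is a non-driver.

Cross-validation is stratified 10-fold (imbalance at 0.12 makes
unstratified folds degenerate) with SMOTE and standardization re-fit inside
every training fold, so no synthetic point's parent rows span a fold
boundary. Rows are put in a canonical (lexicographic) order before the
fold split, making CV and grid-search results invariant to input row
order. Hyperparameter tuning (`tune`) grid-searches depth 2–10, trees
10–300 and feature fraction 0.3–0.5 by mean CV AUC with deterministic
tie-breaking; the defaults above are the chosen operating point.

Models serialize to a single joblib bundle (config, schema version,
standardization parameters, both learner states); reload is bit-stable —
scores before and after a round trip are identical.

## Evaluation

`roc_auc` sweeps thresholds over the unique scores and integrates the ROC
curve trapezoidally with simultaneous steps at tied scores. This estimator
equals the Mann–Whitney U statistic divided by n₁·n₀ with half credit for
ties; the test suite checks the equivalence against a brute-force pairwise
oracle to 1e−12 on 200 random tied instances. `sensitivity_at` counts
positives strictly above the threshold. The benchmark harness maps,
featurizes and scores a labeled mutation table and reports AUC, detection
counts, and the per-mutation score table; unmappable entries are listed
rather than silently dropped, since silent exclusion would inflate
sensitivity.

## Synthetic data

The fixture generators produce mutually consistent worlds (site TSV,
residue-annotation TSV, gene map, FASTA) and MAF cohorts with a controlled
fraction of mutations on site residues; every generated artifact passes the
corresponding loader and FASTA cross-validation by construction, and output
files are byte-identical for a fixed seed.

`gen_labeled_dataset` plants a two-Gaussian class structure: negatives are
standard normal on the 8 continuous features; positives are shifted by d′
pooled-sd units along a random unit direction; the one-hot site flags are
assigned validly but independently of the label. Defaults mirror the class
composition of curated driver/passenger benchmark sets (73 positives / 582
negatives, imbalance ≈ 0.125; the smaller allosteric-shaped set is 24/197).
d′ = 2.5 is used as the reference difficulty: its Bayes-optimal AUC is
Φ(2.5/√2) ≈ 0.96, comparable to the >0.9 regime reported for curated
benchmarks of this kind.

What the generator does *not* emulate: real mutational signatures,
per-gene mutation rates, feature correlations of real structural
descriptors, or label noise in curated knowledge bases. Passing the
synthetic protocol therefore demonstrates that the rebalancing, training,
cross-validation and thresholding machinery recovers a planted signal of
realistic strength under realistic imbalance — not that any particular AUC
will be attained on real cohorts.

Under the reference protocol (73/582, d′ = 2.5, 10-fold CV, defaults) the
pooled AUC is ≈ 0.94–0.96 across generator seeds and sensitivity at the 0.5
threshold averages ≈ 0.81 with seed-to-seed spread of roughly ±0.04 — the
detection rate is the quantity most sensitive to the planted-direction
geometry, because it depends on absolute calibration rather than ranking.

## Numerical and interface choices

- Standardization uses the population standard deviation; zero-variance
  features get sd treated as 1.
- Ranking ties break by gene symbol ascending, then position ascending;
  rankings and score profiles are pure, shuffle-invariant functions of the
  prediction set.
- Domain intervals are 1-based inclusive on both ends (PFAM convention);
  the pan-cancer heatmap reports raw counts (not normalized per cancer-type
  cohort size), documented as such.
- The per-sample cap of 2 000 mutations is enforced strictly: a
  2 000-mutation sample passes, 2 001 is rejected and reported.
- Output TSVs format scores to six decimals, making pipeline runs
  byte-reproducible.
- Problem sizes in the test suite and acceptance script (worlds of 4–6
  proteins, cohorts of tens of mutations, the 24/197 and 73/582 labeled
  sets) are chosen to exercise every code path at interactive runtimes.

## Known limitations

- The v1 feature schema is a physicochemical stand-in; it does not include
  molecular-dynamics-derived descriptors or conservation scores.
- Gene-to-UniProt resolution requires an explicit mapping table; unmapped
  genes are skipped with a warning.
- The SMOTE-inside-CV protocol is enforced (no leakage), which can make CV
  estimates slightly conservative relative to resample-then-split designs.
- No probability calibration beyond the sigmoid output and the balanced
  resampling; scores are comparable within a model, not across models.
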