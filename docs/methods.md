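# Methods

This note documents the models, conventions and numerical choices behind
`cdscreen`, in the order data flows through the pipeline.

## Curation

Raw records arrive as (guest structure, CD identifier, stability value,
conditions). Structures must be SMILES or InChI; name-only records are
rejected with a machine-readable reason (`missing_structure` /
`parse_failure`) rather than converted — IUPAC-name resolution is outside
the package's scope. Canonical guest identity is the InChIKey computed
*after* counter-ion stripping and canonicalization, so salt forms collapse
while stereoisomers stay distinct. Counter-ion stripping removes all
single-atom components; if several multi-atom components remain, the largest
is kept (standard parent-salt convention), and an all-ion record is rejected
(`no_multi_atom_component`). Stability constants given on the linear scale
are converted to ln(K_s) only when the input explicitly flags them as linear
(`ks` column); magnitude heuristics are never used.

Step order: structure filter → standardization (with condition imputation to
25 °C / pH 7) → counter-ion removal → duplicate merge → molecular-weight
filter → condition filter → ln(K_s) outlier filter. Every step appends a
(records in, removed, merged, out) row to the audit report, and the pipeline
asserts conservation of counts.

Boundary conventions (all configurable through `CurationConfig`):

| rule | bounds | inclusivity | rationale |
|---|---|---|---|
| molecular weight | 50–500 Da | strict | "greater than / less than" wording |
| temperature | 20–30 °C | inclusive | imputed 25 °C must survive |
| pH | 5–8 | inclusive | imputed pH 7 must survive |
| ln(K_s) outliers | 2–10 | inclusive | "ranging from 2 to 10" |

Duplicates are groups identical in (guest InChIKey, CD key, T, pH), with
conditions rounded to 0.1 units to avoid float-noise group splits. A group
merges to its arithmetic-mean ln(K_s) when its spread (max − min) is below
10 % of the ln(K_s) range of the dataset *as it exists at the merge step*
(the merge precedes the MW/condition/outlier filters, matching the printed
workflow order); otherwise the whole group is dropped. Whether the 10 %
range should refer to the pre- or post-filter dataset is genuinely open; the
at-merge-time reading follows the step order and is exposed for sensitivity
testing by re-running with a reordered config. Output order is canonical
(sorted by record keys), which makes the pipeline permutation-invariant.

Records with imputed conditions keep an `imputed_*` flag for provenance but
the flag is not used as a model feature.

## Cyclodextrin decomposition descriptors

A CD is represented as `(n_glucose, side-chain fragment, degree of
substitution)`. The macrocycle, nearly invariant across CD types, is
collapsed to its glucose count (6/7/8); the variable chemistry lives in the
side-chain fragment, written as a stand-alone molecule terminated by a
hydrogen atom: the native C-6 hydroxymethyl reads as methanol (`CO`), a
2-hydroxypropyl ether as `COCC(C)O`, a methyl ether as `COC`. The CD feature
vector is `[n_glucose] + descriptors(fragment) + [ds]`.

Conventions the registry commits to (the underlying literature is silent on
both):

* For CDs substituted at secondary hydroxyls (O-2/O-3) the registry fragment
  is the substituent reachable from C-5 via C-6 — the primary face — and all
  other positions fold into the `ds` scalar, the average number of
  substituents per glucose unit. This keeps the one-fragment scheme while
  still separating, e.g., dimethyl- (ds 2.0) from trimethyl-βCD (ds 3.0),
  which share the methyl-ether fragment.
* Heterogeneously substituted CDs (randomly methylated-βCD) store one
  representative fragment plus their average `ds`.

The shipped registry (`src/cdscreen/data/cd_registry.json`, editable) covers
16 CD types across the α/β/γ families with abundance weights reflecting how
strongly natural CDs dominate public stability collections (αCD 411, βCD
638, γCD 160 of ~1650 records, the rest semi-synthetic).

Structure-based decomposition detects pyranose rings (six-membered, one
oxygen), links two rings when a non-ring oxygen bridges them, and accepts a
6/7/8-membered cycle of such links as the macrocycle; the side chain is
excised by breaking the C-5→C-6 bond, which leaves the fragment H-terminated
by valence filling. Heterogeneous structures report the most common fragment
and a `ds` estimated as the non-native fraction of units.

## Featurization

Descriptor providers are a pluggable contract: structure → ordered mapping of
named finite floats. Two are built in:

* `minimal` (~14 descriptors): MW, heavy atoms, ring counts, H-bond
  donors/acceptors, TPSA, Crippen logP, rotatable bonds, fraction Csp3,
  Chi0v, heteroatom fraction, plus two conformer-derived terms — radius of
  gyration and a chirality-signed sum of tetrahedral volumes over
  4-coordinate atoms. The signed-volume term flips sign under reflection, so
  enantiomers (which share every scalar shape descriptor) remain
  distinguishable; neighbor order is fixed by atom index to make the sign
  well defined.
* `rdkit-full` (~220 descriptors): every RDKit 2D descriptor plus the ten
  standard 3D shape descriptors and the signed-volume term.

3D descriptors come from a single ETKDGv3-embedded conformer with a recorded
seed — determinism was preferred over ensemble averaging, whose variance
would be far below the descriptor noise floor for molecules of this size.
The descriptor-set composition is a provider property; no claim is made that
any particular published descriptor count is reproduced.

`SystemFeaturizer` (a sklearn transformer) concatenates guest and CD vectors
under `guest.*` / `cd.*` namespaces, drops features that are non-finite for
any record or constant across all records, and freezes the retained feature
names at fit time; `transform` re-indexes onto exactly that schema and fails
loudly on any mismatch, preventing train/predict skew.

## Threshold datasets

Direct regression of ln(K_s) across heterogeneous literature conditions is
unreliable (a large fraction of records carries imputed conditions), so the
modeling target is binary stability at three thresholds T ∈ {4.5, 5.0, 5.5},
spanning the stability range typical of poorly soluble β-lactam candidates.
For each T independently:

* negative ⇔ T − 1.5 ≤ ln(K_s) < T;
* positive ⇔ T ≤ ln(K_s) ≤ U, where the upper bound U is chosen by scanning
  the sorted unique candidate values and minimizing |#positives − #negatives|,
  ties toward larger U (slight positive excess);
* records below the window or above U are excluded.

The boundary value ln(K_s) = T counts as positive. The scan-and-minimize
balance rule is this package's reconstruction of "approximately balanced"
class design; it is deterministic, exact on small sets (verified against
exhaustive enumeration), and swappable via `ClassificationSpec.balance_rule`.

## Learning and validation

The learner is LightGBM gradient boosting behind `StabilityClassifier`
(sklearn estimator API; `deterministic=True`, single-threaded, seeded).
Hyperparameters come from an internal 5-fold grid search maximizing AUC
(threshold-free, matching the evaluation emphasis); the default grid has 8
points (trees 100/300, leaves 7/31, min-child 5/20, learning rate 0.1) so
the full nested procedure runs in minutes on one CPU. Ties go to the first
grid point in deterministic iteration order. The probability cutoff for hard
labels is 0.5, exposed in config.

Generalization is estimated by 5-fold *external* cross-validation: the keys
are sorted, shuffled with the seed (making fold assignment independent of
input order), and for each fold a fresh grid search + fit runs on the other
four folds only. Pooled out-of-fold predictions — each record scored exactly
once by a model that never saw it — feed the metric suite. Folds are
unstratified by default (plain random division); a stratified toggle exists
for small synthetic sets where a fold could otherwise lose a class.

Metrics: accuracy, rank-based AUC (midranks for ties, computed from
continuous scores), CCR ≡ balanced accuracy = (sensitivity + specificity)/2,
sensitivity, PPV, specificity, NPV. Ratios with zero denominators are
reported as NaN with a warning, never silently zero. The AUC implementation
is cross-checked in the test suite against an independent brute-force
pair-counting oracle.

Final models are refit on all data after a full-data grid search and
serialized as text (LightGBM model string + JSON manifest carrying feature
schema, class spec, hyperparameters and seed); reloaded models reproduce
in-memory predictions bit-exactly.

## Consensus screening

A guest–CD system is *promising* only when all three threshold models vote
positive — a conservative conjunction whose false-positive rate shrinks
multiplicatively. Ranking among candidates uses (promising, mean score, CD
key), the last term for deterministic ties. Validation mode compares each
vote with the measured class (`measured ≥ T`, the same inclusivity as
training) and reports the correct fraction over systems × thresholds. The
shipped cefuroxime axetil validation set (five CDs, measured ln(K_s)
4.63/5.72/4.72/5.98/5.76) reproduces the published outcome: 14 of 15 votes
correct — the ln(K_s) ≥ 5.5 model underestimates the HP-βCD system — and two
promising systems (βCD, methyl-βCD).

## Phase solubility

All concentrations are molar. For a 1:1 A_L system the diagram is linear
with slope m = K_s·S₀/(1 + K_s·S₀) ∈ [0, 1) and intercept S₀; fitting is
ordinary least squares (`scipy.stats.linregress`), with K_s = m/(S₀(1−m)).
S₀ comes from the intercept by default, with an override for narrow
concentration designs where the extrapolated intercept is unstable. Slope
≥ 1 (pole of the inversion) and non-positive S₀ estimates raise errors, as
do degenerate designs with a single distinct CD concentration. Higher-order
complexes (A_P/B_S profiles) are out of scope.

The experimental design emulated in tests and the acceptance script is five
CD levels of 0.02–0.1 mmol dissolved in 15 mL, i.e. ≈1.3–6.7 mM — the
amount-in-volume reading of that window; at face-value 0.02–0.1 mM the
complexation signal of a K_s ≈ 300 M⁻¹ system would sit below 1 %
measurement noise and no estimator could recover it.

## Synthetic data generator

The generator defines the study conditions for all offline testing. It
emulates the statistical shape of public CD stability collections:

* ln(K_s) marginally ≈ Normal(5.37, 2.22) truncated to [2, 10];
* 16 CD types drawn at registry abundance weights (natural CDs dominate);
* guests built by decorating small aromatic/aliphatic scaffolds with common
  substituents (~1200 unique structures, 50 < MW < 500 Da, a fraction with
  defined stereocenters).

The planted structure–property signal is a deliberate caricature of
inclusion energetics: a quadratic size-match between guest heavy-atom count
and cavity preference (9/13/17 atoms for α/β/γ), guest lipophilicity scaled
by side-chain polarity, a TPSA penalty, and a crowding penalty in the degree
of substitution. Every term is computable from the `minimal` provider's
features, so tree models can recover it without heavy dependencies. The raw
signal is standardized over the generated pair population, squashed through
a scaled tanh, re-standardized, and symmetrically bounded at ±1.51 sd; draws
are ln(K_s) = μ + σ(s·g + √(1−s²)·ε) with ε an exact truncated-normal draw
(no probability mass piles on the boundaries), so the marginal keeps its
configured moments at any signal strength s. In the pure-signal limit s = 1
the bounded g keeps values inside the band deterministically. Observed
moments at the defaults are mean ≈ 5.42 and sd ≈ 2.13 — the small residual
bias is the cost of trimming the left-skewed signal tail, and sits well
inside the sampling tolerance the tests assert.

Curation violations are injected at configurable rates with exact bookkeeping:
structureless records; mergeable duplicate pairs (spread 2 % of the ln(K_s)
range at merge time) and discordant pairs (spread 30 %); missing conditions;
MW outliers (sub-50 and super-500 Da guests); condition outliers (37 °C or
pH < 3); ln(K_s) outliers on both sides of [2, 10]. Duplicate values stay
within the existing min–max so they cannot move the range their own merge
rule depends on, and clean values are drawn slightly inside the outlier band
so merge means cannot drift across it. The returned `PlantedTruth` carries
the exact expected per-step removal/merge counts, which the audit report
must match exactly — the basis of the curation acceptance checks.

What the generator does *not* emulate: real binding physics (the signal is
an arbitrary smooth function, not thermodynamics), correlated measurement
error between laboratories, temperature/pH dependence of ln(K_s), and
name-only or malformed-structure records beyond simple absence. Passing
tests therefore demonstrate that the pipeline machinery — curation
bookkeeping, featurization schemas, validation protocol, metric arithmetic —
is correct, not that any particular predictive accuracy transfers to real
measurements.

## Problem sizes and seeds

The test suite and acceptance script run on one CPU in a few minutes using:
2000-record generation for the curation-emulation checks, a labeled dataset
of ~400 records (from 1400 raw) for the external-CV performance checks, 100
random generator configurations for the audit-trail exactness sweep, and 200
noisy replicates for phase-solubility recovery. Every stochastic component
(generation, fold shuffling, tree building, conformer embedding, noise)
takes an explicit integer seed, and all pipeline outputs are reproducible
byte-for-byte from a recorded config.

## Known limitations

* CD structure decomposition assumes substituents do not themselves contain
  linked pyranose rings adjacent to the macrocycle (branched glycosylated
  CDs would confuse ring-linking detection).
* The degree-of-substitution estimate from structures is the non-native
  fraction of units, which undercounts multiply-substituted single units.
* Conformer-dependent 3D descriptors use one embedded conformer; flexible
  guests with several distinct low-energy conformers get a somewhat
  arbitrary (though deterministic) shape description.
* The balance rule reconstructs "approximately balanced" class design; exact
  replication of any particular published class count is not claimed.
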