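# Methods

This note documents the models and procedures implemented in `ditptox`,
the parameters that matter, the numerical conventions, and what the
synthetic-data tests do and do not demonstrate.

## Problem setting

Drug-induced immune thrombocytopenia (DITP) is a rare, serious adverse
reaction in which drug-dependent antibodies destroy platelets. Laboratory
confirmation is slow and available only in specialised labs, which makes
an in-silico screen attractive. The package treats the task as binary
QSAR classification on a small (hundreds of molecules), imbalanced
(roughly 41% toxicants) dataset, and wraps the full study workflow —
featurization, selection by repeated cross-validation, reliability
assessment, and fragment-level interpretation — as a reusable library.

## Dataset handling

A dataset is an ordered list of (id, SMILES, label) records with unique
ids and labels in {0, 1}; rows with unparseable SMILES are rejected at
read time and reported with row numbers rather than imputed. Textual
labels must be mapped explicitly (`column_map['label_values']`) — there
is no silent coercion.

The stratified 8:2 split allocates per-class training counts by the
largest-remainder (Hamilton) rule on `train_fraction · n_class`, with
total seats `round(train_fraction · n)`. For a 93/132 dataset this gives
74/106 (total 180). Published studies sometimes report other per-class
splits of the same total (e.g. 75/105) that no standard rounding rule
produces; the `per_class_counts` override reproduces any explicit
allocation exactly. Splits are seeded and reproducible.

## Featurization

* **MACCS** (166 bits) comes from RDKit (bit 0 of its 167-bit vector is
  unused and dropped).
* **PubChem-layout fingerprint** (881 bits). No open toolkit generates
  the CACTVS/PubChem key set, so the package provides its own 881-bit
  fingerprint organised in the same section families: an exact
  element-count section (115 keys, thresholds like "≥4 C"), a ring
  section (148 keys: per-size counts of saturated/aromatic vs
  unsaturated, carbon-only vs nitrogen/heteroatom-containing rings, from
  the SSSR, plus aromatic-ring counts), a bonded element-pair section
  (64 keys), a curated SMARTS section (~130 functional-group and
  scaffold patterns), and a deterministic hashed substructure-path
  section filling the remaining positions. Widths and determinism match
  the published layout; individual bits in the last two sections are this
  package's own definitions, so bit-exact agreement with Java-toolkit
  output is *not* claimed — nor needed by any downstream stage, which
  consume the block only as "a binary substructure matrix of width 881".
* **hashed** path fingerprints (default width 1024) stand in for the
  CDK/ExtFP dimensionality.
* Externally computed key sets (Klekota–Roth 4860 bits, atom-pair keys,
  bioactivity signatures) are imported from CSV (`load_feature_table`,
  validated and row-aligned by id) or generated from any user SMARTS
  catalogue (`smarts_catalog_block`); they are not reimplemented.
* **13MD** is the fixed list of 13 common properties. Two of them
  historically come from proprietary software; the package substitutes
  open estimators and logs the substitution — ESOL (Delaney) for
  log-solubility and Crippen logP for the apparent partition coefficient
  at pH 7.4 — with `drop_proprietary=True` dropping both instead.
  Because the logD stand-in is perfectly correlated with ALogP it is
  removed again by the correlation filter, which is the honest outcome
  for a duplicated property.
* **RDMD** is the full RDKit descriptor list; the provider's descriptor
  count varies by version (about 210 currently) and is recorded, not
  forced to any historical count.
* Tanimoto similarity is |a∧b|/|a∨b| over set bits; a pair of all-zero
  fingerprints is defined as similarity 1 (identical absence of
  features) — a convention that real fingerprints never trigger.

## Preprocessing

Filters run in a fixed order on continuous columns only: (1) any
non-finite or |x| > 1e8 entry drops the feature ("extreme values" is not
standardised anywhere; 1e8 is configurable), (2) zero variance, (3) a
greedy scan in column order drops a feature iff |Pearson r| > 0.95 with
an earlier survivor — keeping the earlier column makes runs
order-deterministic. Min–max normalization to [0, 1] uses training
extremes; external values outside the training range are clipped (and
counted) rather than extrapolated, preserving the (0, 1) contract.
Binary bits pass through untouched by default (`drop_constant_bits`
optionally removes dead bits). The fitted state serialises to JSON.

## SMOTE

Synthetic minority points interpolate between a minority point and one
of its k = 5 nearest minority neighbors (exact brute-force search —
datasets are hundreds of rows). Default `target_ratio = 1.0` balances
classes fully. SMOTE runs inside each CV training fold only, never on
validation folds or external data, preventing leakage. The original
rows are preserved first and unmodified; every synthetic point is by
construction a convex combination of exactly two minority parents, which
the tests verify geometrically. Whether balancing should precede or
follow normalization is not standardised; here it follows normalization
(distances in the normalized space weight features equally), recorded in
config.

## Model grid and cross-validation

Seven algorithms are consumed through scikit-learn/xgboost adapters —
the package's substance is the harness, not SVM internals. Default
grids: SVM-RBF C ∈ {0.1, 1, 10, 100}; k-NN (Euclidean)
k ∈ {1, 3, 5, 7, 9}; RF trees ∈ {50, 100, 200, 500},
max_features ∈ {sqrt, log2}, depth fixed at 4; MLP (SGD solver) hidden
∈ {50, 100, 200}; AdaBoost estimators ∈ {50, 100, 200, 500}; XGBoost
depth ∈ {3,…,6}, min_child_weight ∈ {1, 3, 5}; Gaussian NB at defaults.
All are config-overridable. Representations are every block plus every
descriptor × fingerprint pair.

Each candidate runs 10×-repeated stratified 5-fold CV. Within every
fold the preprocessor is refit on the fold-training portion and SMOTE is
applied to fold-training rows only — stricter than ambiguous published
wordings, keeping held-out estimates honest; `refit_per_fold=False` is a
compatibility mode that fits preprocessing once on all rows. Ranking is
mean AUC, ties broken by MCC, then ACC, then name (total and
deterministic). Finalists are refit on the whole training set; external
scores are class-1 probabilities, hard-labelled at 0.5 (the conventional
threshold); the consensus is their plain average.

## Metrics

SE, SP, ACC and MCC follow the standard confusion-matrix formulas; a
zero MCC denominator factor returns 0 with a degeneracy flag (common
convention). AUC is computed by the tie-corrected rank (Mann–Whitney)
formulation — the fraction of correctly ordered (positive, negative)
pairs with ties at ½ — hand-written here and cross-checked against both
brute-force pair enumeration and scikit-learn in the tests. Reports
round percentages to 1 d.p. and MCC/AUC to 3 d.p.

## Applicability domain

The published workflow used closed-source GUI software whose exact
distance statistic is undocumented; the only simple reading consistent
with a "95% threshold on the training set" *and* 100% training coverage
is the one implemented: the threshold is the 0.95-quantile
(`numpy.quantile`, linear interpolation) of leave-one-out
nearest-neighbor Euclidean distances among training rows, and a query is
inside iff its nearest-training-row distance (self-matches allowed)
is ≤ the threshold, boundary inclusive. A centroid-distance variant sits
behind `method='centroid'`. The AD is fitted in the same normalized
feature space as the selected model.

## Structural alerts

Information gain uses base-2 entropies with 0·log 0 = 0; an empty
partition contributes 0, and the result is clamped at ≥ 0 against float
cancellation. Enrichment `freq_P` and its symmetric `freq_N` satisfy the
conservation identity `freq_P·n_P/n + freq_N·n_N/n = 1`, which is
property-tested. "Appearing more than six times" is read strictly:
`n_fragment_total ≥ 7`, counted over the full dataset by default
(`training_only` restricts it). Ranking is IG descending, ties by
`freq_P` then fragment id. The miner is representation-agnostic: any
binary block (imported key set, SMARTS catalogue, or the built-in
fingerprints) can be mined, with SMARTS labels attached when a catalogue
supplies them.

## Synthetic data

The generator draws labels Bernoulli(0.41) (the study-scale imbalance,
so SMOTE paths are exercised by default; redrawn within bounded retries
if a single class appears), planted alert bits at class-conditional
rates (default three bits at 0.8 in toxicants / 0.1 in non-toxicants),
background bits at 0.15 in both classes, and descriptors from
unit-variance Gaussians with a configurable class mean-shift (default
1.5 sd). Label noise flips labels after feature generation. The
theoretical enrichment of a planted bit,
`freq_P = p_pos / (π·p_pos + (1−π)·p_neg)`, is returned as ground truth
and the empirical value converges to it (checked at n = 10 000 within
0.05).

What the generator does **not** emulate: real substructure correlation
between fragment bits (bits are independent given the class),
descriptor collinearity structure, chemistry-specific feature
distributions, or any actual DITP mechanism. Green synthetic tests
therefore demonstrate that the machinery recovers known signal and stays
at chance under null labels — not that any particular accuracy is
attainable on real DITP data.

## Problem sizes in tests

The default suite runs CV at reduced sizes (e.g. 5×2 or 5×10 folds on
120–300 synthetic molecules, k-NN/NB models) and the acceptance script
uses a k-NN-only grid over three representations at n = 300 with full
10×5 CV — sizes chosen so the entire suite completes in seconds while
still exercising every stage at the study's scale (n = 225 splits,
881-bit fingerprints, 100-seed alert-recovery sweeps).

## Known limitations

* PubChem-layout bits beyond the element/ring/pair sections are not
  bit-compatible with CACTVS/PaDEL output; for published-key analyses
  import the external table instead.
* The AD distance statistic is a reasoned reconstruction (see above),
  not a reverse-engineered copy of any specific tool.
* Alert mining ignores spatial arrangement of fragments and interactions
  between co-occurring alerts.
* Hard labels use a fixed 0.5 threshold; no probability calibration is
  attempted.
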