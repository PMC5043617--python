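# Methods

## Scope and model

`simtox` predicts binary activity (active/inactive) of small organic
molecules against screening endpoints from binary structural fingerprints,
by two complementary routes plus their fusion:

1. **Similarity-weighted kNN.** The Tanimoto coefficient
   T(A,B) = |A∩B|/|A∪B| over fingerprint bit-sets ranks all training
   compounds against a query; the top k (exact search, no approximation)
   form the neighbour set. The score formulas are branch-wise:
   `score1 = (Σ Tₙ)/k` when all neighbours are active, `score2 = 1 − score1`
   when all are inactive, and
   `score3 = (Σ Tₙ)/k_a + (1 − (Σ Tₘ)/k_in)` for mixed neighbourhoods.
   `score3` ranges over [0, 2]; we use raw/2 as the normalized prediction
   score so that kNN scores are commensurable with classifier probabilities
   for ROC thresholds and for the min-ensemble. The raw value is always
   retained in kNN output. The weighting is entirely contained in the
   formulas — no additional distance weighting is applied.

2. **Classifiers.**
   - *Naïve Bayes*: fingerprint bits are two-valued nominal attributes with
     Bernoulli likelihoods and Laplace smoothing α=1 (chosen because the
     conventional nominal-attribute cap of 20 unique values is vacuous for
     binary bits); continuous descriptor columns get class-conditional
     Gaussians with a variance floor of 1e-9. Class priors are training
     frequencies.
   - *Random forest*: 1000 trees; each grown on a bootstrap of
     ⌈data_fraction·n⌉ rows drawn with replacement (0.8 for the AhR preset,
     0.7 for ER-LBD/HSE), ⌈√p⌉ candidate attributes per split, trees grown
     to purity. The prediction score is the fraction of trees voting
     active. Split criteria: Gini, or the Quinlan information-gain ratio
     (information gain divided by split entropy; splits with zero split
     entropy or non-positive gain are rejected; binary bits split at 0.5).
   - *PNN*: the classic Specht formulation. Every training point is a
     Gaussian kernel centre; the class density is the *average* of
     exp(−‖x−c‖²/2σ²) over that class's centres, making the density
     estimate independent of class size (duplicating a class's points
     changes nothing — important under heavy imbalance, and tested
     exactly). Score = active density / (active + inactive density).
     Distances are Euclidean on the (already z-scaled) feature table.

3. **Min-score ensemble.** Per compound, the minimum of two methods'
   normalized scores. The rule is conservative for the active call: both
   methods must assign high evidence, which vetoes false positives made by
   only one method. Raw (un-normalized) kNN scores are rejected by a
   precondition so a [0,2]-scaled score can never silently mix with
   probabilities.

## Standardization and featurization

Standardization order is fixed: fragment split → drop water and salt
fragments → keep the largest organic fragment (ties by molecular weight,
then input order) → neutralize → aromatize → add explicit hydrogens. The
order matters only in that neutralizing before fragment selection could let
a discarded counter-ion influence the kept fragment. "Salt" is any fragment
without carbon plus a fixed list of common carbon-containing counter-ions
(acetate, trifluoroacetate, maleate, fumarate, oxalate, formate, mesylate,
tosylate, citrate, tartrate); when a molecule *is* one of those species
(e.g. sodium acetate), the organic counter-ion itself is kept rather than
flagging the record. Neutralization is the safe proton add/remove on O/N/S
centres (RDKit Uncharger); quaternary nitrogen keeps its charge.
Unstandardizable records (no organic fragment) are flagged and excluded
downstream with logging, never silently dropped. Tautomer canonicalization,
stereochemistry repair and 3D embedding are out of scope.

Fingerprints: 166 MACCS keys (RDKit key *i* stored 0-based at *i−1*),
ECFP4 folded to 1024 bits (the smallest common folding with low collision
rates at this scale; the bit-length is a free choice), and the E-state
fingerprint as a *binary presence* vector over the 79 Hall–Kier
electrotopological atom types, so that Tanimoto applies uniformly across all
three. Note the type table contains no CH4 type: methane legitimately maps
to an all-zero E-state vector, which is why a Tanimoto of two all-zero
vectors is defined (as 0, with a warning) rather than an error.
Fingerprinting removes explicit hydrogens first, since the public key
definitions assume implicit-H graphs; invariance to input atom ordering is
property-tested.

The 13-descriptor panel — molecular weight, logP, TPSA, H-bond donors and
acceptors, rotatable bonds, ring count, aromatic ring count, heavy atoms,
fraction sp³ carbons, molar refractivity, heteroatom count, valence-electron
count — is a standard physicochemical/topological panel; the identities are
configuration-visible so users can substitute their own. Descriptors are
z-scaled (mean 0, sd 1) on the training set before concatenation with binary
bits, and external sets reuse the *training* scaling parameters, which the
feature-table TSV format stores in its header.

## Cross-validation and metrics

Folds are stratified by a within-class shuffle (seeded) followed by
round-robin assignment: per-fold active counts differ by at most one, folds
partition the record set, and assignment is deterministic per seed. 13 folds
is the default so each test fold is comparable in size to a typical external
validation set. A fold whose test part lacks one class has no defined AUC
and is excluded from the mean with a warning rather than imputed.

AUC is the rank-based Mann–Whitney form with ties counted ½ (trapezoidal
interpolation across tied-score blocks), computed via scikit-learn and
verified in the tests against a literal all-pairs concordance enumeration.
Both the mean ± sd of per-fold AUCs (the headline, matching per-fold error
bars) and the pooled-score AUC are reported, since the two can differ under
heavy imbalance.

## Synthetic data generator

The generator emulates the statistical structure the methods assume, not
chemistry: two class template bit-vectors at a chosen Hamming distance
(default 40 of 166 bits), per-bit independent flip noise (default 10 %),
class imbalance (default 3 % actives — screening-panel territory), a
1300-record training set and a 647-record external hold-out. The Bernoulli
model was chosen over copula or fragment-graph simulation because it has
closed-form moments: the expected cross-class Hamming distance
d·(1−2f)² + 2·n·f·(1−f) is asserted against simulation, and the exact
log-likelihood-ratio scorer gives a Monte-Carlo **Bayes ceiling AUC**
(`empirical_bayes_auc`, half the draws per class since AUC is
prior-independent) that upper-bounds every classifier. At the default
conditions the ceiling is 1.0 (40 informative bits at 10 % noise separate
the classes almost surely), so recovery tests check that the forest reaches
it; weaker-separation configurations exercise the non-saturated regime.

What passing on synthetic data does *not* show: robustness to activity
cliffs, correlated bits, scaffold clustering, or train/external covariate
shift — all present in real screening data and all absent from the
independent-bit model. A small curated SMILES fixture set (substituted
phenols with ortho/meta chloro/bromo/hydroxyl motifs, salts, charged
species) covers the chemistry-facing modules instead.

## Numerical choices

- Tanimoto of two all-zero fingerprints: 0, with a warning (any real organic
  molecule has non-zero MACCS bits; this only affects pathological inputs).
- Neighbour ties at the k-th position: broken by ascending training-row
  index, for bit-for-bit reproducibility.
- PNN densities are computed with log-sum-exp, so σ → 0 degrades exactly to
  nearest-centre classification instead of 0/0 underflow; σ = "auto" is the
  median Euclidean distance over 500 seeded training pairs.
- NB/PNN scores are normalized pairs (active + inactive evidence = 1).
- Prediction threshold 0.5 everywhere; AUC, the headline metric, is
  threshold-free, so the threshold affects only reported hard classes.
- Constant descriptor columns scale with sd := 1 (centre only).

## Design choices on genuinely open points

- The gini criterion is served by scikit-learn's forest; its
  `predict_proba` averages leaf class-fractions, which equals the vote
  fraction whenever trees reach pure leaves (they do, with purity growth and
  duplicate-free rows); the gain-ratio criterion is an in-house
  implementation since scikit-learn lacks it. The two routes are
  cross-checked on separable data in the tests. scikit-learn rounds the
  bootstrap size where the in-house forest uses the ceiling; at n ≥ 100 the
  difference is at most one row.
- "Data sample with replacement" is read as a bootstrap of size
  data_fraction·n, per its plain meaning.
- The PNN is the classic (non-DDA, non-epoch) formulation; dynamic-decay
  variants trained in epochs are deliberately out of scope.
- The kNN prediction score used for ranking is the normalized (not raw)
  value; within a branch AUC is rank-invariant to the choice, and the
  normalized form keeps cross-branch ranks on one scale.
- Mean-of-fold AUCs is the headline rather than pooled AUC; both are
  emitted.

## Problem sizes

Default test and acceptance runs use the 1300/647-record synthetic study
with 1000-tree forests, and smaller (200–650 record, 30–200 tree)
configurations for unit-level checks — sizes chosen so the full suite and
the acceptance script each complete in well under a few minutes on one CPU
while keeping per-fold active counts (≥3) meaningful.

## Known limitations

- No probability calibration; scores are evidence ratios or vote fractions,
  not calibrated probabilities.
- SVMs, gradient boosting, deep models, ToxPrint fingerprints and
  count-based fingerprints are out of scope.
- The gain-ratio forest is pure Python/NumPy and roughly an order of
  magnitude slower than the C-backed gini route; it is intended for
  1000-tree runs on thousands of records, not millions.
- Statistical comparison of AUCs (DeLong tests etc.) is not provided.
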