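# Methods

## Problem and model

Protein *S*-glutathionylation is the reversible formation of a mixed
disulfide between glutathione and a cysteine thiol. Only some cysteines in a
susceptible protein are modified, and the local sequence context of the
cysteine carries part of the signal. `sglut` frames site prediction as
binary classification of cysteine-centered peptide windows: a window of odd
length *w* (default 15, i.e. seven residues on each side) is cut around
every annotated cysteine, encoded as a numeric vector, and classified by a
supervised model evaluated in stratified 5-fold cross-validation.

### Window extraction

Windows are exact substrings — a site closer than (*w* − 1)/2 residues to a
terminus is **discarded, not padded**, for both classes, because every
encoder assumes a full-length window. Negative sites are sampled per
protein from the unmodified cysteines whose window survives extraction, at
most three per positive site (uniformly, without replacement, seeded), which
caps the class imbalance at 1:3. Coordinates are 1-based in all files.
Windows containing non-standard residues (B, J, O, U, X, Z) are excluded
from encoding with a logged warning rather than guessing a substitution.

### Encodings

Eight schemes map a window to a fixed-length vector (dimension at *w* = 15
in parentheses): amino-acid composition (20), reduced-alphabet composition
(10: a 3-class polar/neutral/hydrophobic block plus a 7-class
aliphatic/acid/base/aromatic/amide/small-hydroxyl/sulfur block), contiguous
dipeptide composition (400), contiguous tripeptide counts (8000),
reversal-merged tripeptide counts (4200), per-position one-hot binary
profile (20·*w* = 300), Bi-profile Bayes (2·*w* = 30), and summed
physicochemical properties (10).

Single/pair/reduced compositions are normalized to frequencies; the two
triplet encoders keep raw counts so each vector sums to *w* − 2 (the
min-max normalization applied downstream makes the distinction immaterial
to the classifier, but counts preserve the per-window triplet budget).
"Pair" and "triplet" mean *contiguous* substrings. The reversal merge
treats a 3-mer and its reverse as one feature ('ABD' ≡ 'DBA'); classes are
canonicalized to the lexicographic minimum of the pair and enumerated from
all 20³ triplets, giving (8000 − 400)/2 + 400 = 4200 classes (400 3-mers
are palindromic in the first/last residue). Feature indexing uses the
alphabetical residue order `ACDEFGHIKLMNPQRSTVWY` throughout.

The Bi-profile Bayes encoding looks up, at each window position, the
observed residue's frequency among positive training windows (first *w*
entries) and among negative training windows (last *w* entries). The
frequency matrices are estimated from training data only; an optional
pseudocount (default 0, i.e. plain occurrence frequencies) guards against
all-zero features on very small training sets.

The physicochemical encoder sums ten per-residue scales over the window:
atom count, net side-chain charge, hydrogen-bond capacity, hydrophobicity
(Kyte–Doolittle), hydrophilicity (Hopp–Woods), helix propensity
(Chou–Fasman), isoelectric point, residue mass, expected contacts within a
14 Å sphere, and electron–ion interaction potential. The values ship as an
editable TSV (`src/sglut/data/physchem_properties.tsv`) assembled from the
standard published scales; the file, not constants in code, is the source
of truth, so a user can substitute their preferred variants of these
scales.

### Normalization and feature selection

Each feature is min-max scaled to [0, 1] using the *training* minimum and
maximum; held-out values outside the training range are clipped, and
features constant on the training set map to 0. Features are then ranked by
the absolute two-sample pooled-variance Student *t* statistic between
classes (df = n₁ + n₂ − 2; zero pooled variance gives *t* = 0, *p* = 1;
ties broken by original feature index), and the top *k* are kept. *k*
defaults to a per-scheme reference value (3, 6, 18, 12, 3, 21, 76, 71 for
physchem / reduced composition / Bi-profile / binary / single / pair /
triplet / reduced-triplet respectively) and is caller-overridable. An
automatic inner-CV sweep of *k* was evaluated and rejected: on ~190
training windows the inner AUC estimate is too noisy to pick *k* reliably
and degraded outer performance.

### Classifiers and evaluation

SVMs (linear, polynomial, RBF kernels), *k*-nearest neighbours (default
*k* = 1, Euclidean distance on normalized features) and random forests
(500 trees) are supported. SVM defaults follow LIBSVM's: C = 1 and
γ = 1/n_features. Optional nested tuning (`tune=True`) grid-searches
C ∈ {2⁻⁵ … 2¹⁵} and γ ∈ {2⁻¹⁵ … 2³} (powers of 4) by inner 5-fold AUC;
outer folds never see the tuning data's test parts.

Evaluation is stratified, seeded 5-fold cross-validation. **Everything
data-dependent is fit inside each training fold**: the Bi-profile matrix,
the normalizer, the *t*-ranking, tuning and the classifier. Pooled metrics
(from concatenated out-of-fold predictions) are the headline numbers;
per-fold reports are also emitted, since fold-mean and pooled estimates can
legitimately differ. Metrics are Sen, Spe, Pre, F1, MCC and ACC from the
confusion matrix (0/0 → 0 by convention) plus trapezoidal ROC AUC with
tied scores grouped (equal to the Mann–Whitney U probability with
half-credit for ties). A window-size sweep re-extracts windows at each odd
size 9–21 under a shared seed.

## Motif scanning

The PROSITE dialect supported is exactly: exact residue, wildcard `x`,
allowed set `[DE]`, forbidden set `{FWY}`, and repetition suffixes `(n)` /
`(n,m)` on any element. Terminal anchors (`<`, `>`) are rejected with a
clear message — none of the reference patterns uses them. Matching
backtracks over repetition counts; every admissible start position is
reported once with the shortest satisfying span (match existence, the
use-case here, is independent of span choice). The four packaged reference
patterns (PS00112, PS00071, PS01204, PS00139) cover the active-site motifs
found in well-studied glutathionylated proteins, and the five worked-example
windows (creatine kinase, GAPDH, NF-κB p50/p65, papain) reproduce the
expected one-pattern-per-family match structure.

## Synthetic data

`synth.generate_dataset` emulates the *structure* of a curated site
dataset: 39 proteins (lengths ~N(350, 80²), residues i.i.d. from a
configurable background, uniform 1/20 by default), 75 positive cysteines
planted at interior positions (≥10 residues from each terminus, ≥*w*
apart), and negatives sampled from the remaining cysteines at ≤3 per
positive. The learnable signal is position-specific flank enrichment: with
probability 0.9 the residues L, P, S are placed at offsets −3, +1, +2 from
the positive cysteine (three offsets, enrichment 0.9 — the default
"strong" condition; `null_config()` plants nothing). Everything is
deterministic given the seed.

What the generator does **not** emulate: realistic amino-acid composition,
homology between proteins, correlated multi-position motifs, structural
determinants (exposure, thiol pKa). Passing the signal-recovery tests
therefore shows the pipeline can learn genuine flank preferences without
leaking fold information — it does not certify real-world predictive
accuracy, which depends on curated data.

### Calibration results the tests compute

On the default strong-signal condition, reduced-triplet encoding with the
default RBF-SVM reaches pooled 5-fold AUC ≥ 0.85 on every tested seed
(typically 0.86–0.92). Signal-free data and label-permuted strong-signal
data stay at AUC 0.5 within ±0.08 — the leakage guard: any in-fold fitting
violation inflates these. The *t*-test's type-I error on Gaussian null
features is 5% ± 2% at n = 100, 500 features.

## Numerical choices and edge cases

- 0/0 metric denominators (Pre, F1, MCC) → 0, logged at debug level.
- Constant features: normalizer maps them to 0; *t*-ranking gives them
  *t* = 0, *p* = 1, so they sort last (index order among themselves).
- Degenerate folds (a single class in train or test) raise a dedicated
  error advising a different seed or fold count; the CLI exits with code 3.
- Negative sampling and fold assignment use independent seeded generators;
  identical seeds give byte-identical outputs end to end.
- Problem sizes in tests and the acceptance script (39 proteins / 75
  positives, 5 seeds, 500–1000 random fixtures per oracle check) were
  chosen to estimate every quantity stably while keeping the default suite
  fast.

## Known limitations

- Reported AUCs on synthetic data characterize the pipeline, not the
  biology; the original curated dataset is not distributed with the
  package.
- The per-scheme default *k* values are reference working points at
  *w* = 15; other window sizes may prefer other *k*.
- The physicochemical table is an assembled set of standard scales; users
  wanting a specific published variant of a scale should edit the TSV.
- Profile-style (matrix) PROSITE entries and web-service lookups are out of
  scope; patterns are consumed as strings.
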