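# Methods

## Scope and model

`gpcrnoise` detects label noise in supervised protein subtype datasets:
given sequences with possibly unreliable subtype labels, it identifies
the records whose classification behaviour under repeated cross-validated
one-vs-one SVM classification is so consistent and confident against
their label that mislabeling is the most plausible explanation. The
package covers the full chain — sequence I/O, alignment-free feature
extraction, SVM contract, performance measures, the three-step detector,
an independent ensemble cross-check, a synthetic-data generator and an
orchestration layer/CLI — but deliberately excludes phylogenetic-tree
validation, database lookups and automatic relabeling: the output is a
shortlist for a human curator, not a corrected dataset.

## Alignment-free transformations

All four transformations map a length-L sequence over the 20-letter
amino-acid alphabet to a fixed-length vector; amino acids are always
ordered alphabetically by one-letter code.

**AAC / Digram.** Relative frequencies of the 20 residues and of the 400
ordered adjacent pairs (L−1 overlapping windows). Frequencies rather
than counts are used so sequences of very different lengths live on the
same scale; both are probability vectors summing to 1.

**ACC** (auto-cross covariance). Each residue is replaced by its five
z-scale physicochemical descriptors (packaged in `data/zscales.tsv`,
from the standard five-z-score parameterization). Each descriptor
trajectory is centered by its own per-sequence mean, and for every lag
d = 1..l the 5×5 matrix of lagged products Σᵢ z̃ⱼ(i)·z̃ₖ(i+d)/(L−d) is
computed (diagonal = auto-covariance, off-diagonal = cross-covariance),
giving 25·l features, lag-major with the descriptor-pair block flattened
row-wise. Per-sequence centering follows the established auto-cross
covariance construction; it implies the transform measures sequence
*order*, not composition — a homopolymer maps to the zero vector — which
is verified by brute-force oracles and invariants in the test suite.
The default maximal lag is 13 (the setting reported to work best for
receptor subtype data); desk-scale analyses in the tests use lag 3,
which keeps the 100-iteration detector run fast without changing any
qualitative behaviour.

**PDBT** (physicochemical distance-based transformation). A large panel
of per-amino-acid property scales, each first standardized to mean 0 /
sd 1 over the 20 amino acids; the feature for property p and lag d is
the mean squared difference Σᵢ (P̃ₚ(aᵢ) − P̃ₚ(aᵢ₊d))²/(L−d), concatenated
property-major (531·8 = 4248 features with the defaults). The package
does not ship a curated property compendium: `make_synthetic_property_table`
generates a reproducible synthetic 20×531 table instead (clearly
labelled synthetic). Because every scale is standardized before use, the
transform's structural behaviour — dimensionality, lag mechanics,
homopolymer zeros, oracle agreement — is independent of the specific
values; analyses that interpret individual named scales would need a
curated table, which users can supply as any 20×P `DescriptorTable`.

## SVM contract

The pairwise soft-margin RBF-SVM solver is scikit-learn's libsvm
binding; the package owns everything the analysis depends on: the
one-against-one structure (K(K−1)/2 binary classifiers; 21 for K = 7),
per-fold feature standardization (z-scoring with training-fold
statistics only; on by default because RBF kernels on heterogeneous
feature scales require it, configurable off), vote tallying (each pair
casts one vote; ties at a decision value of exactly 0 favour the
lower-indexed class; the predicted class is the vote argmax with ties to
the lowest index), and the decision-value sign convention: **positive
favours the lower-indexed class of the pair**. libsvm follows this
convention internally for K ≥ 3; scikit-learn's two-class special case
reports the opposite sign and is normalized inside the wrapper, which is
verified against the solver's own binary predictions in the tests.

Hyperparameters (C, γ) are grid-searched by mean stratified-CV accuracy
with folds fixed once per search, ties broken toward smaller C then
smaller γ. Default grids are the standard libsvm-style log₂ grids
(C ∈ 2⁻⁵..2¹⁵, γ ∈ 2⁻¹⁵..2³, steps of 4×); tests and examples use
smaller grids spanning the same region.

## Performance measures

Binary accuracy, precision, recall and MCC come from tp/tn/fp/fn with
explicit degenerate-case handling: any measure with a zero denominator
is NaN and flagged, except MCC whose 0/0 case returns 0 (single-class
predictions carry no correlation) with a flag. Two multi-class
accuracies coexist because both conventions appear in practice: the
proportion of correctly classified instances (trace/N — the headline
number) and the mean of per-class one-vs-rest binary accuracies
(`accuracy_table_mean`, always reported alongside). The multi-class MCC
is the generalized correlation coefficient over all entries of the K×K
confusion matrix; the implementation uses the algebraically equivalent
covariance form and is tested against an independent term-by-term
evaluation of the summation formula and against
`sklearn.metrics.matthews_corrcoef`.

## The detector

Defaults: 100 iterations × stratified 5-fold CV, e = 75 % (inclusive),
θ_R = 0.5, θ_CDV = 60, C-jitter multipliers (0.5, 0.75, 1.0, 1.25, 1.5)
cycled across folds. Design choices made where the procedure was
genuinely open:

- **Stratified shuffling** for the per-iteration CV: plain reshuffling
  can starve a small subtype out of a training fold (the smallest real
  receptor subtype has 48 of 1,510 sequences); stratification protects
  it without otherwise changing the statistics.
- **VT/VP accounting:** the vote totals entering R_s sum over *all*
  n_iterations test occasions, correct or not. A variant counting only
  misclassified occasions is available (`votes_misclassified_only`) for
  sensitivity analysis; per-iteration vote logs are retained so either
  sum can be recomputed by brute force.
- **Most-predicted class** from the misclassification assignment
  counts, ties toward the lowest class index — not from overall vote
  mass, which a near-winning true class could dominate.
- **θ_CDV scaling:** CDV is an un-normalized sum over iterations, so
  when n_iterations ≠ 100 the effective threshold is
  θ_CDV · n_iterations/100.
- **C jitter** emulates "slightly different SVM models" across the
  inner loop; the exact range is a free choice and is configurable.

The shortlist invariant: a sequence is a candidate iff ER ≥ e **and**
(R ≤ θ_R **or** |CDV| ≥ θ_CDV). The frequent-but-small-magnitude
sequences are retained in the report, since they often indicate genuine
subtype overlap rather than mislabeling.

## Ensemble cross-check

The noise-rank filter evaluates NB, RF, SVM and MLP on one shared
stratified 5-fold split (shared folds make per-sequence failures
comparable) and scores each sequence by the weighted number of failing
classifiers (MLP 3, SVM 2, NB 1, RF 1 — taken from the established
noise-rank weighting). Both the consensus set (all fail) and the
majority set (≥ min_failures, default 3) are reported, plus an overlap
report against the SVM-based candidate list. Base-classifier settings
are ordinary defaults (Gaussian NB on standardized features; 500-tree
random forest; the tuned RBF-SVM; a one-hidden-layer MLP of width
min(100, 2·D) trained with lbfgs, which is reliable at the small sample
sizes used here); all are seeded and configurable.

## Synthetic data generator

The generator emulates a subtype-structured protein dataset at desk
scale: K = 7 classes × 30 sequences, lengths 60–200, with class
emission profiles drawn from a Dirichlet (concentration 0.75) and mixed
with the uniform background under `separation` (default 0.8), plus
exactly round(ρ·N) recorded label flips (default ρ = 5 %, uniform to any
other class; an "adjacent" mode flips to the compositionally nearest
class to mimic similarity-driven noise).

Composition alone, however, cannot exercise the covariance-based
transforms: a per-sequence-centered lagged covariance has expectation
~0 under any i.i.d. residue model, whatever the class profiles, so an
i.i.d. generator leaves ACC blind (measured: one-vs-one SVM accuracy at
chance). Real protein families differ not only in composition but in
local repetitiveness and periodicity (homopolymeric runs, amphipathic
alternation, low-complexity regions), and that is precisely the signal
ACC is built to read. The generator therefore adds a class-specific
short-range repeat structure: at each position, with class strength
m ∈ [0.25, 0.9], the residue r positions back is copied, with the period
r cycling 1, 2, 3 across classes. Copying leaves the marginal
composition exactly equal to the emission profile (each position is a
fresh profile draw or a copy of one), but imprints a fingerprint on the
lagged covariances: the lag-d autocovariance decays like m^(d/r) and
vanishes off the period multiples. With the defaults this yields
one-vs-one SVM CV accuracies around 0.86–0.90 on ACC features —
comparable to the high-accuracy regime in which the detection procedure
is meant to operate — while AAC/Digram continue to see the composition
signal. Setting all strengths to 0 recovers the pure i.i.d. composition
model (used in the tests to show a composition classifier at chance when
`separation` = 0).

What the generator does **not** emulate: real domain architecture
(VFT/CRD/7TM), evolutionary correlation between sequences, realistic
length–subtype relationships, and any property-specific biochemistry.
Passing tests therefore demonstrate that the detection machinery
recovers planted label noise under a controlled, class-structured
model — not that any particular real database entry is mislabeled.

## Numerical and degenerate-input conventions

- Tie-breaks: vote argmax → lowest class index; zero decision value →
  vote to the lower-indexed class; grid-search ties → smaller C, then
  smaller γ; most-predicted-class ties → lowest index.
- A sequence never misclassified has no most-predicted class; voting
  ratio and CDV are defined only for frequent misclassifications.
- ER thresholds compare inclusively (≥), so a sequence at exactly e is
  selected.
- Oracles in the test suite (brute-force double loops for ACC/PDBT,
  term-by-term MCC sums, vote recounts) are written independently of
  the library code paths they check.
- All randomness (generator, fold shuffling, label flips) flows from
  explicit integer seeds; per-iteration fold seeds are derived as
  (seed + 1,000,003·iteration) mod 2³¹.

## Problem sizes

The default test and example configuration (210 sequences, ACC at lag
3, 100×5-CV, 25-point tuning grids) completes in well under a minute
per run; the flip-recovery check over five generator seeds takes tens
of seconds. The paper-scale template (1,510 sequences, lengths up to
~2,000, ACC lag 13 or PDBT 4,248 features) is supported by the same
code paths and is a matter of hours rather than seconds; the desk-scale
defaults were chosen so the complete analysis remains interactively
reproducible.

## Known limitations

- The detector flags *consistently and confidently misclassified*
  sequences; genuine subtype overlap produces the same signature at
  small magnitude, and the e, θ_R, θ_CDV thresholds ultimately encode a
  curator's tolerance, not a statistical test with a guaranteed error
  rate.
- The synthetic property panel makes PDBT structurally faithful but not
  biochemically interpretable (see above).
- Tuning optimizes plain CV accuracy; with highly imbalanced class
  sizes a cost-sensitive criterion might select different
  hyperparameters.
- The 0/0 → 0 MCC convention makes degenerate single-class predictions
  look "random" rather than undefined; the degenerate flag should be
  consulted when summarizing.
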