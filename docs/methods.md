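# Methods

## Feature model

A sequence over {A, C, G, U} is represented by sliding-window n-gram
frequencies for a set of selected types (window sizes), by default
{1, 2, 3, 4}. For type *i* there are N_i = 4^i possible grams; the
*concentration* C_i = N_i / Σ_k N_k (sum over the selected types only, so
restricted vocabularies are self-normalising) weights the type-*i* block of
the feature vector. The entry for gram *j* of type *i* is
C_i · t_j / T_i, with t_j the gram's window count and T_i the type's total
window count. Each type block therefore sums to C_i, and the whole vector
sums to 1 whenever every selected type has at least one valid window. The
vector is laid out longest type first (tetragrams, trigrams, bigrams,
unigrams by default), lexicographic over A < C < G < U within a type. The
layout within a type is this package's own deterministic convention; only
the type order is intrinsic to the model.

Assumptions and consequences:

* The embedding is strand-directional (5'→3'); no reverse-complement
  folding is applied, which is why plain reversal is a meaningful negative
  control.
* Composition information lives in the unigram block, order information
  increasingly in the longer blocks; the concentration weights bias the
  classifier toward order.
* A single base change touches at most n windows of type n (≤ 10 windows
  total for types 1–4), so the vector moves by a small, bounded L1 amount —
  the representation is robust to isolated sequencing errors.

### Noise bases

Letters outside {A, C, G, U} (IUPAC ambiguity codes, sequencing noise) are
retained verbatim at I/O time. During counting, any window containing such
a letter is skipped entirely — it contributes to neither t_j nor T_i. This
rule keeps the sum-to-1 normalisation intact and makes the features exactly
invariant to what the noise letter is. Types with T_i = 0 (sequences
shorter than the window, or wall-to-wall noise) contribute an all-zero
block rather than an error, so degenerate inputs cannot crash batch runs;
the sum-to-1 property is waived for such vectors.

## Classifier

One-vs-all linear max-margin classification: for M family labels
(stored sorted), M binary SVMs are fitted with family-*i* rows as positives
and all other rows as negatives; a query goes to the family with the
largest decision value, with exact ties broken to the lexicographically
smallest label. Each binary problem is solved in the primal with the
squared-hinge loss (scikit-learn `LinearSVC`, `dual=False`, tol 1e-8),
which is deterministic — identical inputs give identical models without any
random state. The trade-off parameter *c* (default 1.0) is exposed
everywhere; no per-feature standardisation is applied, because the
concentration weighting *is* the intended feature scaling and standardising
columns would undo it. Models persist as a single versioned JSON file
(labels, weights, intercepts, c, seed, vocabulary signature); prediction
verifies the feature dimension against the signature and fails with a
compatibility error on mismatch.

## Evaluation protocols

* **Stratified k-fold CV** (default k = 5): folds are disjoint, cover the
  dataset, and per family the fold counts differ by at most one
  (generalising positive/negative-ratio stratification to per-family
  proportional allocation, which a multi-family run forces). Every split
  takes an explicit integer seed recorded in the report; the union of test
  folds is asserted to equal the dataset on every run. Reported mean
  accuracy is the example-weighted mean of fold accuracies; per-family
  SE/SP come from the confusion table pooled over held-out predictions.
* **Small-family split**: families with ≥ k members contribute a random
  ⌊1/k⌋ fraction (at least one member) to the test side; families with
  2 to k−1 members contribute exactly one random member; singleton families
  are rejected, since a family must appear on both sides.
* **Training-size sweep**: the dataset is cut into 10 stratified tenths;
  the training set grows cumulatively one tenth at a time (so larger
  training sets contain the smaller ones — the fixed-nesting reading of the
  protocol) and the remainder is tested.

Metrics with a zero denominator raise a typed error rather than returning
0, because silent zeros corrupt averages; in pooled per-family reports an
undefined SE/SP is recorded as null.

## Synthetic data

The generator emulates the family structure the classifier is meant for: a
family is one random ancestor (default 80 nt, uniform composition) plus
members derived by i.i.d. per-base mutation — substitution to a uniformly
chosen different base (default rate 0.10) and single-base indels (default
rate 0.02, split evenly between deletion and insertion). Defaults of
10 families × 20 members at these rates define the standard benchmark
condition used by the end-to-end tests; binary negative-control benchmarks
use 100 positives at substitution 0.05 against either their reversals or
composition-matched randoms. "Reversal" is plain 5'→3' order reversal
without complementation (complementation is available as a flag);
composition matching is mononucleotide with lengths drawn uniformly from
the reference range, and a dinucleotide-preserving Eulerian-walk shuffle is
provided as a stricter null. All generators are pure functions of their
integer seed and produce byte-identical FASTA on repeated calls.

What the generator does **not** emulate: hairpin secondary structure,
phylogenetic (tree-shaped) within-family correlation, registry-specific
composition bias, and hard real negatives such as other sncRNA classes.
Passing tests therefore demonstrate that the pipeline recovers
common-ancestry signal of tunable strength from primary sequence, not that
it reaches any particular accuracy on real registry data.

## Numerical and design choices

* Sum-to-1 checks use an absolute tolerance of 1e-9 (≤ 340 double
  additions); concentration normalisation is checked at 1e-12.
* The weighting-effect analysis (trigram amplification) is run on the
  {1, 2, 3} vocabulary: the scientific claim is that the longest gram type
  is enhanced *relative to the shorter ones it shares the vector with*.
  With tetragrams included, the tetragram block (weight 256/340) dominates
  the weighted variance and the trigram *share* falls even though the
  trigram/unigram variance ratio still rises; the ratio form of the claim
  holds under both vocabularies and is asserted as well.
* The permutation-null check uses 2 × 100 sequences, giving 200 evaluated
  predictions and a binomial 95% band of 50% ± 6.9 points.
* One-vs-all with a linear kernel is the normative formulation here; joint
  multiclass (Crammer–Singer) formulations coincide in practice on these
  features and are out of scope.

## Limitations

* Accuracy on real miRNA registries depends on family granularity, family
  size imbalance and inter-family similarity that the synthetic generator
  does not reproduce; the shipped benchmarks bound what the desk-scale
  evidence shows.
* The default c = 1.0 is a reasonable, not tuned, value; strongly
  overlapping families may need model selection over c.
* Counting is pure-Python and linear in sequence length times the number
  of types; it is comfortably fast for registry-scale inputs (~10^4
  sequences) but not optimised for genome-scale scans.
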