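# famgram

Alignment-free assignment of miRNA sequences (precursors, ~60–120 nt, or
matures, ~18–26 nt) to families, from primary sequence alone — no multiple
alignment, no secondary-structure prediction.

miRNA families group sequences presumed to descend from a common ancestor.
Assigning a newly discovered miRNA to its family is the first step toward
inferring its function, but alignment-based approaches are slow at registry
scale and sensitive to alignment parameters. `famgram` instead embeds each
sequence into a fixed n-gram vector space and classifies it with linear
max-margin decision functions, one per family.

## The model

For each selected n-gram type *i* (default unigrams through tetragrams,
*i* = 1…4), a window of size *i* slides 5'→3' along the sequence and records
the occurrence frequency *t_j* of every gram *j*; windows containing a
letter outside {A, C, G, U} are skipped. With *N_i* = 4^*i*  unique grams of
type *i*, the *concentration* of type *i* is

    C_i = N_i / Σ_k N_k

and the feature value of gram *j* of type *i* is

    x_j = C_i · t_j / T_i ,

where *T_i* is the total window count of type *i*. The default space has
4 + 16 + 64 + 256 = 340 dimensions, laid out tetragrams, trigrams, bigrams,
unigrams (lexicographic within a type), and every complete feature vector
sums to 1. The weighting makes longer, more informative grams outweigh
shorter ones.

Classification is one-vs-all: for *M* families, *M* linear decision
functions *F_i*(x) = w_i·x + b_i are trained (family-*i* members as
positives, everything else as negatives, trade-off parameter *c*); a query
is assigned to argmax_i *F_i*(x). Performance is reported as sensitivity
SE = TP/(TP+FN), specificity SP = TN/(TN+FP) and accuracy
Acc = (TP+TN)/(TP+FP+TN+FN), on the percent scale, under stratified k-fold
cross-validation (default k = 5), with a dedicated one-member-test split for
families smaller than k and a training-size sweep protocol.

Because registry data is not bundled, the package ships generators for the
standard study designs: mutation-derived synthetic families (independent
random ancestors, per-base substitutions and indels), reversed positives
(identical composition, scrambled order) and composition-matched random
negatives, plus a dinucleotide-preserving shuffle as a stricter null.

## Worked example

```
$ python examples/02_family_cross_validation.py
dataset: 200 sequences in 10 families
  fold 1: n_test=40, accuracy 100.00%
  ...
mean 5-fold accuracy: 100.00%
```

Ten synthetic families (20 members each, 80 nt ancestors, 10% per-base
substitutions, 2% indels) are fully recovered by 5-fold cross-validation:
at ~80% within-family identity the concentration-weighted n-gram profile
identifies the family of every held-out member. The other examples print
the feature-space structure (`01`), discrimination of reversed and
composition-matched random negatives — 100.00% balanced CV accuracy on both
(`03`) — and the geometry of the weighting (`04`): on families built from
disjoint trigram pools the trigram share of cross-family center variance
rises from 0.245 to 0.913 when the concentration weights are applied.

The same workflows are available from the shell:

```
famgram synth multi_family --families 10 --members 20 --seed 42 --out data
famgram cv data.fasta data.tsv --folds 5 --seed 42 --out report
famgram train data.fasta data.tsv --out model.json
famgram predict data.fasta model.json --out predictions.tsv
```

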