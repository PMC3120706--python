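"""What the concentration weighting does to the feature geometry.

Builds four families with disjoint trigram support, computes each family's
center vector with and without the concentration weights, and measures
(a) the trigram block's share of the cross-family center variance and
(b) the Euclidean distances between family centers.  Weighting amplifies
the trigram block — the one that actually tells the families apart —
relative to the bigram and unigram blocks (analysis on the {1,2,3}
vocabulary, where the trigram is the longest type).
"""

import numpy as np

from famgram import (
    build_vocabulary,
    center_distance,
    family_center,
    feature_variance_across_families,
    featurize_dataset,
    trigram_pool_families,
)

vocab = build_vocabulary({1, 2, 3})
ds = trigram_pool_families(n_families=4, members_per_family=30, seed=23)
print(f"dataset: {len(ds)} sequences, 4 families on disjoint trigram pools")

for weighted, name in ((False, "unweighted t_j/T_i"), (True, "concentration-weighted")):
    X, y = featurize_dataset(ds, vocab, weighted=weighted)
    y = np.asarray(y)
    centers = {fam: family_center(X[y == fam]) for fam in sorted(set(y))}
    var = feature_variance_across_families(list(centers.values()))
    tri_share = var[vocab.block_slice(3)].sum() / var.sum()
    fams = sorted(centers)
    d01 = center_distance(centers[fams[0]], centers[fams[1]])
    print(f"{name}: trigram share of center variance = {tri_share:.3f}, "
          f"d({fams[0]}, {fams[1]}) = {d01:.4f}")
print("-> the trigram share rises under weighting: the discriminative block is amplified")
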