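"""Discriminate a real family from its classic negative controls.

Two balanced binary benchmarks: family members versus (a) the same bases
read 3'->5' (identical composition, scrambled n-gram order) and (b) i.i.d.
random sequences matching the family's base composition and length range.
High CV accuracy on both shows the features capture sequence order, not
just composition.
"""

from famgram import build_vocabulary, cross_validate, make_benchmark

vocab = build_vocabulary({1, 2, 3, 4})
for kind in ("single_family_reverse", "single_family_random"):
    ds = make_benchmark(kind, members=100, substitution_rate=0.05, seed=17)
    report = cross_validate(ds, vocab, c=1.0, k=5, seed=17)
    labels = sorted(ds.families)
    print(f"{kind}: {len(ds)} sequences ({' vs '.join(labels)}), "
          f"5-fold CV accuracy {report.mean_accuracy:.2f}%")
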