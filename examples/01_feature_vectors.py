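"""Embed sequences into the concentration-weighted n-gram vector space.

Builds the default types-{1,2,3,4} vocabulary (340 dimensions), featurizes
a couple of short sequences and prints the structural facts: the vector
length, the per-type concentration weights, and the sum-to-1 normalization
that holds whenever every type has at least one valid window.
"""

from famgram import RnaSequence, build_vocabulary, featurize

vocab = build_vocabulary({1, 2, 3, 4})
print(f"vocabulary length: {vocab.length} dimensions")
for n in vocab.types:
    print(f"  type {n}: 4^{n} = {4**n} grams, concentration C_{n} = {vocab.concentrations[n]:.3f}")

seq = RnaSequence("example", "ugagguaguagguuguauaguu")  # a ~22 nt mature-like sequence
x = featurize(seq, vocab)
print(f"\nfeaturized {seq.id!r} ({len(seq)} nt): {int((x > 0).sum())} nonzero entries, "
      f"sum = {x.sum():.12f}")

noisy = RnaSequence("noisy", "UGAGGUNGUAGGUUGUAUAGUU")  # one noise base: windows over N are skipped
xn = featurize(noisy, vocab)
print(f"featurized {noisy.id!r} with an N: sum = {xn.sum():.12f} (still 1: "
      "windows over the N are excluded from both the counts and their normalizer)")

short = RnaSequence("short", "ACG")  # too short for tetragrams: that block is zero
xs = featurize(short, vocab)
print(f"featurized {short.id!r} (3 nt): sum = {xs.sum():.6f} = C_1+C_2+C_3 = 84/340")
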