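"""n-gram vocabulary, counting and concentration-weighted featurization.

The counting path is checked against an independent brute-force oracle
that enumerates every window with collections.Counter, and the weighting
identities (sum-to-1, block sums, layout) against hand-computed values.
"""

from collections import Counter
from fractions import Fraction

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from famgram import (
    ParameterError,
    RnaSequence,
    build_vocabulary,
    center_distance,
    count_ngrams,
    family_center,
    feature_variance_across_families,
    featurize,
    featurize_dataset,
)
from famgram.features import write_feature_csv, write_svmlight
from famgram.io import LabeledDataset, normalize_bases

VALID = set("ACGU")


def oracle_counts(bases: str, n: int) -> Counter:
    """Independent window enumerator: every length-n slice over {A,C,G,U}."""
    return Counter(
        bases[i : i + n]
        for i in range(len(bases) - n + 1)
        if VALID.issuperset(bases[i : i + n])
    )


class TestVocabulary:
    def test_default_vocabulary_dimensions_and_concentrations(self):
        v = build_vocabulary({1, 2, 3, 4})
        assert v.length == 340
        assert v.concentrations[3] == pytest.approx(64 / 340)
        assert round(v.concentrations[3], 3) == 0.188
        assert sum(v.concentrations.values()) == pytest.approx(1, abs=1e-12)

    @pytest.mark.parametrize(
        "types,length,conc3",
        [
            ({3}, 64, 1.0),
            ({1, 2, 3}, 84, Fraction(64, 84)),  # recomputed by hand: 4+16+64
        ],
    )
    def test_restricted_types_self_normalize(self, types, length, conc3):
        v = build_vocabulary(types)
        assert v.length == length
        assert v.concentrations[3] == pytest.approx(float(conc3))

    def test_layout_larger_types_first_lexicographic_within(self):
        v = build_vocabulary({1, 2, 3, 4})
        assert v.grams[0] == "AAAA"
        assert v.grams[1] == "AAAC"
        assert v.grams[255] == "UUUU"
        assert v.grams[256] == "AAA"
        assert v.grams[256 + 64] == "AA"
        assert v.grams[-4:] == ("A", "C", "G", "U")
        assert v.index_of("AAA") == 256

    @pytest.mark.parametrize("bad", [{0}, {9}, set()])
    def test_invalid_types_rejected(self, bad):
        with pytest.raises(ParameterError):
            build_vocabulary(bad)


class TestCounting:
    def test_overlapping_windows(self, vocab):
        nc = count_ngrams(RnaSequence("s", "AAAA"), vocab)
        assert nc.counts[3] == {"AAA": 2}
        assert nc.totals[3] == 2

    def test_noise_windows_skipped_entirely(self, vocab):
        nc = count_ngrams(RnaSequence("s", "ACNGU"), vocab)
        assert nc.counts[2] == {"AC": 1, "GU": 1}
        assert nc.totals[2] == 2

    def test_totals_for_clean_sequence(self, vocab):
        nc = count_ngrams(RnaSequence("s", "ACGUACGU"), vocab)
        assert {n: nc.totals[n] for n in (1, 2, 3, 4)} == {1: 8, 2: 7, 3: 6, 4: 5}
        for n in (1, 2, 3, 4):
            assert nc.counts[n] == dict(oracle_counts("ACGUACGU", n))

    def test_short_sequence_zero_totals(self, vocab):
        nc = count_ngrams(RnaSequence("s", "AC"), vocab)
        assert nc.totals[3] == 0 and nc.totals[4] == 0

    @settings(max_examples=200, deadline=None)
    @given(
        bases=st.text(alphabet="ACGUN", min_size=1, max_size=200),
        n=st.sampled_from([1, 2, 3, 4]),
    )
    def test_counts_match_brute_force_oracle(self, vocab, bases, n):
        nc = count_ngrams(bases, vocab)
        expected = oracle_counts(bases, n)
        assert nc.counts[n] == dict(expected)
        assert nc.totals[n] == sum(expected.values())


class TestFeaturize:
    def test_homopolymer_hits_one_gram_per_type(self, vocab):
        x = featurize(RnaSequence("s", "AAAA"), vocab)
        assert x[vocab.index_of("AAAA")] == pytest.approx(256 / 340)
        assert x[vocab.index_of("AAA")] == pytest.approx(64 / 340)
        assert x[vocab.index_of("AA")] == pytest.approx(16 / 340)
        assert x[vocab.index_of("A")] == pytest.approx(4 / 340)
        assert np.count_nonzero(x) == 4
        assert x.sum() == pytest.approx(1, abs=1e-9)

    def test_empty_type_block_waives_sum_to_one(self, vocab):
        x = featurize(RnaSequence("s", "ACG"), vocab)
        assert not x[vocab.block_slice(4)].any()
        assert x.sum() == pytest.approx(84 / 340, abs=1e-9)

    @settings(max_examples=100, deadline=None)
    @given(bases=st.text(alphabet="ACGU", min_size=4, max_size=150))
    def test_sum_to_one_for_valid_sequences(self, vocab, bases):
        x = featurize(bases, vocab)
        assert (x >= 0).all()
        assert x.sum() == pytest.approx(1, abs=1e-9)

    @settings(max_examples=50, deadline=None)
    @given(raw=st.text(alphabet="acgtACGT", min_size=4, max_size=80))
    def test_invariant_to_case_and_t_vs_u(self, vocab, raw):
        a = featurize(normalize_bases(raw), vocab)
        b = featurize(normalize_bases(raw.lower().replace("t", "u")), vocab)
        np.testing.assert_array_equal(a, b)

    def test_single_base_change_bounded_effect(self, vocab):
        # one substitution touches at most n windows per type = 10 windows total
        rng = np.random.default_rng(0)
        bases = "".join(rng.choice(list("ACGU"), size=100))
        mutated = bases[:50] + ("A" if bases[50] != "A" else "C") + bases[51:]
        changed = 0
        for n in (1, 2, 3, 4):
            ca, cb = oracle_counts(bases, n), oracle_counts(mutated, n)
            changed += sum(abs(ca[g] - cb[g]) for g in set(ca) | set(cb))
        assert changed <= 2 * (1 + 2 + 3 + 4)  # each touched window moves one count out, one in
        a, b = featurize(bases, vocab), featurize(mutated, vocab)
        bound = sum(
            vocab.concentrations[n] * 2 * n / (100 - n + 1) for n in (1, 2, 3, 4)
        )
        assert np.abs(a - b).sum() <= bound + 1e-12

    def test_dataset_featurization_aligned_and_deterministic(self, vocab):
        recs = (
            RnaSequence("a", "ACGUACGU", family="f1"),
            RnaSequence("b", "ACGUACGU", family="f1"),
            RnaSequence("c", "UUUUGGGG", family="f2"),
        )
        X, y = featurize_dataset(LabeledDataset(recs), vocab)
        assert X.shape == (3, 340)
        assert y == ["f1", "f1", "f2"]
        np.testing.assert_array_equal(X[0], X[1])
        assert not np.array_equal(X[0], X[2])


class TestCentersAndVariance:
    def test_center_identities(self):
        v = np.array([1.0, 0.0])
        w = np.array([0.0, 1.0])
        np.testing.assert_array_equal(family_center([v]), v)
        np.testing.assert_array_equal(family_center([v, w]), [0.5, 0.5])
        assert family_center([v, w]).sum() == pytest.approx(1)
        with pytest.raises(ParameterError):
            family_center([])

    def test_distance_identities(self):
        v = np.array([1.0, 0.0])
        w = np.array([0.0, 1.0])
        assert center_distance(v, v) == 0
        assert center_distance(v, w) == pytest.approx(np.sqrt(2))
        assert center_distance(v, w) == center_distance(w, v)
        with pytest.raises(ParameterError):
            center_distance(v, np.zeros(3))

    def test_variance_identities(self):
        c = 1.7
        centers = [np.array([0.0, 5.0]), np.array([2 * c, 5.0])]
        var = feature_variance_across_families(centers)
        assert var[0] == pytest.approx(c**2)
        assert var[1] == 0
        scaled = feature_variance_across_families([3 * x for x in centers])
        np.testing.assert_allclose(scaled, 9 * var)
        with pytest.raises(ParameterError):
            feature_variance_across_families([centers[0]])


class TestExport:
    def test_csv_header_matches_vocabulary_order(self, tmp_path, vocab):
        X = np.vstack([featurize("ACGUACGU", vocab)])
        path = tmp_path / "feats.csv"
        write_feature_csv(X, vocab, path, ids=["s1"])
        header = path.read_text().splitlines()[0].split(",")
        assert header[0] == "id"
        assert header[1] == "AAAA"
        assert header[-1] == "U"
        assert len(header) == 341

    def test_svmlight_one_based_sparse(self, tmp_path, vocab):
        X = np.vstack([featurize("AAAA", vocab)])
        path = tmp_path / "feats.svm"
        mapping = write_svmlight(X, ["fam1"], path)
        line = path.read_text().strip()
        assert mapping == {"fam1": 1}
        idx_a = vocab.index_of("AAAA") + 1
        assert line.startswith("1 ")
        assert f"{idx_a}:" in line
        assert "0:" not in line.split(" ", 1)[1]
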