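import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from _oracles import kmer_counts, reversal_classes
from sglut import encoders as enc
from sglut.seqio import ALPHABET, POSITIVE, NEGATIVE, SglutError, WindowSample

PEP = "HLGYVLTCPSNLGTG"  # a real 15-mer window (creatine kinase)

peptide_strategy = st.builds(
    lambda left, right: left + "C" + right,
    st.text(alphabet=ALPHABET, min_size=7, max_size=7),
    st.text(alphabet=ALPHABET, min_size=7, max_size=7),
)


class TestDimensionalities:
    @pytest.mark.parametrize(
        "scheme,expected",
        [
            ("single_aa", 20),
            ("reduced_comp", 10),
            ("pair_aa", 400),
            ("triplet_aa", 8000),
            ("reduced_triplet_aa", 4200),
            ("binary_profile", 300),
            ("biprofile_bayes", 30),
            ("physchem", 10),
        ],
    )
    def test_scheme_dimension(self, scheme, expected):
        assert enc.scheme_dimension(scheme, 15) == expected

    def test_vectors_match_declared_dimension(self, random_windows):
        windows = random_windows(6)
        profile = enc.fit_biprofile(windows)
        for scheme in enc.SCHEMES:
            matrix = enc.encode_windows(windows, scheme, profile=profile)
            assert matrix.values.shape == (6, enc.scheme_dimension(scheme, 15))
            assert len(matrix.feature_names) == matrix.values.shape[1]

    def test_unknown_scheme(self):
        with pytest.raises(SglutError, match="unknown"):
            enc.scheme_dimension("kmer_spectrum", 15)


class TestSingleAndReduced:
    def test_uniform_sequence(self):
        v = enc.encode_single("A" * 15)
        assert v[enc.AA_INDEX["A"]] == 1.0
        assert v.sum() == pytest.approx(1.0)

    def test_hand_count(self):
        v = enc.encode_single(PEP)
        assert v[enc.AA_INDEX["G"]] == pytest.approx(3 / 15)
        assert v[enc.AA_INDEX["L"]] == pytest.approx(3 / 15)
        for aa in set(PEP):
            assert v[enc.AA_INDEX[aa]] == pytest.approx(PEP.count(aa) / 15)

    def test_reduced_single_class_sequence(self):
        v = enc.encode_reduced_comp("C" * 15)
        assert list(v[:3]) == [0.0, 0.0, 1.0]  # C is hydrophobic
        sulfur = 3 + list(enc.SEVEN_CLASSES).index("sulfur")
        assert v[sulfur] == 1.0

    def test_reduced_hand_tally(self):
        # polar: N (1); neutral: H,G,Y,T,P,S,G,T,G (9); hydrophobic: L,V,L,C,L (5)
        v = enc.encode_reduced_comp(PEP)
        assert v[:3] == pytest.approx([1 / 15, 9 / 15, 5 / 15])
        # 7-class: aliphatic L3+V1+G3+P1=8, base H, aromatic Y, amide N,
        # small hydroxyl S1+T2=3, sulfur C
        assert v[3:] == pytest.approx(
            [8 / 15, 0.0, 1 / 15, 1 / 15, 1 / 15, 3 / 15, 1 / 15]
        )

    def test_blocks_sum_to_one(self, random_windows):
        for win in random_windows(50):
            v = enc.encode_reduced_comp(win.peptide)
            assert v[:3].sum() == pytest.approx(1.0)
            assert v[3:].sum() == pytest.approx(1.0)

    def test_table5_memberships_partition_alphabet(self):
        assert sorted("".join(enc.THREE_CLASSES.values())) == sorted(ALPHABET)
        assert sorted("".join(enc.SEVEN_CLASSES.values())) == sorted(ALPHABET)


class TestKmerEncoders:
    def test_pair_uniform(self):
        v = enc.encode_pair("A" * 15)
        assert v[enc.AA_INDEX["A"] * 20 + enc.AA_INDEX["A"]] == 1.0

    def test_triplet_uniform(self):
        v = enc.encode_triplet("A" * 15)
        assert v.sum() == 13
        assert v.max() == 13

    def test_pair_matches_counting_oracle(self, random_windows):
        names = enc.feature_names("pair_aa", 15)
        for win in random_windows(100):
            v = enc.encode_pair(win.peptide)
            counts = kmer_counts(win.peptide, 2)
            assert v.sum() == pytest.approx(1.0)
            for kmer, n in counts.items():
                assert v[names.index(kmer)] == pytest.approx(n / 14)

    def test_triplet_matches_counting_oracle(self, random_windows):
        names = enc.feature_names("triplet_aa", 15)
        for win in random_windows(100):
            v = enc.encode_triplet(win.peptide)
            assert v.sum() == 13
            for kmer, n in kmer_counts(win.peptide, 3).items():
                assert v[names.index(kmer)] == n


class TestReducedTriplet:
    def test_class_count_matches_enumeration_oracle(self):
        assert len(enc.reduced_triplet_classes()) == len(reversal_classes())

    def test_reversed_triplets_share_a_feature(self):
        a = enc.encode_reduced_triplet("ABD".replace("B", "N") + "A" * 12)
        b = enc.encode_reduced_triplet("DNA" + "A" * 12)
        idx = enc._reduced_triplet_index()[enc.canonical_triplet("AND")]
        assert a[idx] >= 1 and b[idx] >= 1

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(peptide_strategy)
    def test_reversal_invariance(self, peptide):
        v1 = enc.encode_reduced_triplet(peptide)
        v2 = enc.encode_reduced_triplet(peptide[::-1])
        assert np.array_equal(v1, v2)
        assert v1.sum() == len(peptide) - 2

    def test_aggregation_equals_triplet_pair_sums(self, random_windows):
        trip_names = enc.feature_names("triplet_aa", 15)
        red_index = enc._reduced_triplet_index()
        for win in random_windows(30):
            full = enc.encode_triplet(win.peptide)
            red = enc.encode_reduced_triplet(win.peptide)
            agg = np.zeros_like(red)
            for j, t in enumerate(trip_names):
                agg[red_index[enc.canonical_triplet(t)]] += full[j]
            assert np.array_equal(agg, red)


class TestBinaryProfile:
    def test_one_hot_structure(self):
        v = enc.encode_binary(PEP)
        assert v.shape == (300,)
        assert v.sum() == 15
        blocks = v.reshape(15, 20)
        assert np.array_equal(blocks.sum(axis=1), np.ones(15))

    def test_center_block_is_cysteine(self, random_windows):
        for win in random_windows(30):
            blocks = enc.encode_binary(win.peptide).reshape(15, 20)
            assert blocks[7, enc.AA_INDEX["C"]] == 1.0

    def test_block_order_follows_alphabet(self):
        v = enc.encode_binary("A" * 7 + "C" + "Y" * 7)
        assert v[0] == 1.0  # A is the first slot of block 1
        assert v[-1] == 1.0  # Y is the last slot of the last block


class TestBiProfile:
    def _windows(self, peptides, labels):
        return [
            WindowSample(f"p{i}", 8, pep, lab)
            for i, (pep, lab) in enumerate(zip(peptides, labels))
        ]

    def test_unanimous_column(self):
        wins = self._windows(
            ["A" * 7 + "C" + "A" * 7, "A" * 7 + "C" + "G" * 7, "G" * 7 + "C" + "G" * 7],
            [POSITIVE, POSITIVE, NEGATIVE],
        )
        profile = enc.fit_biprofile(wins)
        assert profile.pos_freq[0, enc.AA_INDEX["A"]] == 1.0

    def test_row_sums_one_both_classes(self, random_windows):
        profile = enc.fit_biprofile(random_windows(50), pseudocount=0.5)
        assert np.allclose(profile.pos_freq.sum(axis=1), 1.0)
        assert np.allclose(profile.neg_freq.sum(axis=1), 1.0)

    def test_matches_counting_oracle(self, random_windows):
        wins = random_windows(50)
        profile = enc.fit_biprofile(wins)
        pos = [w for w in wins if w.label == POSITIVE]
        for i in range(15):
            for aa in ALPHABET:
                expected = sum(w.peptide[i] == aa for w in pos) / len(pos)
                assert profile.pos_freq[i, enc.AA_INDEX[aa]] == pytest.approx(expected)

    def test_encode_sole_positive_training_window(self):
        pep = "HLGYVLTCPSNLGTG"
        wins = self._windows([pep, "A" * 7 + "C" + "A" * 7], [POSITIVE, NEGATIVE])
        profile = enc.fit_biprofile(wins)
        v = enc.encode_biprofile(pep, profile)
        assert v.shape == (30,)
        assert np.allclose(v[:15], 1.0)

    def test_entries_in_unit_interval(self, random_windows):
        wins = random_windows(40)
        profile = enc.fit_biprofile(wins, pseudocount=0.1)
        for win in random_windows(20):
            v = enc.encode_biprofile(win.peptide, profile)
            assert np.all((v >= 0) & (v <= 1))

    def test_errors(self, random_windows):
        only_pos = [
            WindowSample("p", 8, "A" * 7 + "C" + "A" * 7, POSITIVE) for _ in range(3)
        ]
        with pytest.raises(SglutError, match="each class"):
            enc.fit_biprofile(only_pos)
        profile = enc.fit_biprofile(random_windows(10))
        with pytest.raises(SglutError, match="length"):
            enc.encode_biprofile("ACC", profile)


class TestPhyschem:
    def test_homogeneous_window(self):
        table = enc.load_property_table()
        v = enc.encode_physchem("A" * 15, table)
        assert v == pytest.approx(15 * table.loc["A"].to_numpy())

    def test_permutation_invariance(self, rng):
        table = enc.load_property_table()
        pep = "HLGYVLTCPSNLGTG"
        shuffled = "".join(rng.permutation(list(pep)))
        assert enc.encode_physchem(pep, table) == pytest.approx(
            enc.encode_physchem(shuffled, table)
        )

    def test_packaged_table_shape(self):
        table = enc.load_property_table()
        assert table.shape == (20, 10)
        assert not table.isna().any().any()
        assert sorted(table.index) == sorted(ALPHABET)

    def test_default_table_used_when_omitted(self):
        assert enc.encode_physchem(PEP) == pytest.approx(
            enc.encode_physchem(PEP, enc.load_property_table())
        )


class TestNonStandardHandling:
    def test_encoders_reject_nonstandard(self):
        for fn in (enc.encode_single, enc.encode_pair, enc.encode_triplet,
                   enc.encode_reduced_triplet, enc.encode_binary):
            with pytest.raises(SglutError, match="non-standard"):
                fn("A" * 7 + "C" + "AXAAAAA")

    def test_filter_standard(self):
        good = WindowSample("a", 8, "A" * 7 + "C" + "A" * 7, POSITIVE)
        bad = WindowSample("b", 8, "A" * 7 + "C" + "AXAAAAA", NEGATIVE)
        assert enc.filter_standard([good, bad]) == [good]
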