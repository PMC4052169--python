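import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quadpre import seq_features as sf
from quadpre.scales import DEFAULT_SCALES, STANDARD_AAS

from .oracles import brute_autocorr, brute_cmv, brute_cumulative_autocorr

seqs = st.text(alphabet=STANDARD_AAS, min_size=12, max_size=60)


def idx(aa):
    return STANDARD_AAS.index(aa)


class TestComposition:
    @pytest.mark.parametrize("seq,expect", [
        ("AAAA", {"A": 1.0}),
        ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
        ("ACACAC", {"A": 0.5, "C": 0.5}),
    ])
    def test_examples(self, seq, expect):
        v = sf.composition_vector(seq)
        for aa in STANDARD_AAS:
            assert v[idx(aa)] == pytest.approx(expect.get(aa, 0.0))

    def test_placeholder_excluded_from_counts(self):
        assert sf.composition_vector("AXXA")[idx("A")] == 1.0

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            sf.composition_vector("")


class TestGroupCounts:
    def test_de_lands_in_negative_and_donor_groups(self):
        counts = sf.group_counts("DE")
        names = [f"{g}_{sub}" for g, groups in DEFAULT_SCALES.all_groupings()
                 for sub, _ in groups]
        got = dict(zip(names, counts))
        assert got["R_negatively_charged"] == 2
        assert got["electronic_electron_donor"] == 2
        assert got["hydrophobicity_polar"] == 2
        assert got["exchange_acid_amide"] == 2
        assert sum(counts) == 8  # 2 residues x 4 groupings

    @settings(deadline=None, max_examples=30)
    @given(seq=seqs)
    def test_each_grouping_partitions_the_residues(self, seq):
        counts = sf.group_counts(seq)
        offset = 0
        for _, groups in DEFAULT_SCALES.all_groupings():
            assert counts[offset:offset + len(groups)].sum() == len(seq)
            offset += len(groups)


class TestCompositionMomentVector:
    def test_hand_example_order1(self):
        v = sf.composition_moment_vector("AC", 1)
        assert v[idx("A")] == pytest.approx(1 / 2)
        assert v[idx("C")] == pytest.approx(2 / 2 / 1)

    def test_absent_residue_is_zero(self):
        assert sf.composition_moment_vector("ACAC", 2)[idx("W")] == 0.0

    def test_too_short_for_order(self):
        with pytest.raises(ValueError):
            sf.composition_moment_vector("AC", 2)

    @settings(deadline=None, max_examples=50)
    @given(seq=seqs, order=st.sampled_from([1, 2]))
    def test_matches_brute_force(self, seq, order):
        v = sf.composition_moment_vector(seq, order)
        for aa in "ACWY":
            assert v[idx(aa)] == pytest.approx(brute_cmv(seq, aa, order),
                                               abs=1e-12)


class TestMeanIsoelectricPoint:
    @pytest.mark.parametrize("seq,expect", [
        ("G", DEFAULT_SCALES.pi["G"]),
        ("WWWW", DEFAULT_SCALES.pi["W"]),
        ("AG", (DEFAULT_SCALES.pi["A"] + DEFAULT_SCALES.pi["G"]) / 2),
    ])
    def test_examples(self, seq, expect):
        assert sf.mean_isoelectric_point(seq) == pytest.approx(expect)

    def test_no_standard_residues(self):
        with pytest.raises(ValueError):
            sf.mean_isoelectric_point("XXX")


class TestAutocorrelation:
    @pytest.mark.parametrize("scale", ["FH", "EH", "HP"])
    def test_homopolymer_equals_square_of_scale_value(self, scale):
        c = DEFAULT_SCALES.scale(scale)["W"]
        assert sf.autocorrelation("W" * 9, scale, 3) == pytest.approx(c * c)

    def test_lag_equal_to_length_is_error(self):
        with pytest.raises(ValueError):
            sf.autocorrelation("ACDE", "FH", 4)

    @settings(deadline=None, max_examples=50)
    @given(seq=seqs, scale=st.sampled_from(["FH", "EH", "HP"]),
           lag=st.integers(min_value=1, max_value=10))
    def test_matches_brute_force(self, seq, scale, lag):
        expect = brute_autocorr(seq, DEFAULT_SCALES.scale(scale), lag)
        assert sf.autocorrelation(seq, scale, lag) == pytest.approx(
            expect, abs=1e-12)


class TestCumulativeAutocorrelation:
    def test_homopolymer_hand_value(self):
        # prefix sums c, 2c, 3c; lag 1 -> (c*2c + 2c*3c)/2 = 4c^2
        c = DEFAULT_SCALES.fh["I"]
        assert sf.cumulative_autocorrelation("III", 1) == pytest.approx(4 * c * c)

    def test_lag_at_least_length_is_error(self):
        with pytest.raises(ValueError):
            sf.cumulative_autocorrelation("AC", 2)

    @settings(deadline=None, max_examples=50)
    @given(seq=seqs, lag=st.integers(min_value=1, max_value=6))
    def test_matches_quadratic_oracle(self, seq, lag):
        expect = brute_cumulative_autocorr(seq, DEFAULT_SCALES.fh, lag)
        assert sf.cumulative_autocorrelation(seq, lag) == pytest.approx(
            expect, abs=1e-10)


class TestHydrophobicitySum:
    def test_homopolymer(self):
        assert sf.hydrophobicity_sum("C" * 5, "FH") == pytest.approx(
            5 * DEFAULT_SCALES.fh["C"])

    @settings(deadline=None, max_examples=30)
    @given(s1=seqs, s2=seqs, scale=st.sampled_from(["FH", "EH"]))
    def test_concatenation_additivity(self, s1, s2, scale):
        assert sf.hydrophobicity_sum(s1 + s2, scale) == pytest.approx(
            sf.hydrophobicity_sum(s1, scale) + sf.hydrophobicity_sum(s2, scale))

    def test_empty_is_error(self):
        with pytest.raises(ValueError):
            sf.hydrophobicity_sum("", "FH")


class TestGroupPercentages:
    def test_positively_charged_only(self):
        v = sf.group_percentages("KHR", "R")
        assert v.tolist() == [0.0, 0.0, 1.0, 0.0, 0.0]

    def test_electron_donors_only(self):
        v = sf.group_percentages("DEPA", "electronic")
        assert v.tolist() == [1.0, 0.0, 0.0, 0.0, 0.0]

    @settings(deadline=None, max_examples=30)
    @given(seq=seqs, grouping=st.sampled_from(["R", "electronic"]))
    def test_percentages_sum_to_one(self, seq, grouping):
        assert sf.group_percentages(seq, grouping).sum() == pytest.approx(
            1.0, abs=1e-12)


class TestSequenceFeatureBlock:
    def test_width_and_determinism(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AAS), size=30))
        a = sf.sequence_feature_block(seq)
        b = sf.sequence_feature_block(seq)
        assert a.shape == (123,)
        assert np.array_equal(a, b)
        assert len(sf.seq_feature_names()) == 123

    def test_permutation_changes_positional_but_not_compositional(self, rng):
        seq = "".join(rng.choice(list(STANDARD_AAS), size=40))
        perm = "".join(rng.permutation(list(seq)))
        a, b = sf.sequence_feature_block(seq), sf.sequence_feature_block(perm)
        names = sf.seq_feature_names()
        comp = [i for i, n in enumerate(names)
                if n.startswith(("comp_", "count_", "rgroup", "egroup"))
                or n in ("length", "mean_pi", "hsum_FH", "hsum_EH")]
        assert np.allclose(a[comp], b[comp])
        positional = [i for i, n in enumerate(names)
                      if n.startswith(("cmv", "ac_", "cumac"))]
        assert not np.allclose(a[positional], b[positional])
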