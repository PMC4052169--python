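import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quadpre.core_io import LeakageError
from quadpre.motif_features import (GAP, GIBBS_ALPHABET, GIBBSMotif, GLAM2Motif,
                                    MotifLibrary, gibbs_feature_block,
                                    gibbs_penalty, glam2_feature_block,
                                    glam2_penalty, preprocess_glam2,
                                    read_gibbs_motif, read_glam2_motifs,
                                    sw_align, write_gibbs_motif,
                                    write_glam2_motifs)

from .oracles import enumerate_local_score


def set_motif(*columns, **kw):
    return GLAM2Motif(positions=tuple(frozenset(c) for c in columns), **kw)


def prob_motif(consensus, p=1.0, **kw):
    m = np.full((len(consensus), 21), (1 - p) / 20)
    for i, ch in enumerate(consensus):
        m[i, GIBBS_ALPHABET.index(ch)] = p
        m[i] /= m[i].sum()
    return GIBBSMotif(matrix=m, **kw)


class TestPreprocessing:
    def test_long_gap_run_splits_then_short_fragment_is_deleted(self):
        motif = set_motif("A", "C", *["-"] * 6, "D", "E", "F", "G", "H")
        out = preprocess_glam2(motif)
        assert len(out) == 1
        assert [sorted(p) for p in out[0].positions] == \
            [["D"], ["E"], ["F"], ["G"], ["H"]]

    def test_exactly_five_gaps_unchanged(self):
        motif = set_motif("A", "C", "D", "E", "F", *["-"] * 5, "G")
        out = preprocess_glam2(motif)
        assert len(out) == 1
        assert out[0].positions == motif.positions

    def test_fewer_than_five_residue_positions_deleted(self):
        assert preprocess_glam2(set_motif("A", "C", "D", "E")) == []

    def test_recursive_left_to_right_splitting(self):
        motif = set_motif("A", "C", "D", "E", "F", *["-"] * 7,
                          "G", "H", "I", "K", "L", *["-"] * 8,
                          "M", "N")
        out = preprocess_glam2(motif)
        assert len(out) == 2
        assert all(m.n_aa_positions == 5 for m in out)

    def test_mixed_position_with_gap_and_residue_is_not_gap_only(self):
        motif = set_motif("A", "C", "D", "E", *["A-"] * 6)
        # positions allowing both a residue and a gap never trigger the split
        out = preprocess_glam2(motif)
        assert len(out) == 1 and len(out[0]) == 10


class TestPenalties:
    @pytest.mark.parametrize("position,symbol,expected", [
        ({"A", "C"}, "A", 1.0),          # allowed residue
        ({"A", "-"}, "-", 0.0),          # gap allowed at the position
        ({"A", "C"}, "D", -1.0),         # disallowed residue
        ({"A"}, "-", -1.0 / 3.0),        # gap at a gap-free position
    ])
    def test_set_motif_cases(self, position, symbol, expected):
        assert glam2_penalty(frozenset(position), symbol) == pytest.approx(expected)

    def test_invalid_symbol(self):
        with pytest.raises(ValueError):
            glam2_penalty(frozenset("A"), "1")

    def test_degenerate_probability_column(self):
        m = prob_motif("A", p=1.0)
        assert gibbs_penalty(m.matrix[0], "A") == pytest.approx(1.0)
        assert gibbs_penalty(m.matrix[0], "C") == pytest.approx(0.0)

    def test_uniform_column(self):
        col = np.full(21, 1 / 21)
        for ch in "ACDEFG-":
            assert gibbs_penalty(col, ch) == pytest.approx(1 / 21)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1), symbol=st.sampled_from(GIBBS_ALPHABET))
    def test_probabilities_bounded(self, seed, symbol):
        col = np.random.default_rng(seed).dirichlet(np.ones(21))
        assert 0.0 <= gibbs_penalty(col, symbol) <= 1.0


class TestSmithWaterman:
    def test_perfect_singleton_match_scores_motif_length(self):
        motif = set_motif("D", "E", "F", "G", "H")
        assert sw_align("ACDEFGHIKL", motif) == pytest.approx(5.0)

    def test_disjoint_symbols_floor_at_zero(self):
        motif = set_motif("W", "W", "W", "W", "W")
        assert sw_align("ACDE", motif) == pytest.approx(0.0)

    def test_degenerate_probability_substring_scores_length(self):
        motif = prob_motif("CDEFGH", p=1.0)
        assert sw_align("ACDEFGHIK", motif) == pytest.approx(6.0)

    def test_monotone_under_matching_extension(self):
        short = set_motif("D", "E", "F", "G", "H")
        longer = set_motif("D", "E", "F", "G", "H", "I")
        seq = "ACDEFGHIKL"
        assert sw_align(seq, longer) >= sw_align(seq, short)

    @settings(deadline=None, max_examples=60)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_random_instances_match_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDW"), size=int(rng.integers(1, 9))))
        n = int(rng.integers(1, 5))
        if rng.random() < 0.5:
            cols = []
            for _ in range(n):
                size = int(rng.integers(1, 4))
                cols.append(rng.choice(list("ACDW-"), size=size, replace=False))
            motif = set_motif(*("".join(c) for c in cols))
        else:
            motif = GIBBSMotif(matrix=rng.dirichlet(np.ones(21), size=n))
        assert sw_align(seq, motif) == pytest.approx(
            enumerate_local_score(seq, motif), abs=1e-10)

    @settings(deadline=None, max_examples=30)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_score_never_negative(self, seed):
        rng = np.random.default_rng(seed)
        seq = "".join(rng.choice(list("ACDEFGHIKL"), size=12))
        motif = set_motif(*rng.choice(list("WY"), size=4))
        assert sw_align(seq, motif) >= 0.0


class TestFeatureBlocks:
    def _library(self, n_folds=2):
        lib = MotifLibrary(n_folds=n_folds)
        others = frozenset([2])
        for cls in (1, 2, 3, 4, 6, 8):
            lib.glam2[(1, cls)] = [set_motif("D", "E", "F", "G", "H",
                                             source_class=cls,
                                             source_folds=others)]
            lib.gibbs[(1, cls)] = prob_motif("DEFGH", p=1.0,
                                             source_class=cls,
                                             source_folds=others)
        return lib

    def test_padding_contract_single_motif(self):
        lib = self._library()
        block = glam2_feature_block("ACDEFGHIKL", 1, lib)
        assert block.shape == (30,)
        for k in range(6):
            sub = block[5 * k:5 * k + 5]
            assert sub[0] == pytest.approx(5.0)
            assert np.allclose(sub[1:], 0.0)
            assert all(sub[i] >= sub[i + 1] for i in range(4))

    def test_gibbs_block_width_and_value(self):
        lib = self._library()
        block = gibbs_feature_block("ACDEFGHIKL", 1, lib)
        assert block.shape == (6,)
        assert np.allclose(block, 5.0)

    def test_missing_class_pads_with_warning(self):
        lib = self._library()
        del lib.glam2[(1, 8)]
        with pytest.warns(UserWarning, match="padded"):
            block = glam2_feature_block("ACDEFGHIKL", 1, lib)
        assert np.allclose(block[25:], 0.0)

    def test_own_fold_motif_raises_leakage_error(self):
        lib = self._library()
        lib.glam2[(1, 1)] = [set_motif("D", "E", "F", "G", "H",
                                       source_folds=frozenset([1, 2]))]
        with pytest.raises(LeakageError):
            glam2_feature_block("ACDEFGHIKL", 1, lib)

    def test_column_order_matters(self):
        fwd = prob_motif("DEFGHI", p=1.0)
        rev = GIBBSMotif(matrix=fwd.matrix[::-1].copy())
        seq = "ACDEFGHIKL"
        assert sw_align(seq, fwd) != pytest.approx(sw_align(seq, rev))


class TestMotifFiles:
    def test_glam2_round_trip(self, tmp_path):
        motifs = [set_motif("A", "C-", "DE"), set_motif("W", "Y", "-")]
        p = tmp_path / "m.glam2.txt"
        write_glam2_motifs(motifs, p)
        back = read_glam2_motifs(p)
        assert [m.positions for m in back] == [m.positions for m in motifs]

    def test_gibbs_round_trip(self, tmp_path):
        motif = prob_motif("ACD", p=0.9)
        p = tmp_path / "m.gibbs.txt"
        write_gibbs_motif(motif, p)
        back = read_gibbs_motif(p)
        assert np.allclose(back.matrix, motif.matrix, atol=1e-5)
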