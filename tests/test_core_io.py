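import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from quadpre import core_io
from quadpre.core_io import (BlastHit, ProteinRecord, normalize_sequence,
                             partition_folds, read_blast_tab, read_fasta,
                             read_pssm, read_rsa, read_ss2, validate_class,
                             write_fasta, write_pssm)


class TestFasta:
    def test_basic_parse(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nACDE\n")
        recs = read_fasta(p)
        assert len(recs) == 1
        assert recs[0].sequence == "ACDE" and recs[0].length == 4

    def test_case_and_whitespace_normalization(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\nac de\n")
        assert read_fasta(p)[0].sequence == "ACDE"

    def test_empty_after_normalization_is_error(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">x\n123\n")
        with pytest.raises(ValueError, match="empty sequence"):
            read_fasta(p)

    def test_missing_file(self, tmp_path):
        with pytest.raises(FileNotFoundError):
            read_fasta(tmp_path / "nope.fasta")

    def test_round_trip(self, tmp_path):
        records = [ProteinRecord(id=f"r{i}", sequence=s)
                   for i, s in enumerate(["ACDE", "WWWW", "MKVLXA"])]
        p = tmp_path / "rt.fasta"
        write_fasta(records, p)
        back = read_fasta(p)
        assert [(r.id, r.sequence) for r in back] == \
            [(r.id, r.sequence) for r in records]

    @pytest.mark.parametrize("raw,expected", [
        ("BZUJ", "NQCL"),        # ambiguity/rare letter aliases
        ("AO*A", "AXA"),         # unknown letter -> placeholder, '*' dropped
        ("a c\nd", "ACD"),
    ])
    def test_normalize_policy(self, raw, expected):
        assert normalize_sequence(raw) == expected


class TestOligomerClass:
    @pytest.mark.parametrize("c", [1, 2, 3, 4, 6, 8])
    def test_admissible(self, c):
        assert validate_class(c) == c

    @pytest.mark.parametrize("c", [0, 5, 7, 9, -1])
    def test_rejected(self, c):
        with pytest.raises(ValueError):
            validate_class(c)


class TestProfiles:
    def test_pssm_round_trip_and_length_check(self, tmp_path):
        rng = np.random.default_rng(0)
        m = np.rint(rng.normal(0, 3, size=(4, 20)))
        p = tmp_path / "x.pssm"
        write_pssm(m, "ACDE", p)
        assert np.array_equal(read_pssm(p, 4), m)
        with pytest.raises(ValueError, match="expected 5"):
            read_pssm(p, 5)

    def test_pssm_non_numeric_cell(self, tmp_path):
        p = tmp_path / "bad.pssm"
        lines = ["", "header", "   A R"] + \
            [f"{i+1} A " + " ".join(["1"] * 20) for i in range(3)]
        lines[3] = "1 A oops " + " ".join(["1"] * 19)
        p.write_text("\n".join(lines) + "\n")
        with pytest.raises(ValueError, match="non-numeric"):
            read_pssm(p, 3)

    def test_ss2_parse(self, tmp_path):
        p = tmp_path / "x.ss2"
        p.write_text("# header\n\n1 A H 0.1 0.8 0.1\n2 C E 0.2 0.1 0.7\n"
                     "3 D C 0.9 0.05 0.05\n")
        ss = read_ss2(p, 3)
        assert ss.states == "HEC"
        # file columns are C,H,E; stored columns are H,E,C
        assert ss.confidence[0].tolist() == [0.8, 0.1, 0.1]

    def test_ss2_unknown_state(self, tmp_path):
        p = tmp_path / "x.ss2"
        p.write_text("1 A G 0.1 0.8 0.1\n")
        with pytest.raises(ValueError, match="only H/E/C"):
            read_ss2(p, 1)

    def test_rsa_clip_with_warning(self, tmp_path):
        p = tmp_path / "x.rsa"
        p.write_text("1\t0.5\n2\t1.2\n")
        with pytest.warns(UserWarning, match="clipped"):
            rsa = read_rsa(p, 2)
        assert rsa.tolist() == [0.5, 1.0]

    def test_rsa_length_mismatch(self, tmp_path):
        p = tmp_path / "x.rsa"
        p.write_text("1\t0.5\n")
        with pytest.raises(ValueError):
            read_rsa(p, 2)


class TestBlastTab:
    def test_sorted_ascending_by_evalue(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts1\t1e-5\nq\ts2\t1e-50\nq\ts3\t2\n")
        tables = read_blast_tab(p, {"s1": 1, "s2": 1, "s3": 2})
        evs = [h.evalue for h in tables["q"].hits]
        assert evs == sorted(evs) == [1e-50, 1e-5, 2.0]

    def test_unknown_subject_dropped_with_warning(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\tknown\t1e-5\nq\tmystery\t1e-9\n")
        with pytest.warns(UserWarning, match="dropped 1"):
            tables = read_blast_tab(p, {"known": 2})
        assert len(tables["q"].hits) == 1

    def test_negative_evalue_is_error(self, tmp_path):
        p = tmp_path / "hits.tsv"
        p.write_text("q\ts\t-1\n")
        with pytest.raises(ValueError, match="negative E-value"):
            read_blast_tab(p, {"s": 1})

    def test_hit_invariants(self):
        with pytest.raises(ValueError):
            BlastHit(subject_id="s", subject_class=1, evalue=float("inf"))


def _dummy_records(counts):
    records = []
    for cls, n in counts.items():
        for k in range(n):
            records.append(ProteinRecord(id=f"c{cls}_{k}", sequence="ACDEFGHIKL",
                                         label=cls))
    return records


class TestPartitionFolds:
    def test_forced_two_fold_layout(self):
        records = _dummy_records({c: 2 for c in (1, 2, 3, 4, 6, 8)})
        fa = partition_folds(records, n_folds=2, seed=0)
        assert fa.fold_sizes() == [6, 6]
        for fold in (1, 2):
            for cls in (1, 2, 3, 4, 6, 8):
                assert len(fa.roster(fold, cls)) == 1

    def test_pigeonhole_error_under_strict_policy(self):
        counts = {c: 12 for c in (1, 2, 3, 4, 6, 8)}
        counts[8] = 1
        with pytest.raises(ValueError, match="fewer than"):
            partition_folds(_dummy_records(counts), n_folds=10, seed=0)
        # relaxed policy accepts, still balanced
        fa = partition_folds(_dummy_records(counts), n_folds=10, seed=0,
                             allow_missing_class=True)
        sizes = fa.fold_sizes()
        assert max(sizes) - min(sizes) <= 1

    def test_deterministic_for_fixed_seed(self):
        records = _dummy_records({c: 15 for c in (1, 2, 3, 4, 6, 8)})
        a = partition_folds(records, n_folds=5, seed=3)
        b = partition_folds(records, n_folds=5, seed=3)
        assert a.assignment == b.assignment
        c = partition_folds(records, n_folds=5, seed=4)
        assert a.assignment != c.assignment

    @settings(deadline=None, max_examples=25)
    @given(counts=st.lists(st.integers(min_value=3, max_value=40),
                           min_size=6, max_size=6),
           seed=st.integers(min_value=0, max_value=2**31 - 1))
    def test_partition_invariants(self, counts, seed):
        """Sizes differ by <= 1, every fold covers every class, and the
        per-fold class rosters conserve the totals."""
        by_class = dict(zip((1, 2, 3, 4, 6, 8), counts))
        records = _dummy_records(by_class)
        fa = partition_folds(records, n_folds=3, seed=seed)
        sizes = fa.fold_sizes()
        assert sum(sizes) == len(records)
        assert max(sizes) - min(sizes) <= 1
        for fold in range(1, 4):
            roster_total = 0
            for cls in (1, 2, 3, 4, 6, 8):
                r = fa.roster(fold, cls)
                assert len(r) >= 1
                roster_total += len(r)
            assert roster_total == sizes[fold - 1]
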