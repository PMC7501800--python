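"""Sequence I/O, global alignment (against a brute-force oracle), statistics."""

import itertools

import numpy as np
import pytest

from ratesub.alignio import (
    AlignmentError,
    PairwiseAlignment,
    SequenceRecord,
    alignment_stats,
    global_align,
    pick_best_hit,
    read_alignment_table,
    read_fasta,
    write_alignment_table,
    write_fasta,
)
from ratesub.matrices import blosum62

B62 = blosum62()
GAP_OPEN, GAP_EXTEND = 11.0, 1.0


def brute_force_score(a: str, b: str) -> float:
    """Exhaustively enumerate every monotone alignment and score it.

    A gap run of length L costs GAP_OPEN + GAP_EXTEND * L; matches and
    mismatches score by BLOSUM62.  Independent of the DP in global_align.
    """
    best = [-np.inf]

    def recurse(i, j, last, score):
        if i == len(a) and j == len(b):
            best[0] = max(best[0], score)
            return
        if i < len(a) and j < len(b):
            recurse(i + 1, j + 1, "M", score + B62[a[i], b[j]])
        if i < len(a):  # gap in b
            cost = GAP_EXTEND + (GAP_OPEN if last != "B" else 0)
            recurse(i + 1, j, "B", score - cost)
        if j < len(b):  # gap in a
            cost = GAP_EXTEND + (GAP_OPEN if last != "A" else 0)
            recurse(i, j + 1, "A", score - cost)

    recurse(0, 0, "start", 0.0)
    return best[0]


class TestReadFasta:
    def test_order_and_ids_up_to_whitespace(self, tmp_path):
        path = tmp_path / "toy.fasta"
        path.write_text(">p1 first protein\nMKV\n>p2\nACDEFG\n")
        records = read_fasta(path)
        assert [r.id for r in records] == ["p1", "p2"]
        assert [len(r) for r in records] == [3, 6]

    def test_ambiguity_is_parsed_and_flagged(self, tmp_path):
        path = tmp_path / "amb.fasta"
        path.write_text(">p1\nMKXV\n")
        (rec,) = read_fasta(path)
        assert rec.has_ambiguity

    def test_empty_file_errors(self, tmp_path):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with pytest.raises(AlignmentError, match="no FASTA records"):
            read_fasta(path)

    def test_duplicate_ids_error(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">p1\nMKV\n>p1\nMKV\n")
        with pytest.raises(AlignmentError, match="duplicate"):
            read_fasta(path)

    def test_illegal_characters_error(self):
        with pytest.raises(AlignmentError, match="illegal"):
            SequenceRecord("p1", "MK1V")

    def test_fasta_round_trip(self, tmp_path):
        records = [SequenceRecord("a", "MKV" * 40), SequenceRecord("b", "ACDEFG")]
        path = tmp_path / "rt.fasta"
        write_fasta(records, path)
        again = read_fasta(path)
        assert [(r.id, r.residues) for r in again] == [(r.id, r.residues) for r in records]


class TestGlobalAlign:
    def test_identical_sequences(self):
        a = SequenceRecord("a", "MKVLICTWY")
        aln = global_align(a, SequenceRecord("b", a.residues))
        stats = alignment_stats(aln)
        assert stats.n_gap_columns == 0
        assert stats.percent_identity == 100.0

    def test_score_matches_exhaustive_oracle_on_small_pairs(self):
        rng = np.random.default_rng(42)
        letters = "ARND"
        for _ in range(40):
            n, m = rng.integers(1, 7, size=2)
            a = "".join(rng.choice(list(letters), n))
            b = "".join(rng.choice(list(letters), m))
            aln = global_align(SequenceRecord("a", a), SequenceRecord("b", b))
            assert aln.score == pytest.approx(brute_force_score(a, b))

    def test_reversed_sequence_scores_no_better_than_self(self):
        a = SequenceRecord("a", "MKVLICTWYARNDQEGH")
        rev = SequenceRecord("r", a.residues[::-1])
        self_score = global_align(a, SequenceRecord("b", a.residues)).score
        assert global_align(a, rev).score <= self_score

    def test_empty_sequence_rejected(self):
        with pytest.raises(AlignmentError, match="empty"):
            SequenceRecord("a", "")

    def test_deterministic(self):
        a = SequenceRecord("a", "MKVLICT")
        b = SequenceRecord("b", "MKLICTW")
        aln1, aln2 = global_align(a, b), global_align(a, b)
        assert (aln1.query_row, aln1.hit_row, aln1.score) == (aln2.query_row, aln2.hit_row, aln2.score)


class TestAlignmentStats:
    def test_gap_vs_gap_column_rejected(self):
        with pytest.raises(AlignmentError, match="gap-vs-gap"):
            PairwiseAlignment("q", "h", "A-C", "A-C")

    def test_identical_length_10_pair(self):
        aln = PairwiseAlignment("q", "h", "ACDEFGHIKL", "ACDEFGHIKL")
        stats = alignment_stats(aln)
        assert (stats.span, stats.n_match, stats.percent_identity) == (10, 10, 100.0)

    def test_identity_with_one_mismatch(self):
        aln = PairwiseAlignment("q", "h", "A" * 100, "A" * 99 + "C")
        assert alignment_stats(aln).percent_identity == 99.0

    def test_gap_columns_count_in_denominator(self):
        # 98 matches + 2 gap columns over span 100 -> 98.0, not 100.0
        aln = PairwiseAlignment("q", "h", "A" * 98 + "CC", "A" * 98 + "--")
        stats = alignment_stats(aln)
        assert stats.n_gap_columns == 2
        assert stats.percent_identity == 98.0


class TestAlignmentTable:
    def _write(self, tmp_path, rows):
        path = tmp_path / "aln.tsv"
        header = "qseqid\tsseqid\tpident\tlength\tgaps\tqlen\tqseq\tsseq\n"
        path.write_text(header + "".join("\t".join(map(str, r)) + "\n" for r in rows))
        return path

    def test_reconstructs_alignment_from_gapped_strings(self, tmp_path):
        path = self._write(tmp_path, [("q1", "h1", 80.0, 5, 1, 4, "ACD-F", "ACDEF")])
        [(aln, stats)] = read_alignment_table(path)
        assert stats.span == 5
        assert stats.n_match == 4
        assert stats.n_gap_columns == 1

    def test_unequal_row_lengths_error(self, tmp_path):
        path = self._write(tmp_path, [("q1", "h1", 80.0, 5, 0, 5, "ACDF", "ACDEF")])
        with pytest.raises(AlignmentError, match="span"):
            read_alignment_table(path)

    def test_pident_disagreement_logs_and_keeps_recomputed(self, tmp_path, caplog):
        path = self._write(tmp_path, [("q1", "h1", 99.0, 5, 0, 5, "ACDEF", "ACDEV")])
        with caplog.at_level("WARNING", logger="ratesub.alignio"):
            [(aln, stats)] = read_alignment_table(path)
        assert stats.percent_identity == 80.0
        assert "recomputed" in caplog.text

    def test_round_trip_preserves_columns(self, tmp_path):
        a = SequenceRecord("a", "MKVLICTWYARND")
        b = SequenceRecord("b", "MKVICTWYQARND")
        aln = global_align(a, b)
        pairs = [(aln, alignment_stats(aln, query_length=len(a)))]
        path = tmp_path / "rt.tsv"
        write_alignment_table(pairs, path)
        [(again, _)] = read_alignment_table(path)
        assert again.columns == aln.columns


class TestPickBestHit:
    q = SequenceRecord("q", "MKVLICT")

    def _aln(self, hit_id, q_row, h_row, score):
        return PairwiseAlignment("q", hit_id, q_row, h_row, score)

    def test_single_candidate(self):
        only = self._aln("h1", "MKV", "MKV", 10.0)
        assert pick_best_hit(self.q, [only]) is only

    def test_highest_score_wins(self):
        low = self._aln("h1", "MKV", "MKV", 80.0)
        high = self._aln("h2", "MKV", "MKV", 120.0)
        assert pick_best_hit(self.q, [low, high]) is high

    def test_score_tie_broken_by_identity_then_id(self):
        worse = self._aln("h1", "MKVLI", "MKQQI", 50.0)  # 3/5 identity
        better = self._aln("h2", "MKVLI", "MKVQI", 50.0)  # 4/5 identity
        assert pick_best_hit(self.q, [worse, better]) is better
        tie_a = self._aln("ha", "MKV", "MKV", 50.0)
        tie_b = self._aln("hb", "MKV", "MKV", 50.0)
        assert pick_best_hit(self.q, [tie_b, tie_a]) is tie_a

    def test_empty_candidates_error(self):
        with pytest.raises(AlignmentError, match="no candidate"):
            pick_best_hit(self.q, [])
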