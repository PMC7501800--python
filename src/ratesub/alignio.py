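"""Sequence and pairwise-alignment I/O plus alignment statistics.

The rate classification consumes, per ortholog pair: query length, alignment
span, number of matching residues, combined gap-column count, and percent
identity (matches / span, gap columns included in the denominator — the
BLAST convention).  Pairs can come from the internal global aligner
(:func:`global_align`) or from an external tool's tabular output with
aligned sequence strings (:func:`read_alignment_table`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd
from Bio import SeqIO
from Bio.Align import PairwiseAligner

from .matrices import AA_ORDER, AMBIGUOUS, SubstitutionMatrix, blosum62

log = logging.getLogger(__name__)

_LEGAL = set(AA_ORDER) | AMBIGUOUS
GAP = "-"

#: Default affine gap penalties (BLASTP defaults): a gap run of length L
#: costs ``gap_open + gap_extend * L``.
DEFAULT_GAP_OPEN = 11.0
DEFAULT_GAP_EXTEND = 1.0


class AlignmentError(ValueError):
    pass


@dataclass(frozen=True)
class SequenceRecord:
    """A protein sequence; ambiguity codes are tolerated but flagged."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.residues:
            raise AlignmentError(f"{self.id}: empty sequence")
        bad = set(self.residues) - _LEGAL
        if bad:
            raise AlignmentError(f"{self.id}: illegal characters {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def has_ambiguity(self) -> bool:
        return bool(set(self.residues) & AMBIGUOUS)


@dataclass(frozen=True)
class PairwiseAlignment:
    """Two gapped rows of equal span; no column is gap-vs-gap."""

    query_id: str
    hit_id: str
    query_row: str
    hit_row: str
    score: float = 0.0

    def __post_init__(self) -> None:
        if len(self.query_row) != len(self.hit_row):
            raise AlignmentError(
                f"{self.query_id}/{self.hit_id}: rows differ in span "
                f"({len(self.query_row)} vs {len(self.hit_row)})"
            )
        for q, h in zip(self.query_row, self.hit_row):
            if q == GAP and h == GAP:
                raise AlignmentError(f"{self.query_id}/{self.hit_id}: gap-vs-gap column")

    @property
    def columns(self) -> list[tuple[str, str]]:
        return list(zip(self.query_row, self.hit_row))

    @property
    def span(self) -> int:
        return len(self.query_row)


@dataclass(frozen=True)
class AlignmentStats:
    query_length: int
    span: int
    n_match: int
    n_mismatch: int
    n_gap_columns: int
    percent_identity: float

    def __post_init__(self) -> None:
        if self.n_match + self.n_mismatch + self.n_gap_columns != self.span:
            raise AlignmentError("match + mismatch + gap columns must equal span")
        if not 0.0 <= self.percent_identity <= 100.0:
            raise AlignmentError("percent identity outside [0, 100]")


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Order-preserving FASTA read; ids taken up to the first whitespace."""
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise AlignmentError(f"duplicate id {rec.id!r} in {path}")
        seen.add(rec.id)
        sr = SequenceRecord(rec.id, str(rec.seq).upper(), rec.description)
        if sr.has_ambiguity:
            log.warning("%s: sequence contains ambiguity codes; those columns will not be scored", rec.id)
        records.append(sr)
    if not records:
        raise AlignmentError(f"no FASTA records in {path}")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    with open(path, "w") as fh:
        for rec in records:
            header = f">{rec.id}" + (f" {rec.description}" if rec.description else "")
            fh.write(header + "\n")
            for i in range(0, len(rec.residues), 70):
                fh.write(rec.residues[i : i + 70] + "\n")


def global_align(
    a: SequenceRecord,
    b: SequenceRecord,
    scoring: SubstitutionMatrix | None = None,
    gap_open: float = DEFAULT_GAP_OPEN,
    gap_extend: float = DEFAULT_GAP_EXTEND,
) -> PairwiseAlignment:
    """Optimal global alignment with affine gaps (Needleman-Wunsch).

    A gap run of length L costs ``gap_open + gap_extend * L``.  Scoring
    defaults to BLOSUM62.  Among co-optimal alignments the first in the
    aligner's deterministic traceback order is returned, so results are
    reproducible run to run.
    """
    scoring = scoring or blosum62()
    aligner = PairwiseAligner(mode="global")
    aligner.substitution_matrix = scoring.to_biopython()
    aligner.open_gap_score = -(gap_open + gap_extend)
    aligner.extend_gap_score = -gap_extend
    alignments = aligner.align(a.residues, b.residues)
    best = alignments[0]
    return PairwiseAlignment(a.id, b.id, str(best[0]), str(best[1]), float(best.score))


def alignment_stats(aln: PairwiseAlignment, query_length: int | None = None) -> AlignmentStats:
    """Column-based counts; identity denominator is the full span."""
    if aln.span == 0:
        raise AlignmentError("zero-span alignment")
    n_match = n_mismatch = n_gap = 0
    for q, h in zip(aln.query_row, aln.hit_row):
        if q == GAP or h == GAP:
            n_gap += 1
        elif q == h:
            n_match += 1
        else:
            n_mismatch += 1
    qlen = query_length if query_length is not None else sum(c != GAP for c in aln.query_row)
    return AlignmentStats(
        query_length=qlen,
        span=aln.span,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_gap_columns=n_gap,
        percent_identity=100.0 * n_match / aln.span,
    )


_TABLE_COLUMNS = ["qseqid", "sseqid", "pident", "length", "gaps", "qlen", "qseq", "sseq"]


def read_alignment_table(path: str | Path) -> list[tuple[PairwiseAlignment, AlignmentStats]]:
    """Read a BLAST-like TSV carrying the aligned strings (qseq/sseq).

    The alignment is reconstructed from the gapped strings and its identity
    recomputed; if the recomputed value disagrees with the file's ``pident``
    by more than 0.05 a warning is logged and the recomputed value is kept.
    """
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"qseq": str, "sseq": str})
    missing = [c for c in _TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise AlignmentError(f"{path}: missing columns {missing}")
    out = []
    for row in df.itertuples(index=False):
        aln = PairwiseAlignment(str(row.qseqid), str(row.sseqid), row.qseq, row.sseq)
        stats = alignment_stats(aln, query_length=int(row.qlen))
        if abs(stats.percent_identity - float(row.pident)) > 0.05:
            log.warning(
                "%s vs %s: recomputed identity %.2f differs from pident %.2f; keeping recomputed",
                row.qseqid, row.sseqid, stats.percent_identity, float(row.pident),
            )
        out.append((aln, stats))
    return out


def write_alignment_table(
    pairs: list[tuple[PairwiseAlignment, AlignmentStats]], path: str | Path
) -> None:
    rows = [
        {
            "qseqid": aln.query_id,
            "sseqid": aln.hit_id,
            "pident": round(stats.percent_identity, 3),
            "length": stats.span,
            "gaps": stats.n_gap_columns,
            "qlen": stats.query_length,
            "qseq": aln.query_row,
            "sseq": aln.hit_row,
        }
        for aln, stats in pairs
    ]
    pd.DataFrame(rows, columns=_TABLE_COLUMNS).to_csv(path, sep="\t", index=False)


def pick_best_hit(
    query: SequenceRecord, candidates: list[PairwiseAlignment]
) -> PairwiseAlignment:
    """Best-scoring candidate; ties broken by higher identity, then hit id."""
    if not candidates:
        raise AlignmentError(f"{query.id}: no candidate alignments")

    def key(aln: PairwiseAlignment):
        ident = alignment_stats(aln).percent_identity
        return (-aln.score, -ident, aln.hit_id)

    return min(candidates, key=key)


def longest_isoform(records: list[SequenceRecord], gene_of: dict[str, str] | None = None) -> list[SequenceRecord]:
    """Keep one isoform per gene: the longest, ties by lexicographic id.

    Without a gene map every record is its own gene (no-op de-duplication).
    """
    if gene_of is None:
        return list(records)
    best: dict[str, SequenceRecord] = {}
    for rec in records:
        gene = gene_of.get(rec.id, rec.id)
        cur = best.get(gene)
        if cur is None or (len(rec), ) > (len(cur), ) or (len(rec) == len(cur) and rec.id < cur.id):
            best[gene] = rec
    order = {rec.id: i for i, rec in enumerate(records)}
    return sorted(best.values(), key=lambda r: order[r.id])
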