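"""Overlap-ratio diagnostic of mutation saturation.

Aligning only two taxa hides repeated mutation: a site hit many times still
shows at most one mismatch.  With a third taxon, sites where both focal
residues differ *and* an outgroup residue differs from both ("overlap"
sites) betray multiple independent substitutions.  The fraction of overlap
sites among focal-pair mismatches is the saturation diagnostic: near
saturation it rises 2–3-fold over the pre-saturation baseline (empirically
to roughly 50–60% in real proteomes, a context figure this module reports
but never uses as a hard threshold).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

from .alignio import GAP, read_fasta
from .matrices import AA_INDEX


class SaturationError(ValueError):
    pass


@dataclass(frozen=True)
class MultiAlignment:
    """Pre-aligned rows for >=3 taxa with a designated focal pair."""

    taxon_ids: tuple[str, ...]
    rows: tuple[str, ...]
    focal_pair: tuple[int, int]

    def __post_init__(self) -> None:
        if len(self.taxon_ids) != len(self.rows):
            raise SaturationError("one row per taxon required")
        if len(self.rows) < 3:
            raise SaturationError("need at least three taxa (focal pair + outgroup)")
        spans = {len(r) for r in self.rows}
        if len(spans) != 1:
            raise SaturationError(f"rows differ in span: {sorted(spans)}")
        i, j = self.focal_pair
        if i == j or not (0 <= i < len(self.rows)) or not (0 <= j < len(self.rows)):
            raise SaturationError("focal pair must be two distinct row indices")

    @property
    def outgroups(self) -> tuple[int, ...]:
        return tuple(k for k in range(len(self.rows)) if k not in self.focal_pair)

    @classmethod
    def from_fasta(cls, path: str | Path, focal_a: str, focal_b: str) -> "MultiAlignment":
        records = read_fasta(path)
        ids = tuple(r.id for r in records)
        try:
            pair = (ids.index(focal_a), ids.index(focal_b))
        except ValueError as exc:
            raise SaturationError(f"focal taxon not found among {ids}") from exc
        return cls(ids, tuple(r.residues for r in records), pair)


@dataclass(frozen=True)
class OverlapReport:
    n_sites_used: int
    n_mismatch: int
    n_overlap: int

    @property
    def defined(self) -> bool:
        return self.n_mismatch > 0

    @property
    def ratio(self) -> float:
        if not self.defined:
            return float("nan")
        return self.n_overlap / self.n_mismatch


def overlap_ratio(msa: MultiAlignment) -> OverlapReport:
    """Overlap sites among focal-pair mismatched sites.

    A column is *used* when the focal pair and every outgroup carry standard
    residues (no gap or ambiguity).  A used column is *mismatched* when the
    focal residues differ, and an *overlap* site when additionally at least
    one outgroup residue differs from both focal residues.
    """
    i, j = msa.focal_pair
    out = msa.outgroups
    n_used = n_mismatch = n_overlap = 0
    for col in range(len(msa.rows[0])):
        residues = [msa.rows[k][col] for k in (i, j, *out)]
        if any(r == GAP or r not in AA_INDEX for r in residues):
            continue
        n_used += 1
        qa, qb = residues[0], residues[1]
        if qa == qb:
            continue
        n_mismatch += 1
        if any(r != qa and r != qb for r in residues[2:]):
            n_overlap += 1
    return OverlapReport(n_used, n_mismatch, n_overlap)


def saturation_call(report: OverlapReport, baseline: OverlapReport, fold: float = 2.0) -> str:
    """"saturated-like" when the ratio is >= ``fold`` x the baseline ratio."""
    if not report.defined or not baseline.defined:
        raise SaturationError("overlap ratio undefined (no mismatched sites)")
    return "saturated-like" if report.ratio >= fold * baseline.ratio else "not-saturated-like"
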