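"""Fixed amino-acid substitutions and per-group conservative fractions.

A *substitution* is an alignment column where both rows carry standard
residues and they differ; gap columns and columns touching an ambiguity
code are excluded.  Within each rate-class cell, substitution counts are
pooled across proteins before the conservative fraction is taken (the
fraction feeding the chi-squared group comparisons), so the cell fraction
is the count-weighted mean of per-protein fractions, not their plain mean.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .alignio import GAP, PairwiseAlignment
from .classify import RateClass
from .matrices import AA_INDEX, SubstitutionMatrix, is_conservative, score_substitution

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class Substitution:
    query_residue: str
    hit_residue: str
    column: int

    def __post_init__(self) -> None:
        if self.query_residue == self.hit_residue:
            raise ValueError("identical residues are not a substitution")


@dataclass(frozen=True)
class FractionResult:
    """Conservative/total counts and their ratio for one group x matrix cell."""

    n_conservative: int
    n_total: int
    n_proteins: int = 0
    mean_length: float = float("nan")

    def __post_init__(self) -> None:
        if self.n_conservative > self.n_total:
            raise ValueError("conservative count exceeds total")

    @property
    def defined(self) -> bool:
        return self.n_total > 0

    @property
    def fraction(self) -> float:
        if not self.defined:
            return float("nan")
        return self.n_conservative / self.n_total


def extract_substitutions(aln: PairwiseAlignment) -> list[Substitution]:
    """Mismatch columns with two scorable residues; ambiguity columns dropped."""
    subs: list[Substitution] = []
    n_ambiguous = 0
    for col, (q, h) in enumerate(zip(aln.query_row, aln.hit_row)):
        if q == GAP or h == GAP or q == h:
            continue
        if q not in AA_INDEX or h not in AA_INDEX:
            n_ambiguous += 1
            continue
        subs.append(Substitution(q, h, col))
    if n_ambiguous:
        log.info(
            "%s vs %s: dropped %d mismatch column(s) containing ambiguity codes",
            aln.query_id, aln.hit_id, n_ambiguous,
        )
    return subs


def conservative_fraction(
    subs: list[Substitution],
    m: SubstitutionMatrix,
    n_proteins: int = 1,
    mean_length: float = float("nan"),
) -> FractionResult:
    n_cons = sum(is_conservative(m, s.query_residue, s.hit_residue) for s in subs)
    return FractionResult(n_cons, len(subs), n_proteins, mean_length)


def score_histogram(subs: list[Substitution], m: SubstitutionMatrix) -> dict[int, int]:
    """Count of substitutions per integer score value."""
    return dict(sorted(Counter(
        score_substitution(m, s.query_residue, s.hit_residue) for s in subs
    ).items()))


#: Cell ordering mirroring the fixed-substitution results table layout.
_CELL_ORDER = [
    ("long", "no-gaps"), ("long", "with-gaps"),
    ("short", "no-gaps"), ("short", "with-gaps"),
]


def group_fraction_table(
    classified: list[tuple[RateClass, int, list[Substitution]]],
    matrices: dict[str, SubstitutionMatrix],
    path: str | Path | None = None,
) -> pd.DataFrame:
    """Pooled conservative fractions per rate-class cell and matrix.

    ``classified`` holds, per protein, its rate class, query length, and
    extracted substitutions.  The result has one row per populated
    (length_stratum, gap_stratum, identity_bin) cell with one fraction
    column per matrix plus ``n_proteins`` and ``mean_length``.
    """
    cells: dict[tuple[str, str, str], dict] = {}
    for rc, qlen, subs in classified:
        cell = cells.setdefault(rc.cell, {"lengths": [], "subs": []})
        cell["lengths"].append(qlen)
        cell["subs"].extend(subs)

    from .classify import LONG_BINS, SHORT_BINS  # local to avoid cycle at import

    bin_order = {("long",): [b for b, _ in LONG_BINS], ("short",): [b for b, _ in SHORT_BINS]}
    rows = []
    for length_stratum, gap_stratum in _CELL_ORDER:
        for ident_bin in bin_order[(length_stratum,)] + ["out-of-range"]:
            key = (length_stratum, gap_stratum, ident_bin)
            if key not in cells:
                continue
            cell = cells[key]
            n_prot = len(cell["lengths"])
            mean_len = sum(cell["lengths"]) / n_prot
            row = {
                "length_stratum": length_stratum,
                "gap_stratum": gap_stratum,
                "identity_bin": ident_bin,
            }
            for name, m in matrices.items():
                fr = conservative_fraction(cell["subs"], m, n_prot, mean_len)
                row[name] = fr.fraction
                row[f"{name}_conservative"] = fr.n_conservative
                row[f"{name}_total"] = fr.n_total
            row["n_proteins"] = n_prot
            row["mean_length"] = round(mean_len, 1)
            rows.append(row)
    df = pd.DataFrame(rows)
    if path is not None:
        df.to_csv(path, sep="\t", index=False, float_format="%.6g")
    return df
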