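"""Evolutionary-rate classification of ortholog alignments.

Human–macaque ortholog pairs are binned by query length (long: >1102 aa,
short: 200–1102 aa), presence of alignment gaps, and percent identity.
Long-protein identity bins: >99, 98–99, 96–98, 87–96; short-protein bins:
>95, 90–95, 80–90, 60–80.  Bin intervals are half-open and upper-inclusive,
so a boundary identity (exactly 99, 98, 96, 95, 90 or 80) falls in the
lower bin.

The *slow set* — the proteins treated as still in the linear, unsaturated
phase of divergence — is: length >304 aa at 100% identity (gap-free), or
length >1102 aa at identity >99%.  Everything else eligible is "fast".
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .alignio import AlignmentStats

LONG_THRESHOLD = 1102          # aa; strictly greater -> long stratum
MIN_LENGTH = 200               # eligibility: query length strictly greater
MIN_IDENTITY = 60.0            # eligibility: percent identity strictly greater

#: (bin label, lower edge) per stratum; intervals are (lower, upper] with the
#: upper edge given by the previous bin's lower edge (100 for the top bin).
LONG_BINS = [(">99", 99.0), ("98-99", 98.0), ("96-98", 96.0), ("87-96", 87.0)]
SHORT_BINS = [(">95", 95.0), ("90-95", 90.0), ("80-90", 80.0), ("60-80", 60.0)]
OUT_OF_RANGE = "out-of-range"


class ClassifyError(ValueError):
    pass


@dataclass(frozen=True)
class RateClass:
    length_stratum: str     # "long" | "short"
    gap_stratum: str        # "no-gaps" | "with-gaps"
    identity_bin: str
    slow_set: bool

    @property
    def cell(self) -> tuple[str, str, str]:
        return (self.length_stratum, self.gap_stratum, self.identity_bin)


def eligibility(stats: AlignmentStats) -> bool:
    """Orthologs worth classifying: length >200 aa and identity >60%."""
    return stats.query_length > MIN_LENGTH and stats.percent_identity > MIN_IDENTITY


def _identity_bin(identity: float, bins: list[tuple[str, float]]) -> str:
    # Bottom bin includes its lower edge (87 long / 60 short is eligible-adjacent);
    # all other edges belong to the bin below.
    for i, (label, lower) in enumerate(bins):
        last = i == len(bins) - 1
        if identity > lower or (last and identity == lower):
            return label
    return OUT_OF_RANGE


def classify_rate(stats: AlignmentStats) -> RateClass:
    """Assign an eligible alignment to its (length, gap, identity-bin) cell."""
    if not eligibility(stats):
        raise ClassifyError(
            f"ineligible alignment (length {stats.query_length}, "
            f"identity {stats.percent_identity:.2f})"
        )
    long = stats.query_length > LONG_THRESHOLD
    bins = LONG_BINS if long else SHORT_BINS
    return RateClass(
        length_stratum="long" if long else "short",
        gap_stratum="no-gaps" if stats.n_gap_columns == 0 else "with-gaps",
        identity_bin=_identity_bin(stats.percent_identity, bins),
        slow_set=is_slow_set(stats),
    )


def is_slow_set(stats: AlignmentStats) -> bool:
    """Slow-set rule: >304 aa at 100% identity (gap-free), or >1102 aa at >99%.

    The 100%-identity clause additionally requires zero gap columns: under
    the span-denominator convention 100% identity already implies it, but
    the requirement is made explicit rather than relied upon.
    """
    perfect = (
        stats.query_length > 304
        and stats.percent_identity == 100.0
        and stats.n_gap_columns == 0
    )
    near_perfect = stats.query_length > LONG_THRESHOLD and stats.percent_identity > 99.0
    return perfect or near_perfect


def classification_table(
    entries: list[tuple[str, AlignmentStats, RateClass]], path: str | Path | None = None
) -> pd.DataFrame:
    """One row per protein; written as TSV when a path is given."""
    df = pd.DataFrame(
        [
            {
                "protein_id": pid,
                "length": s.query_length,
                "identity": s.percent_identity,
                "gap_columns": s.n_gap_columns,
                "length_stratum": rc.length_stratum,
                "gap_stratum": rc.gap_stratum,
                "identity_bin": rc.identity_bin,
                "slow_set": rc.slow_set,
            }
            for pid, s, rc in entries
        ]
    )
    if path is not None:
        df.to_csv(path, sep="\t", index=False)
    return df
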