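"""Chi-squared comparison of conservative/non-conservative counts.

Group comparisons throughout the analysis are 2x2 chi-squared tests on
(conservative, non-conservative) x (group 1, group 2) count tables, with
no continuity correction by default (Yates available by flag) and one
degree of freedom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import chi2 as chi2_dist

from .substitutions import FractionResult


class StatsError(ValueError):
    pass


@dataclass(frozen=True)
class ContingencyResult:
    table: tuple[tuple[int, int], tuple[int, int]]
    statistic: float
    p_value: float
    df: int = 1

    @property
    def significance(self) -> str:
        """Report annotation tier: *** <0.001, ** <0.01, * <0.05, else ns."""
        if self.p_value < 0.001:
            return "***"
        if self.p_value < 0.01:
            return "**"
        if self.p_value < 0.05:
            return "*"
        return "ns"


def chi2_2x2(a: int, b: int, c: int, d: int, yates: bool = False) -> ContingencyResult:
    """Pearson chi-squared for the table [[a, b], [c, d]].

    statistic = n (ad - bc)^2 / [(a+b)(c+d)(a+c)(b+d)] with n = a+b+c+d;
    with Yates correction |ad - bc| is shrunk by n/2 (floored at 0) before
    squaring.  Both margins must be positive.
    """
    if min(a, b, c, d) < 0:
        raise StatsError("negative count")
    n = a + b + c + d
    margins = [(a + b), (c + d), (a + c), (b + d)]
    if any(mm == 0 for mm in margins):
        raise StatsError("zero margin: groups are not comparable")
    cross = abs(a * d - b * c)
    if yates:
        cross = max(cross - n / 2.0, 0.0)
    statistic = n * cross**2 / np.prod([float(mm) for mm in margins])
    p = float(chi2_dist.sf(statistic, df=1))
    return ContingencyResult(((a, b), (c, d)), float(statistic), p)


def compare_fractions(
    r1: FractionResult, r2: FractionResult, yates: bool = False
) -> ContingencyResult:
    """Chi-squared on the conservative/non-conservative counts of two groups."""
    if not r1.defined or not r2.defined:
        raise StatsError("cannot compare an undefined fraction (zero substitutions)")
    return chi2_2x2(
        r1.n_conservative, r1.n_total - r1.n_conservative,
        r2.n_conservative, r2.n_total - r2.n_conservative,
        yates=yates,
    )
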