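import pytest

from ratesub.alignio import AlignmentStats
from ratesub.matrices import builtin_matrices


@pytest.fixture(scope="session")
def matrices():
    """The four integer score matrices with cutoffs attached."""
    return builtin_matrices()


def make_stats(query_length, n_match, n_mismatch=0, n_gap=0):
    """AlignmentStats from raw column counts (identity derived, span = sum)."""
    span = n_match + n_mismatch + n_gap
    return AlignmentStats(
        query_length=query_length,
        span=span,
        n_match=n_match,
        n_mismatch=n_mismatch,
        n_gap_columns=n_gap,
        percent_identity=100.0 * n_match / span,
    )
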