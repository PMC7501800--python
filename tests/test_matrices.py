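"""Exchange matrices: loading, normalization, rescaling, and the predicate."""

import itertools

import numpy as np
import pytest

from ratesub.matrices import (
    AA_ORDER,
    MatrixError,
    NormalizedMatrix,
    PropertyScale,
    SubstitutionMatrix,
    blosum62,
    delta_from_scale,
    delta_p,
    delta_v,
    ex_matrix,
    is_conservative,
    load_matrix,
    load_property_scales,
    rescale_to_integer,
    score_substitution,
    write_matrix,
)

PAIRS = [(a, b) for a, b in itertools.product(AA_ORDER, repeat=2) if a != b]


def _matrix_tsv(tmp_path, grid, name="m.tsv"):
    path = tmp_path / name
    lines = ["\t".join([""] + list(AA_ORDER))]
    for i, aa in enumerate(AA_ORDER):
        lines.append(aa + "\t" + "\t".join(str(v) for v in grid[i]))
    path.write_text("\n".join(lines) + "\n")
    return path


class TestLoadMatrix:
    def test_identity_like_file_is_valid(self, tmp_path):
        path = _matrix_tsv(tmp_path, np.eye(20))
        m = load_matrix(path, kind="normalized")
        assert isinstance(m, NormalizedMatrix)
        assert m["A", "A"] == 1.0 and m["A", "R"] == 0.0

    def test_asymmetry_is_rejected_not_symmetrized(self, tmp_path):
        grid = np.eye(20)
        grid[0, 1] = 0.2
        grid[1, 0] = 0.3
        with pytest.raises(MatrixError, match="asymmetric"):
            load_matrix(_matrix_tsv(tmp_path, grid), kind="normalized")

    def test_non_numeric_cell(self, tmp_path):
        path = _matrix_tsv(tmp_path, np.eye(20))
        path.write_text(path.read_text().replace("1.0", "oops", 1))
        with pytest.raises(MatrixError, match="non-numeric"):
            load_matrix(path, kind="normalized")

    def test_missing_amino_acid_row(self, tmp_path):
        path = _matrix_tsv(tmp_path, np.eye(20))
        lines = path.read_text().splitlines()
        path.write_text("\n".join(lines[:-1]) + "\n")  # drop the V row
        with pytest.raises(MatrixError, match="20 data rows"):
            load_matrix(path, kind="normalized")

    def test_out_of_range_normalized_value(self, tmp_path):
        grid = np.eye(20)
        grid[2, 3] = grid[3, 2] = 1.5
        with pytest.raises(MatrixError, match=r"\[0, 1\]"):
            load_matrix(_matrix_tsv(tmp_path, grid), kind="normalized")

    def test_round_trip(self, tmp_path):
        m = ex_matrix()
        out = tmp_path / "ex.tsv"
        write_matrix(m, out)
        again = load_matrix(out, kind="normalized", name="EX")
        assert np.array_equal(m.values, again.values)


class TestBundledMatrices:
    def test_ex_fixture_is_normalized_20x20(self):
        m = ex_matrix()
        assert m.values.shape == (20, 20)
        assert m.values.min() == 0.0 and m.values.max() == 1.0
        assert np.array_equal(m.values, m.values.T)

    @pytest.mark.parametrize("factory", [delta_v, delta_p])
    def test_delta_matrices_attain_extrema(self, factory):
        m = factory()
        off = ~np.eye(20, dtype=bool)
        assert np.isclose(m.values[off].min(), 0.0)
        assert np.isclose(m.values[off].max(), 1.0)  # tied property values exist

    def test_property_scales_have_20_finite_values(self):
        scales = load_property_scales()
        assert set(scales) == {"volume", "polarity"}
        for scale in scales.values():
            assert np.isfinite(scale.as_array()).all()


class TestDeltaFromScale:
    def test_diagonal_is_fully_conservative(self):
        m = delta_from_scale(load_property_scales()["volume"])
        assert np.allclose(np.diag(m.values), 1.0)

    def test_max_difference_pair_scores_zero(self):
        scale = load_property_scales()["volume"]
        p = scale.values
        a, b = max(PAIRS, key=lambda ab: abs(p[ab[0]] - p[ab[1]]))
        m = delta_from_scale(scale)
        assert m[a, b] == 0.0

    def test_toy_scale_hand_computed(self):
        # A=0, G=1, W=3, everything else 0: max pairwise change is 3 (A/W),
        # so delta(A,G) = 1/3 and conservativeness 1 - 1/3 = 2/3.
        values = {aa: 0.0 for aa in AA_ORDER}
        values["G"], values["W"] = 1.0, 3.0
        m = delta_from_scale(PropertyScale("toy", values))
        assert m["A", "G"] == pytest.approx(2 / 3)
        assert m["A", "W"] == 0.0

    def test_all_equal_scale_is_degenerate(self):
        with pytest.raises(MatrixError, match="zero denominator"):
            delta_from_scale(PropertyScale("flat", {aa: 1.0 for aa in AA_ORDER}))

    @pytest.mark.parametrize("prop", ["volume", "polarity"])
    def test_orientation_decreases_with_property_difference(self, prop):
        scale = load_property_scales()[prop]
        m = delta_from_scale(scale)
        for a, b in PAIRS:
            for c, d in [("A", "R"), ("G", "W"), ("I", "L")]:
                da = abs(scale.values[a] - scale.values[b])
                dc = abs(scale.values[c] - scale.values[d])
                if da > dc:
                    assert m[a, b] < m[c, d]


class TestRescaleToInteger:
    @pytest.mark.parametrize("v,expected", [(1.0, 5), (0.0, -5), (0.72, 2), (0.55, 1)])
    def test_transform_values(self, v, expected):
        # 0.55 -> 10*0.55-5 = 0.5, a tie rounded half away from zero -> 1
        grid = np.zeros((20, 20))
        grid[0, 1] = grid[1, 0] = v
        grid[0, 2] = grid[2, 0] = 1.0  # force extrema 0 and 1
        m = rescale_to_integer(NormalizedMatrix("t", grid), cutoff=0)
        assert m["A", "R"] == expected

    @pytest.mark.parametrize("name", ["EX", "delta_V", "delta_P"])
    def test_rescaled_matrices_span_minus5_plus5(self, matrices, name):
        off = ~np.eye(20, dtype=bool)
        scores = matrices[name].scores
        assert scores[off].min() == -5
        assert scores.max() == 5


class TestScoring:
    def test_blosum62_canonical_lookup(self, matrices):
        assert score_substitution(matrices["BLOSUM62"], "F", "Y") == 3

    def test_blosum62_max_replacement_score_is_3(self, matrices):
        assert max(score_substitution(matrices["BLOSUM62"], a, b) for a, b in PAIRS) == 3

    def test_identity_is_not_a_substitution(self, matrices):
        for m in matrices.values():
            with pytest.raises(MatrixError, match="not a substitution"):
                score_substitution(m, "L", "L")

    @pytest.mark.parametrize("pair", [("E", "X"), ("B", "A"), ("A", "*")])
    def test_nonstandard_residue_errors(self, matrices, pair):
        with pytest.raises(MatrixError, match="nonstandard"):
            score_substitution(matrices["BLOSUM62"], *pair)

    def test_cutoffs(self, matrices):
        assert {n: m.conservative_cutoff for n, m in matrices.items()} == {
            "BLOSUM62": 0, "EX": 2, "delta_V": 3, "delta_P": 3,
        }

    def test_predicate_is_strict_and_symmetric_exhaustively(self, matrices):
        for m in matrices.values():
            for a, b in PAIRS:
                s = score_substitution(m, a, b)
                cons = is_conservative(m, a, b)
                assert cons == (s > m.conservative_cutoff)
                assert cons == is_conservative(m, b, a)
                if s == m.conservative_cutoff:
                    assert not cons

    def test_blosum62_borderline_scores(self, matrices):
        b62 = matrices["BLOSUM62"]
        ones = [(a, b) for a, b in PAIRS if score_substitution(b62, a, b) == 1]
        zeros = [(a, b) for a, b in PAIRS if score_substitution(b62, a, b) == 0]
        assert ones and zeros
        assert all(is_conservative(b62, a, b) for a, b in ones)
        assert not any(is_conservative(b62, a, b) for a, b in zeros)

    def test_ex_cutoff_boundary(self, matrices):
        ex = matrices["EX"]
        for a, b in PAIRS:
            s = score_substitution(ex, a, b)
            if s == 2:
                assert not is_conservative(ex, a, b)
            if s == 3:
                assert is_conservative(ex, a, b)


def test_integer_matrix_rejects_fractional_cells():
    grid = np.zeros((20, 20))
    grid[0, 1] = grid[1, 0] = 1.5
    with pytest.raises(MatrixError, match="non-integer"):
        SubstitutionMatrix("bad", grid, 0)
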