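"""Amino-acid exchange matrices and the conservative-change predicate.

Four 20x20 matrices rank how conservative an amino-acid replacement is:

* **BLOSUM62** — the canonical log-odds substitution matrix (used raw, as
  integers).
* **EX** — a laboratory-mutagenesis exchangeability matrix, normalized to
  [0, 1].  The original matrix is not redistributable here, so the bundled
  fixture is a synthetic stand-in (see :func:`ex_matrix`).
* **delta_V / delta_P** — complements of the normalized pairwise change in
  side-chain volume / polarity, so that larger values mean a more
  conservative replacement.

Normalized matrices are turned into integer score matrices by the transform
``round(10*v - 5)``, mapping [0, 1] onto [-5, +5].  A replacement a->b is
called *conservative* when its score strictly exceeds the matrix's cutoff:
0 for BLOSUM62, 2 for EX, 3 for delta_V and delta_P.  The per-matrix cutoffs
keep the overall conservative fraction of random replacements comparable
across matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

#: The 20 standard residues, in the fixed column order used by every
#: matrix file and array in this package.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}
#: Codes tolerated in sequence input but never scored.
AMBIGUOUS = frozenset("BZXUO*")

_SYMMETRY_TOL = 1e-9


class MatrixError(ValueError):
    """Malformed or out-of-contract matrix input."""


def _check_residue(aa: str) -> str:
    if aa in AA_INDEX:
        return aa
    raise MatrixError(f"nonstandard residue {aa!r}: only {AA_ORDER} are scorable")


def _validate_square(values: np.ndarray, name: str) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.shape != (20, 20):
        raise MatrixError(f"{name}: expected a 20x20 grid, got {values.shape}")
    if not np.isfinite(values).all():
        raise MatrixError(f"{name}: non-numeric or non-finite cell")
    asym = np.abs(values - values.T).max()
    if asym > _SYMMETRY_TOL:
        raise MatrixError(f"{name}: asymmetric beyond {_SYMMETRY_TOL} (max |v-vT| = {asym:g})")
    return values


@dataclass(frozen=True)
class NormalizedMatrix:
    """Symmetric 20x20 conservativeness grid with entries in [0, 1].

    Orientation is "higher = more conservative"; after normalization the
    minimum entry is exactly 0 and the maximum exactly 1.
    """

    name: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = _validate_square(self.values, self.name)
        if values.min() < -_SYMMETRY_TOL or values.max() > 1 + _SYMMETRY_TOL:
            raise MatrixError(f"{self.name}: entries outside [0, 1]")
        if not (np.isclose(values.min(), 0.0) and np.isclose(values.max(), 1.0)):
            raise MatrixError(f"{self.name}: normalized extrema must be 0 and 1")
        object.__setattr__(self, "values", values)

    def __getitem__(self, pair: tuple[str, str]) -> float:
        a, b = pair
        return float(self.values[AA_INDEX[_check_residue(a)], AA_INDEX[_check_residue(b)]])


@dataclass(frozen=True)
class SubstitutionMatrix:
    """Symmetric 20x20 integer score grid with a strict conservative cutoff."""

    name: str
    scores: np.ndarray
    conservative_cutoff: int

    def __post_init__(self) -> None:
        scores = _validate_square(self.scores, self.name)
        if not np.allclose(scores, np.round(scores)):
            raise MatrixError(f"{self.name}: integer matrix has non-integer cells")
        object.__setattr__(self, "scores", scores.astype(int))

    def __getitem__(self, pair: tuple[str, str]) -> int:
        a, b = pair
        return int(self.scores[AA_INDEX[_check_residue(a)], AA_INDEX[_check_residue(b)]])

    def to_biopython(self) -> substitution_matrices.Array:
        """Full grid (diagonal included) as a Biopython scoring array."""
        arr = substitution_matrices.Array(alphabet=AA_ORDER, dims=2)
        arr[:, :] = self.scores
        return arr


@dataclass(frozen=True)
class PropertyScale:
    """One physicochemical value per standard residue (e.g. side-chain volume)."""

    name: str
    values: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        missing = set(AA_ORDER) - set(self.values)
        if missing:
            raise MatrixError(f"{self.name}: missing residues {sorted(missing)}")
        extra = set(self.values) - set(AA_ORDER)
        if extra:
            raise MatrixError(f"{self.name}: nonstandard residues {sorted(extra)}")
        if not all(np.isfinite(v) for v in self.values.values()):
            raise MatrixError(f"{self.name}: non-finite property value")

    def as_array(self) -> np.ndarray:
        return np.array([self.values[aa] for aa in AA_ORDER], dtype=float)


# ---------------------------------------------------------------------------
# I/O

def _parse_matrix_lines(lines: list[str], name: str) -> np.ndarray:
    rows = [ln.rstrip("\n") for ln in lines if ln.strip() and not ln.startswith("#")]
    if not rows:
        raise MatrixError(f"{name}: empty matrix file")
    header = rows[0].split("\t")
    header = [h for h in header if h]  # tolerate a leading empty corner cell
    if sorted(header) != sorted(AA_ORDER):
        raise MatrixError(f"{name}: header must contain the 20 codes {AA_ORDER}, got {header}")
    if len(rows) != 21:
        raise MatrixError(f"{name}: expected 20 data rows, got {len(rows) - 1}")
    grid = np.full((20, 20), np.nan)
    for raw in rows[1:]:
        fields = raw.split("\t")
        row_aa = fields[0]
        if row_aa not in AA_INDEX:
            raise MatrixError(f"{name}: unknown row label {row_aa!r}")
        if len(fields) != 21:
            raise MatrixError(f"{name}: row {row_aa} has {len(fields) - 1} cells, expected 20")
        for col_aa, cell in zip(header, fields[1:]):
            try:
                grid[AA_INDEX[row_aa], AA_INDEX[col_aa]] = float(cell)
            except ValueError as exc:
                raise MatrixError(f"{name}: non-numeric cell {cell!r} at ({row_aa},{col_aa})") from exc
    return grid


def load_matrix(
    path: str | Path,
    kind: str = "normalized",
    name: str | None = None,
    cutoff: int | None = None,
) -> NormalizedMatrix | SubstitutionMatrix:
    """Read a 20x20 matrix TSV (row/column header of one-letter codes).

    ``kind`` selects validation: ``"normalized"`` requires entries in [0, 1]
    with extrema 0 and 1; ``"integer"`` requires whole-number scores and a
    ``cutoff``.  Asymmetric files are rejected, never silently symmetrized.
    """
    path = Path(path)
    grid = _parse_matrix_lines(path.read_text().splitlines(), path.name)
    label = name or path.stem
    if kind == "normalized":
        return NormalizedMatrix(label, grid)
    if kind == "integer":
        if cutoff is None:
            raise MatrixError("integer matrices need an explicit conservative cutoff")
        return SubstitutionMatrix(label, grid, cutoff)
    raise MatrixError(f"unknown matrix kind {kind!r}")


def write_matrix(matrix: NormalizedMatrix | SubstitutionMatrix, path: str | Path) -> None:
    values = matrix.values if isinstance(matrix, NormalizedMatrix) else matrix.scores
    with open(path, "w") as fh:
        fh.write("\t".join([""] + list(AA_ORDER)) + "\n")
        for i, aa in enumerate(AA_ORDER):
            fh.write(aa + "\t" + "\t".join(repr(float(v)) if values.dtype.kind == "f" else str(int(v)) for v in values[i]) + "\n")


def load_property_scales(path: str | Path | None = None) -> dict[str, PropertyScale]:
    """Read the bundled (or a user) property table: columns aa, volume, polarity."""
    if path is None:
        path = resources.files("ratesub.data") / "property_scales.tsv"
    lines = [ln for ln in Path(str(path)).read_text().splitlines() if ln.strip() and not ln.startswith("#")]
    header = lines[0].split("\t")
    names = header[1:]
    tables: dict[str, dict[str, float]] = {n: {} for n in names}
    for ln in lines[1:]:
        fields = ln.split("\t")
        for prop, cell in zip(names, fields[1:]):
            tables[prop][fields[0]] = float(cell)
    return {n: PropertyScale(n, vals) for n, vals in tables.items()}


# ---------------------------------------------------------------------------
# Transforms

def delta_from_scale(scale: PropertyScale, name: str | None = None) -> NormalizedMatrix:
    """Conservativeness matrix from a property scale.

    The pairwise change ``delta(a,b) = |p(a)-p(b)|`` is normalized by the
    largest change over all pairs, then complemented (``1 - delta``) so that
    higher values mean more conservative; identical properties give 1, the
    most dissimilar pair gives 0.
    """
    p = scale.as_array()
    delta = np.abs(p[:, None] - p[None, :])
    dmax = delta.max()
    if dmax == 0:
        raise MatrixError(f"{scale.name}: all property values equal, zero denominator")
    return NormalizedMatrix(name or f"delta_{scale.name}", 1.0 - delta / dmax)


def rescale_to_integer(m: NormalizedMatrix, cutoff: int) -> SubstitutionMatrix:
    """Integer scores via ``round(10*v - 5)``, mapping [0,1] onto [-5,+5].

    Ties at .5 round half away from zero (so 0.5 -> 1, -0.5 -> -1).
    """
    x = 10.0 * m.values - 5.0
    scores = np.sign(x) * np.floor(np.abs(x) + 0.5)
    return SubstitutionMatrix(m.name, scores, cutoff)


# ---------------------------------------------------------------------------
# The four matrices of the analysis

def blosum62() -> SubstitutionMatrix:
    """Canonical integer BLOSUM62 restricted to the 20 standard residues.

    Used raw (no rescaling); conservative cutoff is a strict ``> 0``.
    """
    raw = substitution_matrices.load("BLOSUM62")
    idx = [raw.alphabet.index(aa) for aa in AA_ORDER]
    grid = np.array(raw)[np.ix_(idx, idx)]
    return SubstitutionMatrix("BLOSUM62", grid, conservative_cutoff=0)


def ex_matrix(path: str | Path | None = None) -> NormalizedMatrix:
    """Normalized exchangeability ("EX") matrix.

    The published EX matrix is distributed as a spreadsheet that is not
    bundled here; the default fixture ``ex_synthetic_normalized.tsv`` is a
    *synthetic* stand-in built by min-max normalizing canonical BLOSUM62
    off-diagonals into [0, 1] (diagonal set to 1).  It preserves every
    structural property the pipeline relies on — symmetric, [0, 1] range,
    extrema 0 and 1 attained — but its individual values are not the
    laboratory-mutagenesis measurements.  Pass ``path`` to use a
    transcription of the real matrix.
    """
    if path is None:
        path = resources.files("ratesub.data") / "ex_synthetic_normalized.tsv"
    return load_matrix(Path(str(path)), kind="normalized", name="EX")


def delta_v() -> NormalizedMatrix:
    return delta_from_scale(load_property_scales()["volume"], name="delta_V")


def delta_p() -> NormalizedMatrix:
    return delta_from_scale(load_property_scales()["polarity"], name="delta_P")


#: Strict conservative cutoffs, per matrix.
CUTOFFS = {"BLOSUM62": 0, "EX": 2, "delta_V": 3, "delta_P": 3}


def builtin_matrices() -> dict[str, SubstitutionMatrix]:
    """The four integer score matrices with their cutoffs attached.

    BLOSUM62 stays canonical; the three normalized matrices are rescaled
    with ``round(10*v - 5)``.
    """
    return {
        "BLOSUM62": blosum62(),
        "EX": rescale_to_integer(ex_matrix(), CUTOFFS["EX"]),
        "delta_V": rescale_to_integer(delta_v(), CUTOFFS["delta_V"]),
        "delta_P": rescale_to_integer(delta_p(), CUTOFFS["delta_P"]),
    }


# ---------------------------------------------------------------------------
# Scoring

def score_substitution(m: SubstitutionMatrix, a: str, b: str) -> int:
    """Score of the replacement a->b; symmetric; identity is not a substitution."""
    a = _check_residue(a)
    b = _check_residue(b)
    if a == b:
        raise MatrixError(f"{a}->{b} is not a substitution")
    return m[a, b]


def is_conservative(m: SubstitutionMatrix, a: str, b: str) -> bool:
    """True iff score(a,b) strictly exceeds the matrix cutoff."""
    return score_substitution(m, a, b) > m.conservative_cutoff
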