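# Methods

## The question and the procedure

`ratesub` implements an analysis of whether amino-acid changes in slowly
evolving proteins — both *fixed* substitutions between two primate-like
proteomes and *standing* missense variation within a population — are
enriched in conservative (biochemically similar) replacements relative to
changes in fast evolving proteins, and of how mutation saturation in the
fast class confounds the naive reading of between-species mismatches.

The pipeline has four stages:

1. **Rate classification.** Each ortholog pair is globally aligned; proteins
   with query length > 200 aa and percent identity > 60% are binned by
   length stratum (long: > 1102 aa; short: 200–1102 aa), by presence of gap
   columns, and by identity (long: >99, 98–99, 96–98, 87–96; short: >95,
   90–95, 80–90, 60–80). The *slow set* is length > 304 aa at 100% identity
   (gap-free) or length > 1102 aa at identity > 99%; everything else
   eligible is fast.
2. **Conservativeness scoring.** Every mismatch column with two standard
   residues is scored under four 20×20 matrices (below); a replacement is
   conservative when its integer score strictly exceeds the matrix's cutoff.
   Within each rate cell, counts are pooled across proteins before the
   fraction is taken.
3. **Standing-variation analysis.** Missense variants (TSV or an annotated
   VCF dialect) carry a population alternative-allele frequency AF; the
   minor allele frequency is MAF = min(AF, 1−AF). Variants split into a
   rare stratum (MAF < 0.001) and nested common strata (MAF > 0.001, > 0.01,
   > 0.05); a MAF of exactly 0.001 is unassigned and logged. Fractions are
   compared slow vs fast per stratum with 2×2 chi-squared tests
   (uncorrected by default; Yates by flag; tiers \*, \*\*, \*\*\* at 0.05,
   0.01, 0.001).
4. **Saturation diagnostic.** On an alignment of a focal pair plus ≥1
   outgroup, a focal-mismatch column is an *overlap site* when any outgroup
   residue differs from both focal residues. The overlap ratio
   (overlap / mismatch sites) rises toward its i.i.d. ceiling as sites
   accumulate repeated hits; a ratio ≥ 2× a pre-saturation baseline is
   labelled "saturated-like". The empirical 50–60% figure quoted for
   saturated real proteomes is reported as context only.

## The four matrices

* **BLOSUM62** — canonical integer log-odds matrix (from Biopython),
  restricted to the 20 standard residues and used raw; cutoff > 0. Its
  off-diagonal scores span −4…3.
* **EX** — normalized exchangeability matrix, cutoff > 2 after rescaling.
  The published laboratory-mutagenesis matrix is distributed as a
  spreadsheet we do not redistribute; the bundled
  `ex_synthetic_normalized.tsv` is a **synthetic stand-in** (min-max
  normalized BLOSUM62 off-diagonals, diagonal 1) that preserves the
  structural contract — 20×20, symmetric, entries in [0,1], extrema 0 and 1
  attained — so every range, rescaling and cutoff property is exercised.
  Users with a transcription of the real matrix can pass its path to
  `ex_matrix()`.
* **delta_V / delta_P** — built at runtime from bundled Grantham (1974)
  side-chain volume and polarity scales: Δ(a,b) = |p(a)−p(b)| normalized by
  the largest pairwise change, then complemented (1−Δ) so larger = more
  conservative; cutoff > 3 after rescaling. Both scales contain tied values
  (I/L volume; R/Q polarity), so the normalized matrices attain 1
  off-diagonally, and the max-difference pair gives 0.

Normalized matrices become integers via `round(10·v − 5)` (ties rounded
half away from zero), mapping [0,1] onto exactly [−5,+5] when the extrema
are attained. The staggered cutoffs (0 / 2 / 3 / 3) keep the conservative
fraction of a random replacement on a comparable footing across matrices.

## Alignment conventions

The internal aligner is global Needleman–Wunsch with affine gaps
(Biopython's `PairwiseAligner`; a gap run of length L costs
`gap_open + gap_extend·L`, defaults 11/1, BLOSUM62 scoring). Global rather
than local alignment is appropriate because the analysis consumes
near-full-length ortholog pairs and all accounting is column-based; output
from a local search tool can be supplied instead through the alignment-table
reader, which reconstructs columns from the gapped strings and recomputes
identity (logging disagreements > 0.05 with the file's own value). Percent
identity is matches divided by the full span, gap columns included. Among
co-optimal alignments the aligner's first traceback is returned, which is
deterministic for fixed input. Best hits are chosen by score, then identity,
then lexicographic hit id. Bin edges are upper-inclusive (identity exactly
99 falls in 98–99); identity is never rounded before binning.

## The synthetic-data generator

The generator realizes the substitution process the analysis reasons about,
so the pipeline is testable without proteome or population downloads:

* per site and branch, an event count ~ Poisson(divergence), each event
  drawn from the replacement kernel P(b|a) ∝ exp(β·s(a,b)) with s from
  BLOSUM62 by default; β = 0 is uniform replacement, larger β favours
  conservative changes. Poisson events (not one Bernoulli flip) make
  back-mutation, repeated hits, doublet outcomes and saturation realizable.
* ortholog pairs/trios evolve independently from a common ancestor with
  uniform default composition (real compositions are a config option, kept
  off the default to keep enumeration oracles simple).
* default study conditions: slow class = 1,500 aa, 0.002 events/site/branch,
  β = 2 (realized identities concentrate above 99%); fast class = 400 aa,
  0.04 events/site/branch, β = 0 (identities around 90–95%). These mirror
  the long-slow vs short-fast contrast of the fixed-substitution analysis at
  desk scale.
* SNP tables draw a MAF from a rare-heavy spectrum (half the mass below
  0.001, log-uniform tails) and the alternate residue from the stratum's
  kernel (`beta_by_stratum`), emulating the observation that rare variants
  in the fast class are depleted of conservative changes. The analysis
  suites use β = 1.5/2.5 (slow rare/common) vs 0/1 (fast), chosen to give
  clearly ordered expectations while staying in a biologically plausible
  bias range.
* sites may be restricted to k-letter alphabets
  (`site_alphabet_sizes`), modelling positions that accept only a few
  residues at saturation equilibrium; the trio overlap ratio then converges
  to (k−2)/k instead of 18/20.

What the generator does **not** emulate: codon structure and
transition/transversion bias, indels (simulated pairs are gap-free; gap
handling is tested on constructed alignments), linkage and demography
behind the MAF spectrum, and any quantitative MAF–selection coupling.
Passing tests therefore show the machinery is correct under the stated
process, not that real proteomes satisfy the model.

## Numerical and statistical choices

* Chi-squared uses the closed form n(ad−bc)²/[(a+b)(c+d)(a+c)(b+d)] with
  df 1, validated against an independent implementation to 1e−10; zero
  margins are errors (non-comparable groups), not zeros.
* Zero-substitution cells propagate an undefined flag (NaN fraction), never
  0/0.
* Matrix files are rejected on asymmetry beyond 1e−9 rather than silently
  symmetrized.
* Problem sizes in the test suite (e.g. 100-seed parameter-recovery runs
  with 12 slow + 8 fast proteins per seed, 10,000-site trios, 10,000-draw
  kernel checks, brute-force alignment oracles on length ≤ 7 pairs) are
  chosen so the orderings under test are separated by several standard
  errors while the whole suite runs in about a minute.
* Statistical simulator checks use binomial 99% intervals per comparison
  with a calibrated joint criterion across the 12 β × matrix combinations,
  so the suite neither loosens individual intervals nor fails on the ~11%
  chance of a single benign excursion.

## Known limitations

* The bundled EX fixture is synthetic (above); analyses of real data should
  substitute a transcription of the published matrix.
* The slow-set 100%-identity clause explicitly requires zero gap columns;
  under the span-denominator convention this is implied, but inputs from
  other tools may use other denominators, so it is enforced.
* The overlap-site rule with several outgroups ("any outgroup differs from
  both focals") is a generalization of the three-taxon definition;
  convergent coincidences (two lineages independently reaching the same
  residue) are not separately detected.
* The internal aligner has no E-value model; a minimum-score threshold
  stands in for a significance cutoff when filtering candidate hits.
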