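# ratesub

Are amino-acid changes in slowly evolving proteins biased toward
*conservative* replacements?  `ratesub` is a Python toolkit for molecular
evolution researchers that answers this for both **fixed** substitutions
(ortholog mismatches between two species) and **standing** variation
(missense SNPs stratified by minor allele frequency), and for probing the
**mutation-saturation** regime that complicates the comparison.

## What it computes

* **Conservativeness scoring.**  A replacement a→b is scored under four
  20×20 exchange matrices — canonical BLOSUM62, a normalized
  exchangeability (EX) matrix, and Δ-volume / Δ-polarity matrices built
  from Grantham side-chain property scales.  Normalized matrices are mapped
  to integers by `s = round(10·v − 5)` (range −5…+5) and a change is
  *conservative* when `s` strictly exceeds the per-matrix cutoff
  (BLOSUM62 > 0, EX > 2, Δ-matrices > 3).
* **Rate classification.**  Ortholog pairs are globally aligned (affine
  gaps, BLAST-like conventions) and binned by length (> 1102 aa vs
  200–1102 aa), gap presence, and percent identity
  (matches / full span).  The *slow set* is > 304 aa at 100% identity or
  > 1102 aa at > 99% identity.
* **Group fractions and tests.**  Conservative / total substitution counts
  are pooled per bin and compared with 2×2 chi-squared tests
  (`χ² = n(ad−bc)² / [(a+b)(c+d)(a+c)(b+d)]`, df 1).
* **MAF stratification.**  Missense variants (TSV or annotated VCF) are
  split at MAF `< 0.001` (rare) and nested `> 0.001 / > 0.01 / > 0.05`
  strata, with slow-vs-fast fractions per stratum.
* **Saturation diagnostic.**  On focal-pair + outgroup alignments, the
  *overlap ratio* — the fraction of focal mismatches where an outgroup
  differs from both focal residues — detects repeated mutation at a site;
  it approaches 18/20 = 0.9 for i.i.d. saturated sites (or (k−2)/k on
  k-letter site alphabets).
* **Simulation.**  A Poisson-event substitution simulator with a tunable
  conservativeness bias β (`P(b|a) ∝ exp(β·s(a,b))`) generates ortholog
  pairs/trios and SNP tables with known ground truth, so the entire
  pipeline is testable without downloading proteomes or population data.

## Worked example

Simulate a slow class (1,500 aa, low divergence, conservative bias β = 2)
and a fast class (400 aa, higher divergence, unbiased β = 0), align, and
tabulate the pooled conservative fractions:

```python
import ratesub as rs
from ratesub.report import run_fixed_analysis, run_snp_analysis

pairs, truth = rs.simulate_ortholog_set(8, 8, seed=42)
alns = [rs.global_align(q, h) for q, h in pairs]
res = run_fixed_analysis(alns)
print(res["fractions"][["length_stratum", "identity_bin", "BLOSUM62", "EX",
                        "delta_V", "delta_P", "n_proteins", "mean_length"]])
```

```
length_stratum identity_bin  BLOSUM62       EX  delta_V  delta_P  n_proteins  mean_length
          long          >99  0.846154 0.557692 0.461538 0.750000           8       1500.0
         short        90-95  0.101322 0.052863 0.246696 0.251101           7        400.0
         short        80-90  0.166667 0.095238 0.357143 0.380952           1        400.0
```

The slow bin (long, identity > 99%) shows a much higher conservative
fraction than the fast bins under every matrix — the ordering the analysis
is designed to detect.  The same contrast for standing variation:

```python
slow = rs.simulate_snp_table(2000, "slow", {"rare": 1.5, "common": 2.5}, seed=1)
fast = rs.simulate_snp_table(2000, "fast", {"rare": 0.0, "common": 1.0}, seed=2)
out = run_snp_analysis(slow + fast, {v.protein_id for v in slow})
print(out["comparisons"].query("matrix == 'BLOSUM62'"))
```

```
maf_stratum  fraction_slow  fraction_fast       p_value significance
        all       0.752500       0.335500 1.826565e-154          ***
       rare       0.695609       0.117234 9.920862e-153          ***
     gt_001       0.809619       0.552894  7.393000e-35          ***
      gt_01       0.828313       0.546326  6.014643e-28          ***
      gt_05       0.822055       0.543307  5.118504e-17          ***
```

Slow-set variants are more conservative in every MAF stratum, and within
the fast class common variants (`gt_001`) are more conservative than rare
ones (0.553 vs 0.117) — the signature of stronger purifying selection on
rare drastic changes.

A `ratesub` command-line tool exposes the same stages
(`simulate`, `align`, `classify`, `score-fixed`, `score-snps`,
`saturation`, `report`); each stage reads and writes plain TSV/FASTA, so
stages can be run and inspected independently.

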