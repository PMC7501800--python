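"""Missense variant ingestion, MAF stratification, and SNP conservative fractions.

Variants carry an alternative-allele frequency (AF) for one named population;
the minor allele frequency is MAF = min(AF, 1-AF).  Variants are split into a
*rare* stratum (MAF < 0.001) and three nested *common* strata (MAF > 0.001,
> 0.01, > 0.05).  A MAF of exactly 0.001 belongs to neither rare nor common
and is logged as an unassigned boundary case rather than silently binned.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from .matrices import AA_INDEX, SubstitutionMatrix
from .substitutions import FractionResult, Substitution, conservative_fraction, score_histogram

log = logging.getLogger(__name__)

RARE_THRESHOLD = 0.001
COMMON_THRESHOLDS = {"gt_001": 0.001, "gt_01": 0.01, "gt_05": 0.05}
STRATA = ["rare", "gt_001", "gt_01", "gt_05"]
STRATUM_LABELS = {"rare": "<0.001", "gt_001": ">0.001", "gt_01": ">0.01", "gt_05": ">0.05"}


class VariantError(ValueError):
    pass


def compute_maf(af: float) -> float:
    """Minor allele frequency from the alternative allele frequency."""
    if not 0.0 <= af <= 1.0:
        raise VariantError(f"allele frequency {af} outside [0, 1]")
    return min(af, 1.0 - af)


@dataclass(frozen=True)
class MissenseVariant:
    variant_id: str
    protein_id: str
    ref_aa: str
    alt_aa: str
    af: float
    maf: float = field(init=False)

    def __post_init__(self) -> None:
        for aa in (self.ref_aa, self.alt_aa):
            if aa not in AA_INDEX:
                raise VariantError(f"{self.variant_id}: nonstandard residue {aa!r}")
        if self.ref_aa == self.alt_aa:
            raise VariantError(f"{self.variant_id}: ref and alt residues identical (not missense)")
        object.__setattr__(self, "maf", compute_maf(self.af))

    @property
    def substitution(self) -> Substitution:
        return Substitution(self.ref_aa, self.alt_aa, column=-1)


def read_missense_table(path: str | Path) -> list[MissenseVariant]:
    """TSV with columns variant_id, protein_id, ref_aa, alt_aa, af."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str)
    required = ["variant_id", "protein_id", "ref_aa", "alt_aa", "af"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise VariantError(f"{path}: missing columns {missing}")
    return [
        MissenseVariant(r.variant_id, r.protein_id, r.ref_aa, r.alt_aa, float(r.af))
        for r in df.itertuples(index=False)
    ]


def write_missense_table(variants: list[MissenseVariant], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "variant_id": v.variant_id,
                "protein_id": v.protein_id,
                "ref_aa": v.ref_aa,
                "alt_aa": v.alt_aa,
                "af": v.af,
            }
            for v in variants
        ],
        columns=["variant_id", "protein_id", "ref_aa", "alt_aa", "af"],
    ).to_csv(path, sep="\t", index=False)


def read_vcf_missense(path: str | Path, af_field: str = "AFR_AF") -> list[MissenseVariant]:
    """Missense variants from a VCF whose INFO carries amino-acid annotation.

    Expected INFO keys (the supported mini-dialect): ``CSQ_TYPE=missense``,
    ``REF_AA``, ``ALT_AA`` (comma-separated, one per ALT allele), ``PROTEIN``,
    and the named per-allele AF field.  Multi-allelic records are split into
    one variant per ALT allele with its own AF.  Records without amino-acid
    annotation are skipped and counted in a log line.
    """
    from cyvcf2 import VCF

    variants: list[MissenseVariant] = []
    n_skipped = 0
    vcf = VCF(str(path))
    try:
        for rec in vcf:
            csq = rec.INFO.get("CSQ_TYPE")
            ref_aa = rec.INFO.get("REF_AA")
            alt_aa = rec.INFO.get("ALT_AA")
            protein = rec.INFO.get("PROTEIN")
            if csq != "missense" or ref_aa is None or alt_aa is None or protein is None:
                n_skipped += 1
                continue
            af = rec.INFO.get(af_field)
            if af is None:
                raise VariantError(f"{path}: record {rec.CHROM}:{rec.POS} lacks INFO/{af_field}")
            afs = [float(x) for x in (af if isinstance(af, tuple) else (af,))]
            alts = str(alt_aa).split(",")
            if len(afs) != len(rec.ALT) or len(alts) != len(rec.ALT):
                raise VariantError(
                    f"{path}: record {rec.CHROM}:{rec.POS} has {len(rec.ALT)} ALT alleles "
                    f"but {len(afs)} AF / {len(alts)} ALT_AA values"
                )
            vid = rec.ID or f"{rec.CHROM}:{rec.POS}"
            for i, (alt, allele_af) in enumerate(zip(alts, afs)):
                suffix = f".{i}" if len(alts) > 1 else ""
                variants.append(MissenseVariant(vid + suffix, str(protein), str(ref_aa), alt, allele_af))
    finally:
        vcf.close()
    if n_skipped:
        log.info("%s: skipped %d record(s) without missense annotation", path, n_skipped)
    return variants


def stratify_by_maf(variants: list[MissenseVariant]) -> dict[str, list[MissenseVariant]]:
    """Rare (<0.001) plus nested cumulative common strata (>0.001, >0.01, >0.05)."""
    strata: dict[str, list[MissenseVariant]] = {s: [] for s in STRATA}
    n_boundary = 0
    for v in variants:
        if v.maf < RARE_THRESHOLD:
            strata["rare"].append(v)
        elif v.maf == RARE_THRESHOLD:
            n_boundary += 1  # neither <0.001 nor >0.001
        for key, thr in COMMON_THRESHOLDS.items():
            if v.maf > thr:
                strata[key].append(v)
    if n_boundary:
        log.info("%d variant(s) at the MAF=0.001 boundary left unassigned", n_boundary)
    return strata


def split_by_slow_set(
    variants: list[MissenseVariant], slow_proteins: set[str]
) -> tuple[list[MissenseVariant], list[MissenseVariant]]:
    """Partition into slow-set and fast-set variants by protein membership."""
    slow = [v for v in variants if v.protein_id in slow_proteins]
    fast = [v for v in variants if v.protein_id not in slow_proteins]
    return slow, fast


def snp_fraction_report(
    slow: list[MissenseVariant],
    fast: list[MissenseVariant],
    matrices: dict[str, SubstitutionMatrix],
) -> dict:
    """Conservative fractions per set x MAF stratum x matrix, plus score histograms.

    Returns ``{"fractions": {(set, stratum, matrix): FractionResult},
    "histograms": {(set, matrix): {score: count}}}``.  Empty strata yield
    undefined FractionResults (n_total 0), never a 0/0.
    """
    if not slow or not fast:
        raise VariantError("both the slow and the fast variant set must be non-empty")
    fractions: dict[tuple[str, str, str], FractionResult] = {}
    histograms: dict[tuple[str, str], dict[int, int]] = {}
    for set_name, variants in (("slow", slow), ("fast", fast)):
        strata = stratify_by_maf(variants)
        strata["all"] = variants
        subs_all = [v.substitution for v in variants]
        for mname, m in matrices.items():
            histograms[(set_name, mname)] = score_histogram(subs_all, m)
            for stratum, members in strata.items():
                fractions[(set_name, stratum, mname)] = conservative_fraction(
                    [v.substitution for v in members], m, n_proteins=len({v.protein_id for v in members})
                )
    return {"fractions": fractions, "histograms": histograms}


def report_to_frames(report: dict) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Flatten a snp_fraction_report into (fractions, histogram) DataFrames."""
    frac_rows = [
        {
            "set": s,
            "maf_stratum": STRATUM_LABELS.get(stratum, stratum),
            "matrix": m,
            "n_conservative": fr.n_conservative,
            "n_total": fr.n_total,
            "fraction": fr.fraction,
        }
        for (s, stratum, m), fr in report["fractions"].items()
    ]
    hist_rows = []
    for (s, m), hist in report["histograms"].items():
        total = sum(hist.values())
        for score, count in hist.items():
            hist_rows.append(
                {"set": s, "matrix": m, "score": score, "count": count,
                 "fraction": count / total if total else math.nan}
            )
    return pd.DataFrame(frac_rows), pd.DataFrame(hist_rows)
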