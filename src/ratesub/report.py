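"""Pipeline orchestration: publication-shaped result tables with chi-squared annotations.

``run_fixed_analysis`` turns ortholog alignments into the fixed-substitution
fraction table (one row per length x gap x identity-bin cell, one
conservative fraction per matrix) and annotates adjacent identity bins with
chi-squared comparisons.  ``run_snp_analysis`` turns a missense table plus a
slow-set protein list into per-stratum conservative fractions and score
histograms with slow-vs-fast significance tiers.  Every output table carries
a hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .alignio import PairwiseAlignment, alignment_stats
from .classify import classify_rate, classification_table, eligibility, is_slow_set
from .matrices import SubstitutionMatrix, builtin_matrices
from .stats import StatsError, compare_fractions
from .substitutions import FractionResult, extract_substitutions, group_fraction_table
from .variants import MissenseVariant, report_to_frames, snp_fraction_report, split_by_slow_set

log = logging.getLogger(__name__)


class InputError(ValueError):
    """Bad or empty analysis input (CLI exit code 2)."""


@dataclass(frozen=True)
class RunConfig:
    gap_open: float = 11.0
    gap_extend: float = 1.0
    af_field: str = "AFR_AF"
    maf_thresholds: tuple[float, ...] = (0.001, 0.01, 0.05)
    yates: bool = False
    seed: int = 0
    out_dir: str = "."
    extra: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.maf_thresholds) or list(self.maf_thresholds) != sorted(self.maf_thresholds):
            raise ValueError("MAF thresholds must be positive and increasing")

    @property
    def config_hash(self) -> str:
        payload = json.dumps(dataclasses.asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def write_manifest(self, path: str | Path) -> None:
        manifest = dataclasses.asdict(self)
        manifest["config_hash"] = self.config_hash
        manifest["ratesub_version"] = __version__
        Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")


def _stamp(df: pd.DataFrame, config: RunConfig) -> pd.DataFrame:
    df = df.copy()
    df["config_hash"] = config.config_hash
    return df


def run_fixed_analysis(
    alignments: list[PairwiseAlignment],
    config: RunConfig = RunConfig(),
    matrices: dict[str, SubstitutionMatrix] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """Fixed-substitution analysis: classification, fraction table, chi-squared.

    Returns ``{"classification": ..., "fractions": ..., "comparisons": ...}``;
    tables are also written as TSV when ``out_dir`` is given.
    """
    matrices = matrices or builtin_matrices()
    classified, entries = [], []
    for aln in alignments:
        stats = alignment_stats(aln)
        if not eligibility(stats):
            continue
        rc = classify_rate(stats)
        entries.append((aln.query_id, stats, rc))
        classified.append((rc, stats.query_length, extract_substitutions(aln)))
    if not classified:
        raise InputError("no eligible proteins (need length >200 aa and identity >60%)")

    class_df = classification_table(entries)
    frac_df = group_fraction_table(classified, matrices)

    # chi-squared between adjacent identity bins within each stratum pair
    comp_rows = []
    for (ls, gs), sub in frac_df.groupby(["length_stratum", "gap_stratum"], sort=False):
        rows = list(sub.itertuples(index=False))
        for hi, lo in zip(rows, rows[1:]):
            for name in matrices:
                r1 = FractionResult(getattr(hi, f"{name}_conservative"), getattr(hi, f"{name}_total"))
                r2 = FractionResult(getattr(lo, f"{name}_conservative"), getattr(lo, f"{name}_total"))
                try:
                    res = compare_fractions(r1, r2, yates=config.yates)
                except StatsError:
                    continue
                comp_rows.append({
                    "length_stratum": ls, "gap_stratum": gs, "matrix": name,
                    "bin_high": hi.identity_bin, "bin_low": lo.identity_bin,
                    "statistic": res.statistic, "p_value": res.p_value,
                    "significance": res.significance,
                })
    comp_df = pd.DataFrame(comp_rows)

    result = {
        "classification": _stamp(class_df, config),
        "fractions": _stamp(frac_df, config),
        "comparisons": _stamp(comp_df, config),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in result.items():
            df.to_csv(out / f"fixed_{key}.tsv", sep="\t", index=False, float_format="%.6g")
        config.write_manifest(out / "manifest.json")
    return result


def slow_set_from_alignments(alignments: list[PairwiseAlignment]) -> set[str]:
    """Protein ids whose alignment satisfies the slow-set rule."""
    return {
        aln.query_id
        for aln in alignments
        if is_slow_set(alignment_stats(aln))
    }


def run_snp_analysis(
    variants: list[MissenseVariant],
    slow_proteins: set[str],
    config: RunConfig = RunConfig(),
    matrices: dict[str, SubstitutionMatrix] | None = None,
    out_dir: str | Path | None = None,
) -> dict[str, pd.DataFrame]:
    """MAF-stratified SNP analysis with slow-vs-fast chi-squared tiers."""
    matrices = matrices or builtin_matrices()
    slow, fast = split_by_slow_set(variants, slow_proteins)
    if not slow or not fast:
        raise InputError(
            f"need variants in both classes (slow: {len(slow)}, fast: {len(fast)})"
        )
    report = snp_fraction_report(slow, fast, matrices)
    frac_df, hist_df = report_to_frames(report)

    comp_rows = []
    for stratum in ("all", "rare", "gt_001", "gt_01", "gt_05"):
        for name in matrices:
            r_slow = report["fractions"][("slow", stratum, name)]
            r_fast = report["fractions"][("fast", stratum, name)]
            try:
                res = compare_fractions(r_slow, r_fast, yates=config.yates)
            except StatsError:
                continue
            comp_rows.append({
                "maf_stratum": stratum, "matrix": name,
                "fraction_slow": r_slow.fraction, "fraction_fast": r_fast.fraction,
                "statistic": res.statistic, "p_value": res.p_value,
                "significance": res.significance,
            })
    comp_df = pd.DataFrame(comp_rows)

    result = {
        "fractions": _stamp(frac_df, config),
        "histograms": _stamp(hist_df, config),
        "comparisons": _stamp(comp_df, config),
    }
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for key, df in result.items():
            df.to_csv(out / f"snp_{key}.tsv", sep="\t", index=False, float_format="%.6g")
        config.write_manifest(out / "manifest.json")
    return result
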