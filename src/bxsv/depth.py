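"""Allele-specific barcode counting: haplotype-resolved copy number.

Each phased heterozygous SNV carries one allele per haplotype; the
number of droplet barcodes supporting each allele in the tumor is a
proxy for the copy number of that haplotype at that position. The normal
sample defines the haplotype orientation, so counts are comparable
across positions, phase blocks are bridged consistently, and two tumor
samples can be compared against the same germline scaffold.

Fold estimates use medians (robust to per-SNV noise) of in-region vs
flanking counts for the same haplotype, which also cancels uniform
coverage differences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import PhasedVariant
from .phasing import _join_variants

logger = logging.getLogger(__name__)

DEFAULT_BIN_WIDTH = 50_000
DEFAULT_RANK_ALPHA = 0.01
DEFAULT_MIN_SNVS = 10
DEFAULT_CONCORDANCE = 0.95


@dataclass
class HaplotypeDepthProfile:
    """Per-SNV haplotype-resolved barcode counts over a region."""

    snvs: pd.DataFrame  # chrom, pos, phase_set, count_hap1, count_hap2
    n_excluded: int = 0

    def binned(self, bin_width: int = DEFAULT_BIN_WIDTH) -> pd.DataFrame:
        """Median per-hap counts per genomic bin (totals preserved as sums)."""
        df = self.snvs.copy()
        df["bin_start"] = (df["pos"] // bin_width) * bin_width
        agg = df.groupby(["chrom", "bin_start"]).agg(
            n_snvs=("pos", "size"),
            median_hap1=("count_hap1", "median"),
            median_hap2=("count_hap2", "median"),
            sum_hap1=("count_hap1", "sum"),
            sum_hap2=("count_hap2", "sum"),
        )
        return agg.reset_index()

    def in_region(self, chrom: str, start: int, end: int) -> pd.DataFrame:
        m = (
            (self.snvs["chrom"] == chrom)
            & (self.snvs["pos"] >= start)
            & (self.snvs["pos"] < end)
        )
        return self.snvs[m]


def allele_specific_counts(
    normal_variants: Sequence[PhasedVariant],
    tumor_variants: Sequence[PhasedVariant],
    region: Optional[tuple[str, int, int]] = None,
) -> HaplotypeDepthProfile:
    """Per-SNV barcode counts for the allele on each haplotype.

    Normal phasing defines which allele sits on haplotype 1/2; the tumor
    sample's per-allele barcode sets supply the counts. SNVs absent from
    the tumor or unphased in the normal are excluded and tallied.
    """
    joined = _join_variants(normal_variants, tumor_variants)
    n_excluded = len(normal_variants) - len(joined)
    rows = []
    for nv, tv in joined:
        if region is not None:
            c, s, e = region
            if nv.chrom != c or not (s <= nv.pos < e):
                continue
        alt_on_1 = nv.hap_of_alt == 1
        c1 = len(tv.barcodes_alt) if alt_on_1 else len(tv.barcodes_ref)
        c2 = len(tv.barcodes_ref) if alt_on_1 else len(tv.barcodes_alt)
        rows.append(
            {
                "chrom": nv.chrom,
                "pos": nv.pos,
                "phase_set": nv.phase_set,
                "count_hap1": c1,
                "count_hap2": c2,
            }
        )
    if not rows:
        logger.warning("no SNVs joined between normal and tumor variant sets")
        return HaplotypeDepthProfile(
            pd.DataFrame(columns=["chrom", "pos", "phase_set", "count_hap1", "count_hap2"]),
            n_excluded=n_excluded,
        )
    return HaplotypeDepthProfile(pd.DataFrame(rows), n_excluded=n_excluded)


def detect_amplified_haplotype(
    profile: HaplotypeDepthProfile,
    region: tuple[str, int, int],
    flanks: Sequence[tuple[str, int, int]],
    alpha: float = DEFAULT_RANK_ALPHA,
    min_snvs: int = DEFAULT_MIN_SNVS,
    purity: Optional[float] = None,
) -> tuple[str, float]:
    """Which haplotype (if any) is amplified in ``region`` vs its flanks.

    The candidate haplotype is the one whose in-region median count
    exceeds its own flank median by the larger factor; it is declared
    only if a Mann-Whitney rank test of in-region vs flank counts passes
    ``alpha``. The fold estimate is the median ratio for that haplotype,
    rounded to the nearest 0.5; with ``purity`` given, the raw mixture
    ratio (pF + 1 - p) is inverted to the tumor-cell fold F.

    Returns ('1' | '2' | 'none', fold).
    """
    inr = profile.in_region(*region)
    fl = pd.concat([profile.in_region(*f) for f in flanks], ignore_index=True)
    if len(inr) < min_snvs or len(fl) < min_snvs:
        raise ValueError(
            f"too few SNVs to assess region ({len(inr)} in-region, {len(fl)} flank; "
            f"need {min_snvs})"
        )
    folds, pvals = {}, {}
    for hap in ("1", "2"):
        col = f"count_hap{hap}"
        flank_med = max(fl[col].median(), 1.0)
        folds[hap] = inr[col].median() / flank_med
        pvals[hap] = stats.mannwhitneyu(
            inr[col], fl[col], alternative="greater"
        ).pvalue
    best = max(folds, key=lambda h: folds[h])
    other = "2" if best == "1" else "1"
    # allele-specific signal requires the haplotypes to differ
    if pvals[best] >= alpha or folds[best] < 1.25 or folds[other] >= 0.8 * folds[best]:
        return "none", 1.0
    fold = folds[best]
    if purity is not None:
        if not (0 < purity <= 1):
            raise ValueError("purity must be in (0, 1]")
        fold = max((fold - (1 - purity)) / purity, 0.0)
    return best, _round_half(fold)


def _round_half(x: float) -> float:
    return round(x * 2) / 2


def compare_haplotypes_across_samples(
    profile_a: HaplotypeDepthProfile,
    profile_b: HaplotypeDepthProfile,
    normal_variants: Sequence[PhasedVariant],
    region: tuple[str, int, int],
    flanks: Sequence[tuple[str, int, int]],
    concordance_threshold: float = DEFAULT_CONCORDANCE,
    **detect_kwargs,
) -> tuple[bool, float]:
    """Is the same haplotype amplified in two tumor samples?

    Both profiles must be oriented by the same normal scaffold; the
    comparison is trusted only if the two profiles share at least
    ``concordance_threshold`` of in-region SNV positions (same phase-set
    orientation on both sides). Returns (same_haplotype, concordance).
    """
    hap_a, _ = detect_amplified_haplotype(profile_a, region, flanks, **detect_kwargs)
    hap_b, _ = detect_amplified_haplotype(profile_b, region, flanks, **detect_kwargs)
    if hap_a == "none" or hap_b == "none":
        raise ValueError("amplified haplotype unassessable in at least one sample")
    in_a = profile_a.in_region(*region)
    in_b = profile_b.in_region(*region)
    merged = in_a.merge(in_b, on=["chrom", "pos"], suffixes=("_a", "_b"))
    if len(in_a) == 0 or len(merged) == 0:
        raise ValueError("no common SNVs to compare")
    concordance = (
        (merged["phase_set_a"] == merged["phase_set_b"]).mean()
        * len(merged)
        / max(len(in_a), len(in_b))
    )
    if concordance < concordance_threshold:
        raise ValueError(
            f"haplotype orientation concordance {concordance:.2f} below "
            f"{concordance_threshold}: comparison untrusted"
        )
    return hap_a == hap_b, float(concordance)
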