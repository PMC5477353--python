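"""SV phasing from droplet barcodes: the core barcode set algebra.

For an SV v = (x, y), the analysis proceeds in four steps:

1. **Window barcodes** ``B(x)``: every barcode with a read mapped inside
   the w-window centred on a breakpoint, regardless of any evidence of
   association with the SV.
2. **SV-specific molecules** ``S(x, y) = B(x) ∩ B(y)``: when the
   breakpoints are farther apart than ordinary molecules (or on
   different chromosomes), each shared barcode marks one HMW molecule
   spanning the junction.
3. **Molecule linking** ``C(v_i, v_j) = S_i ∩ S_j``: SVs sharing
   junction-spanning molecules lie in cis on one DNA molecule.
4. **Haplotype assignment**: heterozygous SNVs near the breakpoints,
   phased in the *normal* sample, route the tumor's per-allele barcodes
   into haplotype supports ``H1``/``H2``; ``R_k = H_k ∩ S`` counts the
   SV molecules on each haplotype. SVs assigned to haplotypes within one
   phase block are in cis (same haplotype) or trans (different).

Haplotype labels are arbitrary per phase block, so calls in different
blocks are never compared.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

from .model import PhasedVariant, SVCall
from .reads import ReadsLike, as_read_store

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = 100_000  # w: breakpoint window size
DEFAULT_MEAN_MOLECULE_LENGTH = 50_000
DEFAULT_MIN_SHARED = 2  # molecules shared between SVs for a cis call
DEFAULT_MIN_ASSIGNABLE = 5
DEFAULT_MAJOR_FRACTION = 0.8
DEFAULT_MIXED_MINOR = 0.3


class BarcodeSet(frozenset):
    """A set of droplet barcodes with a provenance tag.

    Behaves as a frozenset; ``provenance`` records whether the set is a
    window set B, an SV-specific set S, a shared set C, or a haplotype
    support H/R.
    """

    def __new__(cls, iterable: Iterable[str] = (), provenance: str = ""):
        self = super().__new__(cls, iterable)
        self.provenance = provenance
        return self

    def sorted(self) -> list[str]:
        return sorted(self)


class BreakpointsTooCloseError(ValueError):
    """Breakpoint separation does not exceed what ordinary molecules span."""


@dataclass
class HaplotypeSupport:
    """Eq.-7-style molecule support of one SV for each haplotype."""

    sv_id: str
    phase_set: str
    n_total_sv_molecules: int
    n_assignable: int
    r1: int
    r2: int
    call: str  # 'hap1' | 'hap2' | 'mixed' | 'unassigned'
    fraction_major: Optional[float]

    def __post_init__(self) -> None:
        assert self.r1 + self.r2 == self.n_assignable <= self.n_total_sv_molecules


@dataclass
class PhaseVerdict:
    """cis/trans relationship of an SV pair with its evidence."""

    sv_pair: tuple[str, str]
    relationship: str  # 'cis_molecule' | 'cis_haplotype' | 'trans' | 'unresolved'
    shared_molecules: int = 0
    shared_barcodes: BarcodeSet = field(default_factory=BarcodeSet)
    phase_set: str = ""
    calls: tuple[str, str] = ("", "")


# ---------------------------------------------------------------------------
# steps 1-3: window sets, SV-specific sets, molecule linking
# ---------------------------------------------------------------------------

def window_barcodes(
    reads: ReadsLike, chrom: str, point: int, w: int = DEFAULT_WINDOW
) -> BarcodeSet:
    """B(point): barcodes of all reads overlapping [point - w/2, point + w/2)."""
    if w <= 0:
        raise ValueError("window size must be > 0")
    store = as_read_store(reads)
    lo, hi = point - w // 2, point + w // 2
    if lo < 0:
        logger.warning("window at %s:%d truncated at contig start", chrom, point)
        lo = 0
    return BarcodeSet(store.barcodes_in(chrom, lo, hi), provenance="window B")


def sv_specific_barcodes(
    sv: SVCall,
    reads: ReadsLike,
    w: int = DEFAULT_WINDOW,
    min_span: Optional[int] = None,
    mean_molecule_length: int = DEFAULT_MEAN_MOLECULE_LENGTH,
) -> BarcodeSet:
    """S(x, y) = B(x) ∩ B(y): one barcode per putative junction-spanning
    molecule.

    Intrachromosomal breakpoints must be separated by more than
    ``min_span`` (default twice the mean molecule length): closer pairs
    would share barcodes through ordinary reference molecules and the
    intersection would carry no SV signal.
    """
    if min_span is None:
        min_span = 2 * mean_molecule_length
    if sv.chrom1 == sv.chrom2 and sv.span is not None and sv.span <= min_span:
        raise BreakpointsTooCloseError(
            f"{sv.sv_id}: breakpoints {sv.span} bp apart are too close for "
            f"barcode-intersection evidence (min_span {min_span})"
        )
    store = as_read_store(reads)
    bx = window_barcodes(store, sv.chrom1, sv.x, w)
    by = window_barcodes(store, sv.chrom2, sv.y, w)
    return BarcodeSet(bx & by, provenance="sv-specific S")


def background_rate(
    reads: ReadsLike,
    w: int = DEFAULT_WINDOW,
    n_samples: int = 200,
    seed: int = 0,
    min_span: Optional[int] = None,
    mean_molecule_length: int = DEFAULT_MEAN_MOLECULE_LENGTH,
    alpha: float = 0.05,
) -> tuple[np.ndarray, int]:
    """Empirical null of |S| over random distant window pairs.

    Samples window-pair positions from the read territory subject to the
    same min-span condition as a real SV, and returns the sampled |S|
    values plus their (1 - alpha) quantile — the background threshold
    above which an observed S set is considered significant.
    """
    if n_samples <= 0:
        raise ValueError("n_samples must be > 0")
    if min_span is None:
        min_span = 2 * mean_molecule_length
    store = as_read_store(reads)
    rng = np.random.default_rng(seed)
    spots: list[tuple[str, int, int]] = []
    for chrom in store.chroms:
        lo, hi = store.chrom_bounds(chrom)
        if hi - lo > min_span + 2 * w:
            spots.append((chrom, lo + w // 2, hi - w // 2))
    if not spots:
        raise ValueError("read territory too small to sample distant window pairs")
    counts = np.zeros(n_samples, dtype=np.int64)
    for i in range(n_samples):
        for _attempt in range(1000):
            chrom, lo, hi = spots[rng.integers(len(spots))]
            a, b = sorted(rng.integers(lo, hi, size=2))
            if b - a > min_span:
                break
        else:
            raise ValueError("could not sample a window pair satisfying min_span")
        counts[i] = len(
            window_barcodes(store, chrom, int(a), w)
            & window_barcodes(store, chrom, int(b), w)
        )
    threshold = int(np.quantile(counts, 1 - alpha, method="higher"))
    return counts, threshold


def link_svs(
    s_i: Iterable[str], s_j: Iterable[str], min_shared: int = DEFAULT_MIN_SHARED
) -> tuple[BarcodeSet, str]:
    """C = S_i ∩ S_j; cis_molecule when enough molecules span both SVs."""
    c = BarcodeSet(frozenset(s_i) & frozenset(s_j), provenance="shared C")
    verdict = "cis_molecule" if len(c) >= min_shared else "no_molecule_link"
    if len(c) == 1:
        logger.info("single shared molecule: weak cis evidence")
    return c, verdict


# ---------------------------------------------------------------------------
# step 4: haplotype assignment
# ---------------------------------------------------------------------------

def _join_variants(
    normal_variants: Sequence[PhasedVariant],
    tumor_variants: Sequence[PhasedVariant],
) -> list[tuple[PhasedVariant, PhasedVariant]]:
    """Join tumor onto normal records by (chrom, pos, ref, alt); only
    positions heterozygous-and-phased in the normal are used."""
    tindex = {
        (v.chrom, v.pos, v.ref_allele, v.alt_allele): v for v in tumor_variants
    }
    out = []
    for nv in normal_variants:
        if not nv.is_phased:
            continue
        tv = tindex.get((nv.chrom, nv.pos, nv.ref_allele, nv.alt_allele))
        if tv is not None:
            out.append((nv, tv))
    return out


def allele_support_sets(
    sv: SVCall,
    normal_variants: Sequence[PhasedVariant],
    tumor_variants: Sequence[PhasedVariant],
    w: int = DEFAULT_WINDOW,
) -> dict[str, tuple[BarcodeSet, BarcodeSet]]:
    """H1/H2 per phase block for the SNVs in the two breakpoint windows.

    The normal sample's phasing defines which allele of each SNV lies on
    haplotype 1/2; the tumor sample's per-allele barcode lists supply the
    supporting molecules. Returned keyed by normal phase_set — sets from
    different phase blocks are never merged (labels are arbitrary per
    block).
    """
    windows = [
        (sv.chrom1, sv.x - w // 2, sv.x + w // 2),
        (sv.chrom2, sv.y - w // 2, sv.y + w // 2),
    ]
    h1: dict[str, set] = {}
    h2: dict[str, set] = {}
    for nv, tv in _join_variants(normal_variants, tumor_variants):
        if not any(c == nv.chrom and s <= nv.pos < e for c, s, e in windows):
            continue
        ps = nv.phase_set
        # route tumor allele barcodes by the NORMAL haplotype orientation
        alt_on_1 = nv.hap_of_alt == 1
        h1.setdefault(ps, set()).update(tv.barcodes_alt if alt_on_1 else tv.barcodes_ref)
        h2.setdefault(ps, set()).update(tv.barcodes_ref if alt_on_1 else tv.barcodes_alt)
    if not h1:
        logger.warning("%s: no phased SNVs overlap the breakpoint windows", sv.sv_id)
    return {
        ps: (
            BarcodeSet(h1[ps], provenance="hap-support H1"),
            BarcodeSet(h2[ps], provenance="hap-support H2"),
        )
        for ps in h1
    }


def assign_haplotype(
    s: Iterable[str],
    h1: Iterable[str],
    h2: Iterable[str],
    min_assignable: int = DEFAULT_MIN_ASSIGNABLE,
    major_fraction_threshold: float = DEFAULT_MAJOR_FRACTION,
    mixed_minor_threshold: float = DEFAULT_MIXED_MINOR,
    sv_id: str = "",
    phase_set: str = "",
) -> HaplotypeSupport:
    """R1 = H1 ∩ S, R2 = H2 ∩ S; call the SV's haplotype from the counts.

    A barcode in both H1 and H2 (droplet holding molecules of both
    haplotypes, or a misassigned SNV barcode) is excluded as
    unassignable. The call is 'mixed' when the minor haplotype holds at
    least ``mixed_minor_threshold`` of assignable molecules, 'hap1'/'hap2'
    when the major fraction reaches ``major_fraction_threshold`` with at
    least ``min_assignable`` molecules, else 'unassigned'.
    """
    s = frozenset(s)
    if not s:
        raise ValueError("S is empty: nothing to assign")
    h1, h2 = frozenset(h1), frozenset(h2)
    ambiguous = h1 & h2
    r1 = (h1 - ambiguous) & s
    r2 = (h2 - ambiguous) & s
    n1, n2 = len(r1), len(r2)
    n = n1 + n2
    frac_major = max(n1, n2) / n if n else None
    call = "unassigned"
    if n >= min_assignable:
        if min(n1, n2) / n >= mixed_minor_threshold:
            call = "mixed"
        elif frac_major >= major_fraction_threshold:
            call = "hap1" if n1 >= n2 else "hap2"
    return HaplotypeSupport(
        sv_id=sv_id,
        phase_set=phase_set,
        n_total_sv_molecules=len(s),
        n_assignable=n,
        r1=n1,
        r2=n2,
        call=call,
        fraction_major=frac_major,
    )


def haplotype_support(
    sv: SVCall,
    s: Iterable[str],
    normal_variants: Sequence[PhasedVariant],
    tumor_variants: Sequence[PhasedVariant],
    w: int = DEFAULT_WINDOW,
    **assign_kwargs,
) -> dict[str, HaplotypeSupport]:
    """Per-phase-block haplotype support of one SV (steps 4a + 4b)."""
    out = {}
    for ps, (h1, h2) in allele_support_sets(sv, normal_variants, tumor_variants, w).items():
        out[ps] = assign_haplotype(
            s, h1, h2, sv_id=sv.sv_id, phase_set=ps, **assign_kwargs
        )
    return out


def phase_sv_pair(
    sv_i: SVCall,
    sv_j: SVCall,
    s_i: Iterable[str],
    s_j: Iterable[str],
    support_i: Optional[dict[str, HaplotypeSupport]] = None,
    support_j: Optional[dict[str, HaplotypeSupport]] = None,
    min_shared: int = DEFAULT_MIN_SHARED,
) -> PhaseVerdict:
    """Decide the cis/trans relationship of two SVs.

    Cascade: (1) shared junction-spanning molecules → cis_molecule;
    (2) both SVs haplotype-called within the same phase block →
    cis_haplotype (same haplotype) or trans (different); (3) unresolved.
    """
    c, verdict = link_svs(s_i, s_j, min_shared)
    pair = (sv_i.sv_id, sv_j.sv_id)
    if verdict == "cis_molecule":
        return PhaseVerdict(
            sv_pair=pair,
            relationship="cis_molecule",
            shared_molecules=len(c),
            shared_barcodes=c,
        )
    for ps in sorted(set(support_i or {}) & set(support_j or {})):
        ci, cj = support_i[ps].call, support_j[ps].call
        if ci in ("hap1", "hap2") and cj in ("hap1", "hap2"):
            return PhaseVerdict(
                sv_pair=pair,
                relationship="cis_haplotype" if ci == cj else "trans",
                shared_molecules=len(c),
                phase_set=ps,
                calls=(ci, cj),
            )
    return PhaseVerdict(sv_pair=pair, relationship="unresolved", shared_molecules=len(c))


# ---------------------------------------------------------------------------
# pipeline: Table-style summary over a set of SVs
# ---------------------------------------------------------------------------

def sv_phasing_table(
    svs: Sequence[SVCall],
    tumor_reads: ReadsLike,
    normal_reads: Optional[ReadsLike] = None,
    normal_variants: Sequence[PhasedVariant] = (),
    tumor_variants: Sequence[PhasedVariant] = (),
    w: int = DEFAULT_WINDOW,
    mean_molecule_length: int = DEFAULT_MEAN_MOLECULE_LENGTH,
    min_span: Optional[int] = None,
    subtract_normal_s: bool = True,
    **assign_kwargs,
):
    """Run steps 1-4 for every SV; returns (DataFrame, evidence dict).

    The DataFrame mirrors the published per-SV summary: breakpoints,
    |B| per window, |S|, phase block, r1/r2 with fractions, and the
    haplotype call. ``evidence`` holds the S sets and per-block supports
    for pairwise phasing. With ``subtract_normal_s``, barcodes that are
    SV-specific in the matched normal (systematic window artifacts) are
    removed from each tumor S set.
    """
    import pandas as pd

    tstore = as_read_store(tumor_reads)
    nstore = as_read_store(normal_reads) if normal_reads is not None else None
    rows = []
    evidence: dict[str, dict] = {}
    for sv in svs:
        b1 = window_barcodes(tstore, sv.chrom1, sv.x, w)
        b2 = window_barcodes(tstore, sv.chrom2, sv.y, w)
        try:
            s = sv_specific_barcodes(
                sv, tstore, w, min_span=min_span, mean_molecule_length=mean_molecule_length
            )
        except BreakpointsTooCloseError as exc:
            logger.warning("%s", exc)
            evidence[sv.sv_id] = {"S": BarcodeSet(), "support": {}, "skipped": str(exc)}
            continue
        if subtract_normal_s and nstore is not None:
            s_norm = sv_specific_barcodes(
                sv, nstore, w, min_span=min_span,
                mean_molecule_length=mean_molecule_length,
            )
            s = BarcodeSet(s - s_norm, provenance="sv-specific S (normal-subtracted)")
        support = haplotype_support(
            sv, s, normal_variants, tumor_variants, w, **assign_kwargs
        ) if s else {}
        evidence[sv.sv_id] = {"S": s, "B1": b1, "B2": b2, "support": support}
        best = _best_support(support)
        rows.append(
            {
                "sv_id": sv.sv_id,
                "sv_class": sv.sv_class.value,
                "chrom1": sv.chrom1,
                "breakpoint1": sv.x,
                "chrom2": sv.chrom2,
                "breakpoint2": sv.y,
                "n_barcodes_window1": len(b1),
                "n_barcodes_window2": len(b2),
                "n_sv_molecules": len(s),
                "phase_set": best.phase_set if best else "",
                "r1": best.r1 if best else 0,
                "r2": best.r2 if best else 0,
                "n_assignable": best.n_assignable if best else 0,
                "fraction_major": best.fraction_major if best else np.nan,
                "call": best.call if best else "unassigned",
            }
        )
    return pd.DataFrame(rows), evidence


def _best_support(support: dict[str, HaplotypeSupport]) -> Optional[HaplotypeSupport]:
    if not support:
        return None
    return max(support.values(), key=lambda h: (h.n_assignable, h.phase_set))


def phase_all_pairs(
    svs: Sequence[SVCall],
    evidence: dict[str, dict],
    min_shared: int = DEFAULT_MIN_SHARED,
) -> list[PhaseVerdict]:
    """phase_sv_pair over every SV pair with available S sets."""
    verdicts = []
    have = [sv for sv in svs if evidence.get(sv.sv_id, {}).get("S")]
    for i in range(len(have)):
        for j in range(i + 1, len(have)):
            ei, ej = evidence[have[i].sv_id], evidence[have[j].sv_id]
            verdicts.append(
                phase_sv_pair(
                    have[i],
                    have[j],
                    ei["S"],
                    ej["S"],
                    ei.get("support"),
                    ej.get("support"),
                    min_shared=min_shared,
                )
            )
    return verdicts
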