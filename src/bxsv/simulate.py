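"""Coordinate-level linked-read simulator with full ground truth.

The simulator emulates droplet-partitioned linked-read sequencing of a
tumor/normal pair without generating nucleotide sequence: alignments are
emitted directly as coordinate records, because every downstream
operation consumes mapped positions and barcodes only.

Model, in order of generation:

* a phased diploid SNV scaffold (heterozygous SNVs from a homogeneous
  point process, alleles assigned to haplotypes, positions partitioned
  into phase blocks);
* derived tumor haplotypes expressed as piecewise coordinate maps over
  oriented reference segments (:class:`DerivedGenome`), from which true
  junction breakpoints are extracted automatically;
* droplet partitions, each holding 3-5 HMW molecules under one barcode;
  molecule lengths follow a truncated exponential (bounds 1 kb-500 kb)
  whose scale is solved so the truncated mean equals the requested mean;
* molecules drawn from the tumor-derived genome with probability
  ``purity``, otherwise from the unrearranged germline genome;
* reads every ~``read_spacing`` bp along each molecule, mapped through
  the derived-to-reference coordinate map; a read crossing a junction is
  emitted as split, soft-clipped segments (segments < 20 bp suppressed);
* per-SNV allele barcode sets from the molecules overlapping each SNV,
  honoring molecule haplotype, with an optional misassignment rate.

Molecules are placed over the full genome extent but reads are emitted
only for molecules touching the configured active regions; this keeps
droplet co-occupancy statistics (hence barcode-collision rates) realistic
while simulating only the neighborhoods that matter.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model import BarcodedRead, PhasedVariant, RearrangementSpec, SVCall, SVClass, Segment

logger = logging.getLogger(__name__)

_BASES = np.array(list("ACGT"))

MIN_SEGMENT_LEN = 20  # split-read segments shorter than this are suppressed
MOL_LEN_BOUNDS = (1_000, 500_000)


# ---------------------------------------------------------------------------
# phased diploid scaffold
# ---------------------------------------------------------------------------

@dataclass
class Scaffold:
    """Phased diploid SNV scaffold over a set of reference regions."""

    regions: list[tuple[str, int, int]]
    snvs: pd.DataFrame  # chrom, pos, ref, alt, hap_of_alt, phase_set
    contigs: dict[str, int]

    def snv_positions(self, chrom: str) -> np.ndarray:
        sub = self.snvs[self.snvs["chrom"] == chrom]
        return sub["pos"].to_numpy()

    @property
    def phase_blocks(self) -> dict[str, tuple[int, int]]:
        out: dict[str, tuple[int, int]] = {}
        for ps, grp in self.snvs.groupby("phase_set"):
            out[str(ps)] = (int(grp["pos"].min()), int(grp["pos"].max()))
        return out


def merge_regions(regions: Iterable[tuple[str, int, int]]) -> list[tuple[str, int, int]]:
    """Merge overlapping/adjacent intervals; warn when merging occurs."""
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    n_in = 0
    for c, s, e in regions:
        if e <= s:
            raise ValueError(f"degenerate region {c}:{s}-{e}")
        by_chrom.setdefault(c, []).append((s, e))
        n_in += 1
    merged: list[tuple[str, int, int]] = []
    for c in sorted(by_chrom):
        ivs = sorted(by_chrom[c])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s <= cur_e:
                cur_e = max(cur_e, e)
            else:
                merged.append((c, cur_s, cur_e))
                cur_s, cur_e = s, e
        merged.append((c, cur_s, cur_e))
    if len(merged) < n_in:
        logger.warning("merged %d overlapping regions into %d", n_in, len(merged))
    return merged


def build_reference_model(
    regions: Sequence[tuple[str, int, int]],
    snv_density: float = 1e-3,
    phase_block_mean: float = 1_000_000,
    seed: int = 0,
) -> Scaffold:
    """Place heterozygous phased SNVs over reference regions.

    SNVs arrive as a homogeneous point process with rate ``snv_density``
    per bp; the ALT allele of each lands on haplotype 1 or 2 with equal
    probability. Phase-block boundaries follow a Poisson process with
    mean spacing ``phase_block_mean``, so a mean at or above the region
    length yields a single block per region.
    """
    if snv_density <= 0:
        raise ValueError("snv_density must be > 0")
    rng = np.random.default_rng(seed)
    regions = merge_regions(regions)
    # phase-block boundaries: one Poisson process per chromosome, spanning
    # all its regions, so blocks can bridge unsimulated gaps
    chrom_span: dict[str, tuple[int, int]] = {}
    for chrom, rstart, rend in regions:
        lo, hi = chrom_span.get(chrom, (rstart, rend))
        chrom_span[chrom] = (min(lo, rstart), max(hi, rend))
    chrom_bounds: dict[str, np.ndarray] = {}
    for chrom in sorted(chrom_span):
        lo, hi = chrom_span[chrom]
        bounds = [lo]
        while bounds[-1] < hi:
            bounds.append(bounds[-1] + max(1, int(rng.exponential(phase_block_mean))))
        chrom_bounds[chrom] = np.array(bounds)
    rows = []
    for chrom, rstart, rend in regions:
        length = rend - rstart
        n = rng.poisson(snv_density * length)
        pos = np.sort(rng.choice(length, size=min(n, length), replace=False)) + rstart
        hap = rng.integers(1, 3, size=pos.size)
        ref_i = rng.integers(0, 4, size=pos.size)
        alt_i = (ref_i + rng.integers(1, 4, size=pos.size)) % 4
        bounds = chrom_bounds[chrom]
        block_of = np.searchsorted(bounds[1:], pos, side="right")
        phase_set = [str(int(bounds[b]) + 1) for b in block_of]
        rows.append(
            pd.DataFrame(
                {
                    "chrom": chrom,
                    "pos": pos,
                    "ref": _BASES[ref_i],
                    "alt": _BASES[alt_i],
                    "hap_of_alt": hap,
                    "phase_set": phase_set,
                }
            )
        )
    snvs = (
        pd.concat(rows, ignore_index=True)
        if rows
        else pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "hap_of_alt", "phase_set"])
    )
    contigs = {}
    for chrom, _s, e in regions:
        contigs[chrom] = max(contigs.get(chrom, 0), e + 1_000_000)
    return Scaffold(regions=regions, snvs=snvs, contigs=contigs)


# ---------------------------------------------------------------------------
# derived-haplotype coordinate map
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Junction:
    """A non-reference adjacency in a derived genome."""

    d_pos: int  # derived coordinate of the junction
    chrom1: str
    x: int  # reference breakpoint left in canonical order
    chrom2: str
    y: int
    sv_class: SVClass
    # side of each breakpoint carrying junction support: 'left' means the
    # spanning molecule covers reference positions below the breakpoint
    side1: str
    side2: str


class DerivedGenome:
    """Total, invertible piecewise map between a derived haplotype and
    reference coordinates, built from an ordered oriented segment list."""

    def __init__(self, segments: Sequence[Segment], name: str = "derived"):
        if not segments:
            raise ValueError("derived genome needs at least one segment")
        self.name = name
        self.segments = list(segments)
        d = 0
        d_starts, d_ends = [], []
        for seg in self.segments:
            d_starts.append(d)
            d += seg.length
            d_ends.append(d)
        self.d_starts = np.array(d_starts, dtype=np.int64)
        self.d_ends = np.array(d_ends, dtype=np.int64)
        self.length = int(d)

    @classmethod
    def identity(cls, regions: Sequence[tuple[str, int, int]], name: str = "ref") -> "DerivedGenome":
        return cls([Segment(c, s, e) for c, s, e in merge_regions(regions)], name=name)

    @classmethod
    def from_spec(cls, spec: RearrangementSpec) -> "DerivedGenome":
        return cls(spec.expanded_segments(), name=spec.name)

    # -- forward map -------------------------------------------------------

    def block_of(self, d_pos) -> np.ndarray:
        return np.clip(
            np.searchsorted(self.d_starts, np.asarray(d_pos), side="right") - 1,
            0,
            len(self.segments) - 1,
        )

    def derived_to_ref(self, d_pos: int) -> tuple[str, int, int]:
        """Map one derived coordinate to (chrom, ref position, strand)."""
        if not (0 <= d_pos < self.length):
            raise ValueError(f"derived position {d_pos} outside [0,{self.length})")
        b = int(self.block_of(d_pos))
        seg = self.segments[b]
        off = d_pos - int(self.d_starts[b])
        if seg.orientation == "forward":
            return seg.chrom, seg.start + off, 1
        return seg.chrom, seg.end - 1 - off, -1

    def map_interval(self, d_start: int, d_end: int) -> list[tuple[str, int, int, int]]:
        """Map a derived interval to reference segments (chrom, start, end,
        strand), split at block boundaries, in derived order."""
        if d_end <= d_start:
            return []
        d_start = max(0, d_start)
        d_end = min(self.length, d_end)
        out = []
        b = int(self.block_of(d_start))
        pos = d_start
        while pos < d_end:
            seg = self.segments[b]
            blk_end = int(self.d_ends[b])
            chunk_end = min(d_end, blk_end)
            off_a = pos - int(self.d_starts[b])
            off_b = chunk_end - int(self.d_starts[b])
            if seg.orientation == "forward":
                out.append((seg.chrom, seg.start + off_a, seg.start + off_b, 1))
            else:
                out.append((seg.chrom, seg.end - off_b, seg.end - off_a, -1))
            pos = chunk_end
            b += 1
        return out

    # -- inverse map -------------------------------------------------------

    def ref_to_derived(self, chrom: str, start: int, end: int) -> list[tuple[int, int]]:
        """All derived intervals whose image overlaps [start, end) on
        the reference (multi-valued under duplication)."""
        out = []
        for seg, ds in zip(self.segments, self.d_starts):
            if seg.chrom != chrom or seg.end <= start or seg.start >= end:
                continue
            lo, hi = max(seg.start, start), min(seg.end, end)
            if seg.orientation == "forward":
                out.append((int(ds) + lo - seg.start, int(ds) + hi - seg.start))
            else:
                out.append((int(ds) + seg.end - hi, int(ds) + seg.end - lo))
        return sorted(out)

    # -- junction extraction ----------------------------------------------

    def junctions(self) -> list[Junction]:
        """Non-reference adjacencies between consecutive segments."""
        out = []
        for i in range(len(self.segments) - 1):
            a, b = self.segments[i], self.segments[i + 1]
            # reference point where the derived allele leaves a / enters b
            if a.orientation == "forward":
                exit_pt, exit_side = a.end, "left"
            else:
                exit_pt, exit_side = a.start, "right"
            if b.orientation == "forward":
                enter_pt, enter_side = b.start, "right"
            else:
                enter_pt, enter_side = b.end, "left"
            contiguous = (
                a.chrom == b.chrom
                and a.orientation == b.orientation
                and exit_pt == enter_pt
            )
            if contiguous:
                continue
            if a.chrom != b.chrom:
                svc = SVClass.TRA
            elif a.orientation != b.orientation:
                svc = SVClass.INV
            elif (enter_pt > exit_pt) == (a.orientation == "forward"):
                svc = SVClass.DEL
            else:
                svc = SVClass.DUP
            c1, p1, s1 = a.chrom, exit_pt, exit_side
            c2, p2, s2 = b.chrom, enter_pt, enter_side
            if (c1, p1) > (c2, p2):
                c1, p1, s1, c2, p2, s2 = c2, p2, s2, c1, p1, s1
            out.append(
                Junction(
                    d_pos=int(self.d_ends[i]),
                    chrom1=c1,
                    x=p1,
                    chrom2=c2,
                    y=p2,
                    sv_class=svc,
                    side1=s1,
                    side2=s2,
                )
            )
        return out


# ---------------------------------------------------------------------------
# simulated sample containers
# ---------------------------------------------------------------------------

@dataclass
class SimTruth:
    """Complete ground truth for one simulated sample."""

    molecules: pd.DataFrame  # mol_id, barcode, partition_id, origin, haplotype, genome, d_start, d_end, n_reads
    genomes: dict[str, DerivedGenome]
    sv_calls: list[SVCall]
    junctions: dict[str, list[tuple[str, int]]]  # sv_id -> [(genome, d_pos)]
    sv_haplotype: dict[str, int]
    snvs: pd.DataFrame

    def molecule_footprint(self, mol_id: int) -> list[tuple[str, int, int, int]]:
        row = self.molecules.loc[mol_id]
        g = self.genomes[row["genome"]]
        return g.map_interval(int(row["d_start"]), int(row["d_end"]))

    def spanning_barcodes(self, sv_id: str, min_overhang: int = 0) -> frozenset:
        """Barcodes of truth molecules strictly containing a junction of
        this SV (in derived coordinates), on the SV's genome."""
        hits = set()
        mol = self.molecules
        for genome, d_pos in self.junctions.get(sv_id, []):
            sub = mol[
                (mol["genome"] == genome)
                & (mol["d_start"] < d_pos - min_overhang)
                & (mol["d_end"] > d_pos + min_overhang)
                & (mol["n_reads"] > 0)
            ]
            hits.update(sub["barcode"])
        return frozenset(hits)

    @staticmethod
    def molecule_of_read(read_id: str) -> int:
        return int(read_id[1:].split("r", 1)[0])


@dataclass
class SimSample:
    """One simulated sample: emitted evidence plus its ground truth."""

    name: str
    reads: list[BarcodedRead]
    variants: list[PhasedVariant]
    truth: SimTruth
    params: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# molecule length distribution
# ---------------------------------------------------------------------------

def _exp_scale_for_truncated_mean(mean: float, lo: float, hi: float) -> float:
    """Scale of an exponential so that, truncated to [lo, hi], its mean is
    ``mean``."""
    span = hi - lo
    target = mean - lo

    def trunc_mean(scale: float) -> float:
        z = span / scale
        if z > 700:
            return scale
        return scale - span * np.exp(-z) / (1 - np.exp(-z))

    return brentq(lambda s: trunc_mean(s) - target, 1.0, 100 * mean)


def sample_molecule_lengths(
    rng: np.random.Generator,
    n: int,
    mean: float,
    dist: str = "exponential",
    bounds: tuple[int, int] = MOL_LEN_BOUNDS,
) -> np.ndarray:
    lo, hi = bounds
    if dist == "exponential":
        scale = _exp_scale_for_truncated_mean(mean, lo, hi)
        u = rng.random(n)
        cdf_hi = 1 - np.exp(-(hi - lo) / scale)
        return (lo + -scale * np.log1p(-u * cdf_hi)).astype(np.int64)
    if dist == "lognormal":
        sigma = 0.6
        mu = np.log(mean) - sigma**2 / 2
        out = rng.lognormal(mu, sigma, n)
        return np.clip(out, lo, hi).astype(np.int64)
    raise ValueError(f"unknown molecule length distribution {dist!r}")


# ---------------------------------------------------------------------------
# main simulation
# ---------------------------------------------------------------------------

def _interval_arrays(intervals: list[tuple[int, int]]) -> tuple[np.ndarray, np.ndarray]:
    if not intervals:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    merged = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    arr = np.array(merged, dtype=np.int64)
    return arr[:, 0], arr[:, 1]


def _overlaps_any(starts: np.ndarray, ends: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Vectorized: does [a_i, b_i) overlap any of the sorted disjoint
    intervals [starts, ends)?"""
    if starts.size == 0:
        return np.zeros(a.shape, dtype=bool)
    idx = np.searchsorted(starts, b, side="left") - 1
    ok = idx >= 0
    hit = np.zeros(a.shape, dtype=bool)
    hit[ok] = ends[idx[ok]] > a[ok]
    # also catch interval starting inside [a,b)
    idx2 = np.searchsorted(starts, a, side="left")
    ok2 = idx2 < starts.size
    hit[ok2] |= starts[idx2[ok2]] < b[ok2]
    return hit


def expected_read_coverage(
    n_partitions: int,
    genomes: dict[str, DerivedGenome],
    genome_weight: dict[str, float],
    mean_molecule_length: float,
    read_length: int,
    read_spacing: int,
) -> float:
    """Expected read depth at a typical (diploid) active reference
    position, summed over genome copies."""
    n_mol = n_partitions * 4.0
    depth = 0.0
    for gname, g in genomes.items():
        w = genome_weight.get(gname, 0.0)
        depth += n_mol * w * mean_molecule_length / g.length
    return depth * read_length / read_spacing


def simulate_sample(
    scaffold: Scaffold,
    rearrangements: Sequence[RearrangementSpec] = (),
    purity: float = 0.0,
    mean_molecule_length: int = 50_000,
    n_partitions: Optional[int] = None,
    coverage_target: Optional[float] = None,
    read_length: int = 150,
    read_spacing: int = 1_000,
    seed: int = 0,
    sample: str = "sample",
    genome_extent: Optional[Sequence[tuple[str, int, int]]] = None,
    active_regions: Optional[Sequence[tuple[str, int, int]]] = None,
    snv_misassignment_rate: float = 0.005,
    molecule_length_dist: str = "exponential",
) -> SimSample:
    """Simulate one linked-read sample at coordinate level.

    ``purity`` is the probability that a molecule derives from the
    rearranged tumor genome (0 for a germline sample). ``genome_extent``
    is the reference territory molecules may occupy (default: the
    scaffold regions); ``active_regions`` restricts read emission
    (default: the scaffold regions), emulating a targeted desk-scale
    slice of a whole-genome library.
    """
    if not (0 <= purity <= 1):
        raise ValueError("purity must be in [0, 1]")
    if purity == 0 and rearrangements:
        raise ValueError("rearrangements supplied for a purity-0 (germline) sample")
    rng = np.random.default_rng(seed)
    extent = merge_regions(genome_extent if genome_extent is not None else scaffold.regions)
    active = merge_regions(active_regions if active_regions is not None else scaffold.regions)

    # genomes: shared identity germline + per-haplotype tumor maps
    genomes: dict[str, DerivedGenome] = {"germline": DerivedGenome.identity(extent, "germline")}
    spec_by_hap: dict[int, list[RearrangementSpec]] = {}
    for spec in rearrangements:
        spec_by_hap.setdefault(spec.haplotype, []).append(spec)
    for hap in (1, 2):
        gname = f"tumor_hap{hap}"
        specs = spec_by_hap.get(hap, [])
        if specs:
            segs: list[Segment] = []
            for sp in specs:
                segs.extend(sp.expanded_segments())
            genomes[gname] = DerivedGenome(segs, name=gname)
        else:
            genomes[gname] = DerivedGenome.identity(extent, gname)

    _l1 = genomes["tumor_hap1"].length
    _l2 = genomes["tumor_hap2"].length
    genome_weight = {
        "germline": 1 - purity,
        "tumor_hap1": purity * _l1 / (_l1 + _l2),
        "tumor_hap2": purity * _l2 / (_l1 + _l2),
    }
    if n_partitions is None:
        if coverage_target is None:
            raise ValueError("give n_partitions or coverage_target")
        unit = expected_read_coverage(
            1, genomes, genome_weight, mean_molecule_length, read_length, read_spacing
        )
        n_partitions = int(np.ceil(coverage_target / unit))
    elif coverage_target is not None:
        got = expected_read_coverage(
            n_partitions, genomes, genome_weight, mean_molecule_length, read_length, read_spacing
        )
        if got < coverage_target:
            unit = got / n_partitions
            raise ValueError(
                f"coverage target {coverage_target}x unattainable with "
                f"{n_partitions} partitions; need >= {int(np.ceil(coverage_target / unit))}"
            )

    # --- partitions and molecules -----------------------------------------
    occupancy = rng.integers(3, 6, size=n_partitions)
    n_mol = int(occupancy.sum())
    partition_id = np.repeat(np.arange(n_partitions), occupancy)
    is_tumor = rng.random(n_mol) < purity
    # haplotype of origin in proportion to genome length: an amplified
    # haplotype contributes correspondingly more DNA mass
    l1, l2 = genomes["tumor_hap1"].length, genomes["tumor_hap2"].length
    p_hap1_tumor = l1 / (l1 + l2)
    hap1_draw = rng.random(n_mol)
    haplotype = np.where(
        is_tumor,
        np.where(hap1_draw < p_hap1_tumor, 1, 2),
        np.where(hap1_draw < 0.5, 1, 2),
    )
    genome_of = np.where(
        is_tumor,
        np.where(haplotype == 1, "tumor_hap1", "tumor_hap2"),
        "germline",
    )
    lengths = sample_molecule_lengths(
        rng, n_mol, mean_molecule_length, molecule_length_dist
    )
    d_start = np.zeros(n_mol, dtype=np.int64)
    for gname, g in genomes.items():
        m = genome_of == gname
        if not m.any():
            continue
        L = np.minimum(lengths[m], g.length - 1)
        lengths[m] = L
        d_start[m] = rng.integers(0, g.length - L)
    d_end = d_start + lengths

    # which molecules emit reads: overlap of derived footprint with active
    emits = np.zeros(n_mol, dtype=bool)
    active_derived: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for gname, g in genomes.items():
        ivs: list[tuple[int, int]] = []
        for c, s, e in active:
            ivs.extend(g.ref_to_derived(c, s, e))
        active_derived[gname] = _interval_arrays(ivs)
        m = genome_of == gname
        s_arr, e_arr = active_derived[gname]
        emits[m] = _overlaps_any(s_arr, e_arr, d_start[m], d_end[m])
    emits &= lengths >= read_length

    barcodes = np.array([f"BC{p:07d}-1" for p in range(n_partitions)])

    # --- reads -------------------------------------------------------------
    em_idx = np.flatnonzero(emits)
    n_reads_per = np.zeros(n_mol, dtype=np.int64)
    n_reads_per[em_idx] = (lengths[em_idx] - read_length) // read_spacing + 1
    total = int(n_reads_per[em_idx].sum())
    mol_of_read = np.repeat(em_idx, n_reads_per[em_idx])
    # read ordinal within its molecule
    csum = np.concatenate(([0], np.cumsum(n_reads_per[em_idx])))
    ordinal = np.arange(total) - np.repeat(csum[:-1], n_reads_per[em_idx])
    jitter = rng.integers(-read_spacing // 4, read_spacing // 4 + 1, size=total)
    r_dstart = d_start[mol_of_read] + ordinal * read_spacing + jitter
    r_dstart = np.clip(r_dstart, d_start[mol_of_read], d_end[mol_of_read] - read_length)
    strand_flip = rng.random(total) < 0.5

    reads: list[BarcodedRead] = []
    for gname, g in genomes.items():
        sel = np.flatnonzero(genome_of[mol_of_read] == gname)
        if sel.size == 0:
            continue
        ds = r_dstart[sel]
        blk = g.block_of(ds)
        blk_end = g.d_ends[blk]
        crossing = ds + read_length > blk_end
        # fast path: reads inside one block
        simple = sel[~crossing]
        sblk = blk[~crossing]
        for k, i in enumerate(simple):
            seg = g.segments[int(sblk[k])]
            off = int(r_dstart[i] - g.d_starts[int(sblk[k])])
            if seg.orientation == "forward":
                rs = seg.start + off
                re_ = rs + read_length
                strand = "-" if strand_flip[i] else "+"
            else:
                re_ = seg.end - off
                rs = re_ - read_length
                strand = "+" if strand_flip[i] else "-"
            mol = int(mol_of_read[i])
            reads.append(
                BarcodedRead(
                    read_id=f"m{mol}r{int(ordinal[i])}",
                    sample=sample,
                    chrom=seg.chrom,
                    start=rs,
                    end=re_,
                    strand=strand,
                    barcode=barcodes[partition_id[mol]],
                    is_clipped=False,
                )
            )
        for i in sel[crossing]:
            pieces = g.map_interval(int(r_dstart[i]), int(r_dstart[i]) + read_length)
            mol = int(mol_of_read[i])
            kept = [p for p in pieces if p[2] - p[1] >= MIN_SEGMENT_LEN]
            for chrom, rs, re_, pstrand in kept:
                strand = "-" if strand_flip[i] == (pstrand > 0) else "+"
                reads.append(
                    BarcodedRead(
                        read_id=f"m{mol}r{int(ordinal[i])}",
                        sample=sample,
                        chrom=chrom,
                        start=rs,
                        end=re_,
                        strand=strand,
                        barcode=barcodes[partition_id[mol]],
                        is_clipped=True,
                    )
                )

    # --- SNV allele barcode support ----------------------------------------
    snvs = scaffold.snvs.reset_index(drop=True)
    pos_by_chrom = {
        c: (grp["pos"].to_numpy(), grp.index.to_numpy())
        for c, grp in snvs.groupby("chrom")
    }
    ref_sets: list[set] = [set() for _ in range(len(snvs))]
    alt_sets: list[set] = [set() for _ in range(len(snvs))]
    hap_of_alt = snvs["hap_of_alt"].to_numpy()
    for i in em_idx:
        g = genomes[genome_of[i]]
        bc = barcodes[partition_id[i]]
        hap = int(haplotype[i])
        # a misassigned molecule supports the wrong allele at every SNV
        # it covers (one stray molecule, as seen in real barcode lists)
        flipped = snv_misassignment_rate > 0 and rng.random() < snv_misassignment_rate
        for chrom, rs, re_, _strand in g.map_interval(int(d_start[i]), int(d_end[i])):
            if chrom not in pos_by_chrom:
                continue
            pos, idx = pos_by_chrom[chrom]
            lo = np.searchsorted(pos, rs, side="left")
            hi = np.searchsorted(pos, re_, side="left")
            for j in idx[lo:hi]:
                on_alt = (hap_of_alt[j] == hap) != flipped
                (alt_sets[j] if on_alt else ref_sets[j]).add(bc)

    variants = [
        PhasedVariant(
            chrom=row.chrom,
            pos=int(row.pos),
            ref_allele=row.ref,
            alt_allele=row.alt,
            phase_set=str(row.phase_set),
            hap_of_alt=int(row.hap_of_alt),
            barcodes_ref=frozenset(ref_sets[j]),
            barcodes_alt=frozenset(alt_sets[j]),
        )
        for j, row in enumerate(snvs.itertuples(index=False))
    ]

    # --- truth tables -------------------------------------------------------
    molecules = pd.DataFrame(
        {
            "mol_id": np.arange(n_mol),
            "barcode": barcodes[partition_id],
            "partition_id": partition_id,
            "origin": np.where(is_tumor, "tumor_clone", "normal"),
            "haplotype": haplotype,
            "genome": genome_of,
            "d_start": d_start,
            "d_end": d_end,
            "n_reads": n_reads_per,
        }
    ).set_index("mol_id", drop=False)

    sv_calls, junction_map, sv_hap = _truth_svs(genomes, spec_by_hap)
    truth = SimTruth(
        molecules=molecules,
        genomes=genomes,
        sv_calls=sv_calls,
        junctions=junction_map,
        sv_haplotype=sv_hap,
        snvs=snvs,
    )
    params = {
        "purity": purity,
        "mean_molecule_length": mean_molecule_length,
        "n_partitions": n_partitions,
        "read_length": read_length,
        "read_spacing": read_spacing,
        "seed": seed,
        "snv_misassignment_rate": snv_misassignment_rate,
    }
    return SimSample(name=sample, reads=reads, variants=variants, truth=truth, params=params)


def _truth_svs(
    genomes: dict[str, DerivedGenome],
    spec_by_hap: dict[int, list[RearrangementSpec]],
) -> tuple[list[SVCall], dict[str, list[tuple[str, int]]], dict[str, int]]:
    """Extract deduplicated truth SV calls from the tumor genomes'
    junctions, with deterministic per-class numbering."""
    raw: dict[tuple, dict] = {}
    for hap in sorted(spec_by_hap):
        gname = f"tumor_hap{hap}"
        for j in genomes[gname].junctions():
            key = (j.chrom1, j.x, j.chrom2, j.y, j.sv_class)
            entry = raw.setdefault(key, {"instances": [], "hap": hap, "junction": j})
            entry["instances"].append((gname, j.d_pos))
    # deterministic naming: per class, ordered by coordinates
    counters: dict[str, int] = {}
    sv_calls, junction_map, sv_hap = [], {}, {}
    for key in sorted(raw, key=lambda k: (k[0], k[1], k[2], k[3], k[4].value)):
        c1, x, c2, y, svc = key
        counters[svc.value] = counters.get(svc.value, 0) + 1
        sv_id = f"{svc.value}{counters[svc.value]}"
        sv_calls.append(
            SVCall(sv_id=sv_id, chrom1=c1, x=x, chrom2=c2, y=y, sv_class=svc, source="truth")
        )
        junction_map[sv_id] = raw[key]["instances"]
        sv_hap[sv_id] = raw[key]["hap"]
    return sv_calls, junction_map, sv_hap
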