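"""Readers and writers for the standard formats the pipeline touches.

Internal coordinates are 0-based half-open everywhere; VCF positions are
converted from/to 1-based and BEDPE is consumed as-is (already 0-based
half-open). Barcode identity is the full tag string including any library
suffix (e.g. ``-1``) — suffixes distinguish libraries and are never
trimmed. An optional quality annotation after ``_`` in VCF barcode lists
(Long Ranger dialect, e.g. ``ACGT-1_55``) is stripped.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Optional, Sequence

import pysam
from cyvcf2 import VCF

from .model import (
    BarcodedRead,
    LoadReport,
    PhasedVariant,
    SVCall,
    SVClass,
    sort_svs,
)

logger = logging.getLogger(__name__)

DEFAULT_BARCODE_TAG = "BX"
DEFAULT_MIN_MAPQ = 20


# ---------------------------------------------------------------------------
# barcoded alignments (SAM/BAM)
# ---------------------------------------------------------------------------

def read_barcoded_alignments(
    path: str,
    region: Optional[tuple[str, int, int]] = None,
    sample: str = "",
    barcode_tag: str = DEFAULT_BARCODE_TAG,
    min_mapq: int = DEFAULT_MIN_MAPQ,
    report: Optional[LoadReport] = None,
) -> Iterator[BarcodedRead]:
    """Stream BarcodedRead records from a SAM/BAM file.

    Reads lacking the barcode tag or mapping below ``min_mapq`` are
    dropped and tallied in ``report``. A region query requires an index.
    """
    if report is None:
        report = LoadReport()
    mode = "rb" if path.endswith(".bam") else "r"
    with pysam.AlignmentFile(path, mode) as af:
        if region is not None:
            if not af.has_index():
                raise FileNotFoundError(
                    f"region query on {path} requires an index (.bai/.csi)"
                )
            it = af.fetch(region[0], region[1], region[2])
        else:
            it = af.fetch(until_eof=True)
        seen_tag = False
        for aln in it:
            if aln.is_unmapped:
                report.drop("unmapped")
                continue
            if aln.mapping_quality < min_mapq:
                report.drop("low_mapq")
                continue
            try:
                bx = aln.get_tag(barcode_tag)
                seen_tag = True
            except KeyError:
                report.drop("no_barcode")
                continue
            report.emitted += 1
            yield BarcodedRead(
                read_id=aln.query_name,
                sample=sample,
                chrom=aln.reference_name,
                start=aln.reference_start,
                end=aln.reference_end,
                strand="-" if aln.is_reverse else "+",
                barcode=str(bx),
                is_clipped=_is_soft_clipped(aln),
                mate_of=None,
            )
        if report.emitted == 0 and report.dropped.get("no_barcode", 0) > 0 and not seen_tag:
            raise KeyError(
                f"no read in {path} carries barcode tag {barcode_tag!r}; "
                f"is the tag name correct?"
            )


def load_barcoded_alignments(path: str, **kwargs) -> tuple[list[BarcodedRead], LoadReport]:
    """Eager variant of :func:`read_barcoded_alignments`."""
    report = LoadReport()
    reads = list(read_barcoded_alignments(path, report=report, **kwargs))
    return reads, report


def _is_soft_clipped(aln: pysam.AlignedSegment) -> bool:
    ct = aln.cigartuples
    if not ct:
        return False
    return ct[0][0] == 4 or ct[-1][0] == 4  # BAM_CSOFT_CLIP


def write_barcoded_alignments(
    reads: Iterable[BarcodedRead],
    path: str,
    contigs: dict[str, int],
    barcode_tag: str = DEFAULT_BARCODE_TAG,
) -> None:
    """Write reads as a coordinate-sorted SAM/BAM with barcode tags.

    Coordinate-level records: the sequence is emitted as ``*`` with a
    CIGAR of aligned length; soft-clip status is encoded in a 1-bp clip
    so that round-tripping preserves ``is_clipped``.
    """
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": c, "LN": int(n)} for c, n in contigs.items()],
        }
    )
    order = {c: i for i, c in enumerate(contigs)}
    reads = sorted(reads, key=lambda r: (order[r.chrom], r.start, r.read_id))
    mode = "wb" if path.endswith(".bam") else "w"
    with pysam.AlignmentFile(path, mode, header=header) as out:
        for r in reads:
            a = pysam.AlignedSegment(header)
            a.query_name = r.read_id
            a.reference_name = r.chrom
            a.reference_start = r.start
            a.mapping_quality = 60
            length = r.end - r.start
            if r.is_clipped:
                a.cigarstring = f"{length}M1S"
            else:
                a.cigarstring = f"{length}M"
            a.flag = 16 if r.strand == "-" else 0
            a.set_tag(barcode_tag, r.barcode, value_type="Z")
            out.write(a)


# ---------------------------------------------------------------------------
# phased VCF (Long Ranger dialect)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class BarcodeDialect:
    """How per-allele barcode lists are encoded in the VCF sample field.

    Long Ranger writes one list per allele separated by ``allele_sep``,
    barcodes within a list separated by ``barcode_sep``, and an optional
    quality suffix after ``qual_sep`` on each barcode.
    """

    field: str = "BX"
    allele_sep: str = ","
    barcode_sep: str = ";"
    qual_sep: str = "_"

    def decode(self, raw: str, n_alleles: int = 2) -> list[frozenset]:
        if raw in (".", ""):
            return [frozenset() for _ in range(n_alleles)]
        parts = raw.split(self.allele_sep)
        sets: list[frozenset] = []
        for i in range(n_alleles):
            if i < len(parts) and parts[i]:
                bcs = (
                    b.split(self.qual_sep, 1)[0]
                    for b in parts[i].split(self.barcode_sep)
                    if b
                )
                sets.append(frozenset(b for b in bcs if b))
            else:
                sets.append(frozenset())
        return sets

    def encode(self, sets: Sequence[Iterable[str]]) -> str:
        return self.allele_sep.join(
            self.barcode_sep.join(sorted(s)) for s in sets
        )


def read_phased_vcf(
    path: str,
    sample: Optional[str] = None,
    dialect: BarcodeDialect = BarcodeDialect(),
) -> tuple[list[PhasedVariant], dict[str, tuple[int, int]], LoadReport]:
    """Load heterozygous SNVs with phase and per-allele barcode sets.

    Returns the variant list, a phase-block index mapping
    ``phase_set -> (min pos, max pos)`` over phased hets (0-based), and a
    load report. Only biallelic SNVs are retained; unphased hets are kept
    with ``hap_of_alt=0`` so that depth counting can still use them, but
    they never enter haplotype-support sets.
    """
    vcf = VCF(path)
    if sample is None:
        if len(vcf.samples) != 1:
            raise ValueError(
                f"{path} has samples {vcf.samples}; specify one explicitly"
            )
        sidx = 0
    else:
        try:
            sidx = vcf.samples.index(sample)
        except ValueError:
            raise ValueError(f"sample {sample!r} not in {path} ({vcf.samples})")
    have_bx = dialect.field in [f for f in _format_ids(vcf)]
    if not have_bx:
        logger.warning(
            "%s: no %s FORMAT field; barcode sets will be empty", path, dialect.field
        )

    report = LoadReport()
    variants: list[PhasedVariant] = []
    blocks: dict[str, tuple[int, int]] = {}
    for v in vcf:
        if len(v.ALT) != 1:
            report.drop("multiallelic")
            continue
        if len(v.REF) != 1 or len(v.ALT[0]) != 1:
            report.drop("not_snv")
            continue
        gt = v.genotypes[sidx]
        alleles, phased = gt[:-1], bool(gt[-1])
        if len(alleles) != 2 or -1 in alleles:
            report.drop("missing_gt")
            continue
        if alleles[0] == alleles[1]:
            report.drop("homozygous")
            continue
        phase_set = "."
        hap_of_alt = 0
        if phased:
            ps = v.format("PS")
            if ps is not None:
                phase_set = str(int(ps[sidx][0]))
            # GT 'a|b': allele a sits on haplotype 1, allele b on haplotype 2
            hap_of_alt = 1 if alleles[0] == 1 else 2
        bc_ref: frozenset = frozenset()
        bc_alt: frozenset = frozenset()
        if have_bx:
            raw = v.format(dialect.field)
            if raw is not None:
                try:
                    s = raw[sidx]
                    if isinstance(s, bytes):
                        s = s.decode()
                    bc_ref, bc_alt = dialect.decode(str(s), 2)
                except Exception:
                    report.drop("malformed_barcodes")
                    continue
        pos0 = v.POS - 1
        variants.append(
            PhasedVariant(
                chrom=v.CHROM,
                pos=pos0,
                ref_allele=v.REF,
                alt_allele=v.ALT[0],
                phase_set=phase_set,
                hap_of_alt=hap_of_alt,
                barcodes_ref=bc_ref,
                barcodes_alt=bc_alt,
            )
        )
        report.emitted += 1
        if hap_of_alt:
            lo, hi = blocks.get(phase_set, (pos0, pos0))
            blocks[phase_set] = (min(lo, pos0), max(hi, pos0))
    return variants, blocks, report


def _format_ids(vcf: VCF) -> list[str]:
    ids = []
    for line in vcf.raw_header.splitlines():
        if line.startswith("##FORMAT=<ID="):
            ids.append(line.split("ID=")[1].split(",")[0])
    return ids


def write_phased_vcf(
    variants: Iterable[PhasedVariant],
    path: str,
    sample: str,
    contigs: dict[str, int],
    dialect: BarcodeDialect = BarcodeDialect(),
) -> None:
    """Write heterozygous SNVs as a minimal phased VCF with barcode lists."""
    variants = sorted(variants, key=lambda v: (v.chrom, v.pos))
    with open(path, "w") as out:
        out.write("##fileformat=VCFv4.2\n")
        for c, n in contigs.items():
            out.write(f"##contig=<ID={c},length={n}>\n")
        out.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        out.write('##FORMAT=<ID=PS,Number=1,Type=Integer,Description="Phase set">\n')
        out.write(
            f'##FORMAT=<ID={dialect.field},Number=1,Type=String,'
            'Description="Barcodes supporting each allele">\n'
        )
        out.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            f"{sample}\n"
        )
        for v in variants:
            if v.hap_of_alt == 1:
                gt = "1|0"
            elif v.hap_of_alt == 2:
                gt = "0|1"
            else:
                gt = "0/1"
            ps = v.phase_set if v.phase_set != "." else "."
            bx = dialect.encode([v.barcodes_ref, v.barcodes_alt])
            fields = [gt, str(ps), bx if bx != dialect.allele_sep else "."]
            out.write(
                f"{v.chrom}\t{v.pos + 1}\t.\t{v.ref_allele}\t{v.alt_allele}"
                f"\t.\tPASS\t.\tGT:PS:{dialect.field}\t{':'.join(fields)}\n"
            )


# ---------------------------------------------------------------------------
# BEDPE
# ---------------------------------------------------------------------------

def read_bedpe(path: str, source: str = "") -> list[SVCall]:
    """Parse SV calls from BEDPE (0-based half-open intervals).

    Point estimates are interval midpoints; intrachromosomal calls are
    canonicalized to x <= y.
    """
    calls: list[SVCall] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 6:
                raise ValueError(f"{path}:{lineno}: fewer than 6 BEDPE columns")
            c1, s1, e1, c2, s2, e2 = f[0], int(f[1]), int(f[2]), f[3], int(f[4]), int(f[5])
            if e1 <= s1 or e2 <= s2:
                raise ValueError(f"{path}:{lineno}: interval end <= start")
            name = f[6] if len(f) > 6 and f[6] != "." else f"sv{lineno}"
            calls.append(
                SVCall(
                    sv_id=name,
                    chrom1=c1,
                    x=_midpoint(s1, e1),
                    chrom2=c2,
                    y=_midpoint(s2, e2),
                    sv_class=SVClass.parse(name),
                    source=source,
                    breakpoint_intervals=((s1, e1), (s2, e2)),
                )
            )
    return calls


def _midpoint(s: int, e: int) -> int:
    return s if e - s == 1 else (s + e) // 2


def write_bedpe(calls: Iterable[SVCall], path: str) -> None:
    """Write canonical SVCalls as BEDPE; write∘read is the identity."""
    with open(path, "w") as out:
        for sv in sort_svs(calls):
            (s1, e1), (s2, e2) = sv.breakpoint_intervals
            out.write(
                f"{sv.chrom1}\t{s1}\t{e1}\t{sv.chrom2}\t{s2}\t{e2}"
                f"\t{sv.sv_id}\t.\t+\t-\t{sv.sv_class.value}\n"
            )


# ---------------------------------------------------------------------------
# BED (gene / driver lists)
# ---------------------------------------------------------------------------

def read_bed(path: str) -> list[tuple[str, int, int, str]]:
    """Parse a BED file into (chrom, start, end, name) tuples."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: fewer than 3 BED columns")
            start, end = int(f[1]), int(f[2])
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            name = f[3] if len(f) > 3 else f"feature{lineno}"
            out.append((f[0], start, end, name))
    return out
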