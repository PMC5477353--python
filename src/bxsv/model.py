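"""Core data model for linked-read SV analysis.

All genomic coordinates are 0-based, half-open. Conversion to 1-based
(VCF) or BEDPE conventions happens only at file boundaries in
:mod:`bxsv.io_formats`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Optional


class SVClass(str, Enum):
    """Rearrangement class labels as reported by linked-read SV callers."""

    DEL = "DEL"
    DUP = "DUP"
    INV = "INV"
    TRA = "TRA"
    DISTAL = "DISTAL"
    UNK = "UNK"

    @classmethod
    def parse(cls, label: str) -> "SVClass":
        label = label.strip().upper().rstrip("0123456789")
        try:
            return cls(label)
        except ValueError:
            return cls.UNK


@dataclass(frozen=True)
class BarcodedRead:
    """One aligned read segment carrying its droplet barcode.

    A read that crosses a rearrangement junction appears as several
    segments sharing ``read_id``, each flagged ``is_clipped``.
    """

    read_id: str
    sample: str
    chrom: str
    start: int  # 0-based inclusive
    end: int  # 0-based exclusive
    strand: str  # '+' or '-'
    barcode: str
    is_clipped: bool = False
    mate_of: Optional[str] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(
                f"read {self.read_id}: start {self.start} >= end {self.end}"
            )
        if not self.barcode:
            raise ValueError(f"read {self.read_id}: empty barcode")


@dataclass
class SVCall:
    """A candidate rearrangement: an ordered pair of genomic breakpoints.

    ``x`` and ``y`` are point estimates; ``breakpoint_intervals`` keep the
    uncertainty intervals as reported in BEDPE. On an intrachromosomal
    call the breakpoints are stored in canonical order (x <= y).
    """

    sv_id: str
    chrom1: str
    x: int
    chrom2: str
    y: int
    sv_class: SVClass = SVClass.UNK
    source: str = ""
    breakpoint_intervals: tuple = ()

    def __post_init__(self) -> None:
        if not self.breakpoint_intervals:
            self.breakpoint_intervals = (
                (self.x, self.x + 1),
                (self.y, self.y + 1),
            )
        self.canonicalize()

    def canonicalize(self) -> "SVCall":
        """Enforce x <= y on intrachromosomal calls (swap ends if needed)."""
        if self.chrom1 == self.chrom2 and self.x > self.y:
            self.x, self.y = self.y, self.x
            i1, i2 = self.breakpoint_intervals
            self.breakpoint_intervals = (i2, i1)
        for (s, e), p in zip(self.breakpoint_intervals, (self.x, self.y)):
            if not (s <= p < e):
                raise ValueError(
                    f"{self.sv_id}: point {p} outside interval [{s},{e})"
                )
        return self

    @property
    def span(self) -> Optional[int]:
        """Breakpoint separation in bp, or None for interchromosomal calls."""
        if self.chrom1 != self.chrom2:
            return None
        return self.y - self.x

    def breakpoints(self) -> list[tuple[str, int]]:
        return [(self.chrom1, self.x), (self.chrom2, self.y)]


@dataclass
class PhasedVariant:
    """A heterozygous SNV with phase information and per-allele barcodes.

    ``hap_of_alt`` says which haplotype carries the ALT allele within the
    variant's phase block; 0 marks an unphased heterozygote. Barcode sets
    may intersect: a droplet holding molecules from both parental
    chromosomes contributes its barcode to both alleles.
    """

    chrom: str
    pos: int  # 0-based internally; 1-based on VCF I/O
    ref_allele: str
    alt_allele: str
    phase_set: str = "."
    hap_of_alt: int = 0  # 1, 2, or 0 (unphased)
    barcodes_ref: frozenset = frozenset()
    barcodes_alt: frozenset = frozenset()

    @property
    def is_phased(self) -> bool:
        return self.hap_of_alt in (1, 2)

    def barcodes_on_hap(self, hap: int) -> frozenset:
        """Barcodes supporting the allele residing on haplotype ``hap``."""
        if hap not in (1, 2):
            raise ValueError("haplotype must be 1 or 2")
        if not self.is_phased:
            raise ValueError("variant is unphased; haplotype sets undefined")
        return self.barcodes_alt if self.hap_of_alt == hap else self.barcodes_ref


@dataclass(frozen=True)
class Segment:
    """One oriented reference segment of a derived (rearranged) haplotype."""

    chrom: str
    start: int
    end: int
    orientation: str = "forward"  # 'forward' | 'reverse'

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"degenerate segment {self.chrom}:{self.start}-{self.end}")
        if self.orientation not in ("forward", "reverse"):
            raise ValueError(f"bad orientation {self.orientation!r}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class RearrangementSpec:
    """An ordered list of oriented reference segments defining a derived
    tumor haplotype, with an optional tandem-duplicated sub-list.

    ``tandem_copies`` copies of ``segments[tandem_slice]`` are laid head to
    tail in place of the single motif. ``tandem_copies=1`` with a single
    forward segment reproduces the reference identity map.
    """

    name: str
    haplotype: int  # 1 or 2
    segments: list[Segment] = field(default_factory=list)
    tandem_copies: int = 1
    tandem_slice: tuple[int, int] = (0, 0)  # [i, j) indices into segments

    def __post_init__(self) -> None:
        if self.haplotype not in (1, 2):
            raise ValueError("haplotype must be 1 or 2")
        if self.tandem_copies < 1:
            raise ValueError("tandem_copies must be >= 1")
        i, j = self.tandem_slice
        if self.tandem_copies > 1 and not (0 <= i < j <= len(self.segments)):
            raise ValueError("tandem_slice does not address a segment sub-list")

    def expanded_segments(self) -> list[Segment]:
        """The full derived segment list with the tandem motif unrolled."""
        if self.tandem_copies == 1:
            return list(self.segments)
        i, j = self.tandem_slice
        motif = self.segments[i:j]
        return (
            list(self.segments[:i])
            + motif * self.tandem_copies
            + list(self.segments[j:])
        )


@dataclass
class LoadReport:
    """Bookkeeping for a file-loading pass: totals must be conserved."""

    emitted: int = 0
    dropped: dict = field(default_factory=dict)

    def drop(self, reason: str, n: int = 1) -> None:
        self.dropped[reason] = self.dropped.get(reason, 0) + n

    @property
    def total(self) -> int:
        return self.emitted + sum(self.dropped.values())


def canonical_sv_sort_key(sv: SVCall) -> tuple:
    return (sv.chrom1, sv.x, sv.chrom2, sv.y, sv.sv_id)


def sort_svs(svs: Iterable[SVCall]) -> list[SVCall]:
    return sorted(svs, key=canonical_sv_sort_key)
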