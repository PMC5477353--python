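"""Somatic SV filtering: tumor-normal subtraction, cross-caller
validation, driver-gene proximity annotation, and copy-ratio thresholds.

Breakpoint matching uses positional proximity (default slop 5 kb) and is
class-agnostic by default because DEL/DUP naming differs across callers;
a strict-class mode is available. Germline subtraction requires BOTH
breakpoints of a tumor call to sit within slop of a normal call's
breakpoints (chromosome pairing order-insensitive): matching on a single
end would over-filter translocations sharing one fragile site.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

from intervaltree import IntervalTree

from .model import SVCall

DEFAULT_SLOP = 5_000
DEFAULT_DRIVER_WINDOW = 1_000_000
DEFAULT_AMP_THRESHOLD = 1.25
DEFAULT_DEL_THRESHOLD = 0.95


@dataclass
class BreakpointWindow:
    """A half-open +/-slop window around one end of an SV."""

    sv_id: str
    which_end: int  # 1 or 2
    chrom: str
    interval: tuple[int, int]

    @classmethod
    def around(cls, sv: SVCall, which_end: int, slop: int) -> "BreakpointWindow":
        chrom, point = sv.breakpoints()[which_end - 1]
        return cls(sv.sv_id, which_end, chrom, (point - slop, point + slop))


@dataclass
class CnvSegment:
    chrom: str
    start: int
    end: int
    ratio: float
    label: str = "neutral"


def _pair_distance(a: SVCall, b: SVCall, same_class: bool = False) -> Optional[int]:
    """Max per-end breakpoint distance under the best chromosome pairing,
    or None if the calls cannot be paired."""
    if same_class and a.sv_class != b.sv_class:
        return None
    best = None
    pairings = [((a.chrom1, a.x, b.chrom1, b.x), (a.chrom2, a.y, b.chrom2, b.y)),
                ((a.chrom1, a.x, b.chrom2, b.y), (a.chrom2, a.y, b.chrom1, b.x))]
    for end1, end2 in pairings:
        c1a, p1a, c1b, p1b = end1
        c2a, p2a, c2b, p2b = end2
        if c1a != c1b or c2a != c2b:
            continue
        d = max(abs(p1a - p1b), abs(p2a - p2b))
        best = d if best is None else min(best, d)
    return best


def subtract_germline(
    tumor_svs: Sequence[SVCall],
    normal_svs: Sequence[SVCall],
    slop: int = DEFAULT_SLOP,
    same_class: bool = False,
) -> tuple[list[SVCall], list[dict]]:
    """Remove tumor calls matching a normal call at both breakpoints.

    A tumor call is germline-filtered iff some normal call has both
    breakpoints strictly within ``slop`` (half-open: a shift of exactly
    slop does not match). Returns the somatic calls plus a per-call
    decision log.
    """
    if slop < 0:
        raise ValueError("slop must be >= 0")
    somatic: list[SVCall] = []
    log: list[dict] = []
    for t in tumor_svs:
        hit = None
        for n in normal_svs:
            d = _pair_distance(t, n, same_class)
            if d is not None and d < slop:
                hit = n
                break
        log.append(
            {
                "sv_id": t.sv_id,
                "decision": "germline" if hit else "somatic",
                "matched_normal": hit.sv_id if hit else "",
            }
        )
        if hit is None:
            somatic.append(t)
    return somatic, log


def cross_validate(
    svs_a: Sequence[SVCall],
    svs_b: Sequence[SVCall],
    slop: int = DEFAULT_SLOP,
    same_class: bool = False,
) -> tuple[list[tuple[SVCall, SVCall]], list[SVCall], list[SVCall]]:
    """Greedy one-to-one matching of two call sets by breakpoint proximity.

    Candidate pairs (both ends within slop) are matched closest-first,
    ties broken lexically on (sv_id_a, sv_id_b); each call matches at
    most once. Symmetric in a/b up to tie order.
    """
    candidates = []
    for a in svs_a:
        for b in svs_b:
            d = _pair_distance(a, b, same_class)
            if d is not None and d < slop:
                candidates.append((d, a.sv_id, b.sv_id, a, b))
    candidates.sort(key=lambda t: (t[0], t[1], t[2]))
    used_a: set[str] = set()
    used_b: set[str] = set()
    matched: list[tuple[SVCall, SVCall]] = []
    for _d, ida, idb, a, b in candidates:
        if ida in used_a or idb in used_b:
            continue
        used_a.add(ida)
        used_b.add(idb)
        matched.append((a, b))
    a_only = [a for a in svs_a if a.sv_id not in used_a]
    b_only = [b for b in svs_b if b.sv_id not in used_b]
    return matched, a_only, b_only


def annotate_drivers(
    svs: Sequence[SVCall],
    genes: Sequence[tuple[str, int, int, str]],
    window: int = DEFAULT_DRIVER_WINDOW,
) -> list[tuple[str, str]]:
    """(sv_id, gene) pairs where a gene interval intersects the
    [breakpoint - window, breakpoint + window) region of either SV end."""
    trees: dict[str, IntervalTree] = {}
    for chrom, start, end, name in genes:
        trees.setdefault(chrom, IntervalTree()).addi(start, end, name)
    out: list[tuple[str, str]] = []
    for sv in svs:
        hits: set[str] = set()
        for chrom, point in sv.breakpoints():
            tree = trees.get(chrom)
            if tree is None:
                continue
            for iv in tree.overlap(point - window, point + window):
                hits.add(iv.data)
        out.extend((sv.sv_id, g) for g in sorted(hits))
    return out


def classify_cnv(
    segments: Iterable[tuple[str, int, int, float]],
    amp_threshold: float = DEFAULT_AMP_THRESHOLD,
    del_threshold: float = DEFAULT_DEL_THRESHOLD,
) -> list[CnvSegment]:
    """Label copy-ratio segments: amplification above ``amp_threshold``,
    deletion below ``del_threshold``, neutral otherwise."""
    if amp_threshold <= del_threshold:
        raise ValueError("amp_threshold must exceed del_threshold")
    out = []
    for chrom, start, end, ratio in segments:
        if ratio > amp_threshold:
            label = "amplification"
        elif ratio < del_threshold:
            label = "deletion"
        else:
            label = "neutral"
        out.append(CnvSegment(chrom, start, end, ratio, label))
    return out
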