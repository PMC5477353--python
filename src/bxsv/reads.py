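"""In-memory index over barcoded reads for fast window queries.

The barcode-window operations repeatedly ask "which barcodes have a read
overlapping [a, b)?". A per-chromosome sort by start position plus the
maximum read length makes each query two binary searches.
"""

from __future__ import annotations

from typing import Iterable, Union

import numpy as np

from .model import BarcodedRead


class ReadStore:
    """Column-store of BarcodedRead records indexed by (chrom, start)."""

    def __init__(self, reads: Iterable[BarcodedRead]):
        reads = list(reads)
        self.barcode_ids: list[str] = sorted({r.barcode for r in reads})
        self._bc_index = {b: i for i, b in enumerate(self.barcode_ids)}
        self._by_chrom: dict[str, dict[str, np.ndarray]] = {}
        self._reads_by_chrom: dict[str, list[BarcodedRead]] = {}
        for r in reads:
            self._reads_by_chrom.setdefault(r.chrom, []).append(r)
        for chrom, rs in self._reads_by_chrom.items():
            rs.sort(key=lambda r: (r.start, r.end, r.read_id))
            self._by_chrom[chrom] = {
                "start": np.array([r.start for r in rs], dtype=np.int64),
                "end": np.array([r.end for r in rs], dtype=np.int64),
                "bc": np.array([self._bc_index[r.barcode] for r in rs], dtype=np.int64),
                "maxlen": max((r.end - r.start for r in rs), default=0),
            }
        self.n_reads = len(reads)

    def __len__(self) -> int:
        return self.n_reads

    @property
    def chroms(self) -> list[str]:
        return sorted(self._by_chrom)

    def overlapping_indices(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Indices (within chrom order) of reads overlapping [start, end)."""
        cols = self._by_chrom.get(chrom)
        if cols is None or end <= start:
            return np.empty(0, dtype=np.int64)
        s = cols["start"]
        lo = np.searchsorted(s, start - cols["maxlen"], side="left")
        hi = np.searchsorted(s, end, side="left")
        idx = np.arange(lo, hi)
        keep = cols["end"][idx] > start
        return idx[keep]

    def overlapping_reads(self, chrom: str, start: int, end: int) -> list[BarcodedRead]:
        rs = self._reads_by_chrom.get(chrom, [])
        return [rs[i] for i in self.overlapping_indices(chrom, start, end)]

    def barcodes_in(self, chrom: str, start: int, end: int) -> frozenset:
        """Distinct barcodes with at least one read overlapping [start, end)."""
        cols = self._by_chrom.get(chrom)
        if cols is None:
            return frozenset()
        idx = self.overlapping_indices(chrom, start, end)
        ids = np.unique(cols["bc"][idx])
        return frozenset(self.barcode_ids[i] for i in ids)

    def reads_of_barcodes(self, barcodes: Iterable[str]) -> list[BarcodedRead]:
        wanted = set(barcodes)
        return [
            r
            for rs in self._reads_by_chrom.values()
            for r in rs
            if r.barcode in wanted
        ]

    def all_reads(self) -> list[BarcodedRead]:
        return [r for rs in self._reads_by_chrom.values() for r in rs]

    def chrom_bounds(self, chrom: str) -> tuple[int, int]:
        cols = self._by_chrom[chrom]
        return int(cols["start"].min()), int(cols["end"].max())


ReadsLike = Union[ReadStore, Iterable[BarcodedRead]]


def as_read_store(reads: ReadsLike) -> ReadStore:
    return reads if isinstance(reads, ReadStore) else ReadStore(reads)
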