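"""Static plots: molecule maps, barcode-overlap heatmaps, depth tracks."""

from __future__ import annotations

from typing import Sequence

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt
import numpy as np

from .depth import HaplotypeDepthProfile
from .finemap import MoleculeRecord, OverlapMatrix

HAP_COLORS = {"1": "black", "2": "red", "": "0.6"}


def molecule_map(
    molecules: Sequence[MoleculeRecord],
    out: str,
    breakpoints: Sequence[tuple[str, int]] = (),
    title: str = "",
) -> None:
    """One row per molecule; segments are its read clusters, colored by
    haplotype call; dashed verticals mark breakpoints."""
    fig, ax = plt.subplots(figsize=(10, max(2, 0.12 * len(molecules) + 1)))
    order = sorted(
        range(len(molecules)),
        key=lambda i: min(c.start for c in molecules[i].clusters),
    )
    for row, i in enumerate(order):
        mol = molecules[i]
        color = HAP_COLORS.get(mol.haplotype, "0.6")
        for cl in mol.clusters:
            ax.plot([cl.start, cl.end], [row, row], color=color, lw=2)
            ax.plot(
                [r.start for r in cl.reads],
                [row] * cl.n_reads,
                ".",
                color=color,
                ms=2,
            )
    for _chrom, pos in breakpoints:
        ax.axvline(pos, color="tab:blue", ls="--", lw=0.8)
    ax.set_xlabel("reference position (bp)")
    ax.set_ylabel("SV-specific molecule")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def overlap_heatmap(
    matrix: OverlapMatrix,
    out: str,
    title: str = "",
    quantiles: tuple[float, float] = (0.95, 0.99),
) -> None:
    """Barcode-sharing heatmap; off-diagonal color thresholds are display
    quantiles of the off-diagonal values."""
    m = matrix.matrix.astype(float)
    off = m[~np.eye(len(m), dtype=bool)]
    vmax = np.quantile(off, quantiles[1]) if off.size else 1.0
    fig, ax = plt.subplots(figsize=(7, 6))
    extent_mb = [
        matrix.region_start / 1e6,
        (matrix.region_start + len(m) * matrix.bin_size) / 1e6,
    ]
    im = ax.imshow(
        m,
        origin="lower",
        cmap="coolwarm",
        vmax=max(vmax, 1.0),
        extent=extent_mb + extent_mb,
    )
    fig.colorbar(im, ax=ax, label="shared barcodes")
    ax.set_xlabel(f"{matrix.chrom} (Mb)")
    ax.set_ylabel(f"{matrix.chrom} (Mb)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)


def depth_track(
    profile: HaplotypeDepthProfile,
    out: str,
    regions: Sequence[tuple[str, int, int]] = (),
    title: str = "",
) -> None:
    """Per-SNV allele barcode counts, haplotype 1 black / haplotype 2 red."""
    df = profile.snvs
    fig, ax = plt.subplots(figsize=(10, 3.5))
    ax.plot(df["pos"] / 1e6, df["count_hap1"], ".", color="black", ms=2.5, label="haplotype 1")
    ax.plot(df["pos"] / 1e6, df["count_hap2"], ".", color="red", ms=2.5, label="haplotype 2")
    for _c, s, e in regions:
        ax.axvspan(s / 1e6, e / 1e6, color="tab:blue", alpha=0.08)
    ax.set_xlabel("position (Mb)")
    ax.set_ylabel("allele barcode count")
    ax.legend(markerscale=4, frameon=False)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(out, dpi=120)
    plt.close(fig)
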