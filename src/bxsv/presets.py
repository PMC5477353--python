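"""Canned simulation scenarios.

Three presets mirror the study conditions the toolkit is designed for:

* ``normal`` — an unrearranged germline library (mean molecule ~51 kb).
* ``right_met`` — a metastasis-like derived haplotype on chromosome 10:
  a 30-Mb deletion plus a nearby inversion with deletions at its
  boundaries, the whole motif tandem-duplicated ~9-fold, all on
  haplotype 1 (tumor purity < 40%; mean molecule ~45 kb).
* ``left_met`` — five discrete events (two duplications, two deletions,
  an inversion) on haplotype 1, with a second, distinct rearrangement on
  haplotype 2 close to the inversion so the inversion's barcode windows
  collect molecules from both haplotypes; one duplication is tagged as
  visible only to an orthogonal short-read caller.

Coordinates are desk-scale: molecules are simulated over the full
reference extent (so droplet co-occupancy statistics stay realistic) but
reads are emitted only within +/-1 Mb of each true breakpoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

from .model import RearrangementSpec, Segment
from .simulate import (
    SimSample,
    build_reference_model,
    merge_regions,
    simulate_sample,
)

MB = 1_000_000

PRESET_NAMES = ("normal", "right_met", "left_met")


@dataclass
class PresetConfig:
    """Fully parameterized scenario: scaffold + sample settings + truth."""

    name: str
    genome_extent: list[tuple[str, int, int]]
    scaffold_regions: list[tuple[str, int, int]]
    snv_density: float
    phase_block_mean: float
    mean_molecule_length: int
    purity: float
    n_partitions: int
    rearrangements: list[RearrangementSpec] = field(default_factory=list)
    active_regions: Optional[list[tuple[str, int, int]]] = None
    blind_to_linkedread: frozenset = frozenset()
    description: str = ""


def _breakpoint_windows(
    breakpoints: Sequence[tuple[str, int]], pad: int = MB
) -> list[tuple[str, int, int]]:
    return merge_regions([(c, p - pad, p + pad) for c, p in breakpoints])


def _right_met_spec() -> RearrangementSpec:
    """Derived haplotype 1 of the right-metastasis scenario on chr10.

    One motif copy runs: 92.79->93.32 Mb forward, a 30-Mb deletion to
    123.32 Mb, forward to 123.75 Mb, an inverted 123.79-124.20 Mb
    segment (deletions at both inversion boundaries), then forward from
    124.35 Mb to 131.51 Mb; nine copies lie head to tail.
    """
    c = "chr10"
    pre = Segment(c, 90_000_000, 92_790_688)
    a = Segment(c, 92_790_688, 93_321_592)
    b = Segment(c, 123_321_592, 123_750_000)
    inv = Segment(c, 123_790_000, 124_200_000, "reverse")
    d = Segment(c, 124_350_000, 131_511_990)
    post = Segment(c, 131_511_990, 132_500_000)
    return RearrangementSpec(
        name="right_met_hap1",
        haplotype=1,
        segments=[pre, a, b, inv, d, post],
        tandem_copies=9,
        tandem_slice=(1, 5),
    )


def _left_met_specs() -> list[RearrangementSpec]:
    # full-chromosome identity flanks keep droplet co-occupancy (hence
    # barcode-collision background) at whole-genome-library levels
    c = "chr10"
    ext = (0, 135_000_000)
    hap1 = RearrangementSpec(
        name="left_met_hap1",
        haplotype=1,
        segments=[
            Segment(c, ext[0], 122_900_000),
            Segment(c, 122_400_000, 122_900_000),   # DUP (122.4, 122.9)
            Segment(c, 122_900_000, 123_450_000),
            Segment(c, 123_650_000, 123_670_000),   # DEL (123.45, 123.65)
            Segment(c, 123_170_000, 123_450_000),   # DUP (123.17, 123.67)
            Segment(c, 123_650_000, 123_800_000),   # DEL (123.45, 123.65) again
            Segment(c, 123_800_000, 124_000_000, "reverse"),  # INV (123.8, 124.0)
            Segment(c, 124_000_000, 124_550_000),
            Segment(c, 124_850_000, ext[1]),        # DEL (124.55, 124.85)
        ],
    )
    hap2 = RearrangementSpec(
        name="left_met_hap2",
        haplotype=2,
        segments=[
            Segment(c, ext[0], 123_810_000),
            Segment(c, 123_810_000, 123_990_000, "reverse"),  # INV (123.81, 123.99)
            Segment(c, 123_990_000, ext[1]),
        ],
    )
    return [hap1, hap2]


def preset(name: str) -> PresetConfig:
    """Return the fully parameterized configuration for a named scenario."""
    if name == "normal":
        region = ("chr10", 90_000_000, 95_000_000)
        return PresetConfig(
            name="normal",
            genome_extent=[("chr10", 0, 250_000_000)],
            scaffold_regions=[region],
            snv_density=1e-3,
            phase_block_mean=1.4 * MB,
            mean_molecule_length=51_000,
            purity=0.0,
            n_partitions=65_000,
            active_regions=[region],
            description="unrearranged germline library, ~51 kb molecules",
        )
    if name == "right_met":
        spec = _right_met_spec()
        bps = [
            ("chr10", 92_790_688),
            ("chr10", 93_321_592),
            ("chr10", 123_321_592),
            ("chr10", 123_750_000),
            ("chr10", 123_790_000),
            ("chr10", 124_200_000),
            ("chr10", 124_350_000),
            ("chr10", 131_511_990),
        ]
        windows = _breakpoint_windows(bps)
        return PresetConfig(
            name="right_met",
            genome_extent=[("chr10", 90_000_000, 132_500_000)],
            scaffold_regions=windows,
            snv_density=1e-3,
            phase_block_mean=200 * MB,  # one block spans the locus
            mean_molecule_length=45_000,
            purity=0.4,
            n_partitions=8_000,
            rearrangements=[spec],
            active_regions=windows,
            description=(
                "haplotype-1 motif: 30-Mb deletion, inversion with boundary "
                "deletions, ~9-fold tandem duplication"
            ),
        )
    if name == "left_met":
        specs = _left_met_specs()
        roi = [("chr10", 122_000_000, 126_000_000)]
        return PresetConfig(
            name="left_met",
            genome_extent=[("chr10", 0, 135_000_000)],
            scaffold_regions=roi,
            snv_density=1e-3,
            phase_block_mean=200 * MB,
            mean_molecule_length=45_000,
            purity=0.4,
            n_partitions=70_000,
            rearrangements=specs,
            active_regions=roi,
            blind_to_linkedread=frozenset({"DUP1"}),
            description=(
                "five haplotype-1 events (2 DUP, 2 DEL, 1 INV) plus a distinct "
                "haplotype-2 inversion at nearly the same locus; DUP1 visible "
                "only to the orthogonal caller"
            ),
        )
    raise ValueError(f"unknown preset {name!r}; choose from {PRESET_NAMES}")


def simulate_preset(
    name: str,
    seed: int = 0,
    n_partitions: Optional[int] = None,
    purity: Optional[float] = None,
    snv_misassignment_rate: float = 0.005,
) -> dict[str, SimSample]:
    """Build the scaffold and simulate the preset's samples.

    Returns ``{"normal": ...}`` plus ``{"tumor": ...}`` for tumor
    presets. Both samples share one germline scaffold, and their seeds
    are derived from ``seed`` so runs are reproducible end to end.
    """
    cfg = preset(name)
    scaffold = build_reference_model(
        cfg.scaffold_regions,
        snv_density=cfg.snv_density,
        phase_block_mean=cfg.phase_block_mean,
        seed=seed,
    )
    n_parts = n_partitions if n_partitions is not None else cfg.n_partitions
    pur = purity if purity is not None else cfg.purity
    out = {
        "normal": simulate_sample(
            scaffold,
            rearrangements=(),
            purity=0.0,
            mean_molecule_length=51_000,
            n_partitions=n_parts,
            seed=seed * 2 + 1,
            sample="normal",
            genome_extent=cfg.genome_extent,
            active_regions=cfg.active_regions,
            snv_misassignment_rate=snv_misassignment_rate,
        )
    }
    if cfg.rearrangements:
        out["tumor"] = simulate_sample(
            scaffold,
            rearrangements=cfg.rearrangements,
            purity=pur,
            mean_molecule_length=cfg.mean_molecule_length,
            n_partitions=n_parts,
            seed=seed * 2 + 2,
            sample=cfg.name,
            genome_extent=cfg.genome_extent,
            active_regions=cfg.active_regions,
            snv_misassignment_rate=snv_misassignment_rate,
        )
    return out


# ---------------------------------------------------------------------------
# ad-hoc scenario construction
# ---------------------------------------------------------------------------

def specs_from_events(
    chrom: str,
    extent: tuple[int, int],
    events: Sequence[tuple[str, int, int, int]],
) -> list[RearrangementSpec]:
    """Build per-haplotype derived-genome specs from simple event tuples.

    ``events`` are (sv_class, haplotype, x, y) with sv_class in
    {DEL, DUP, INV}; events on one haplotype must be non-overlapping.
    A DUP is a single extra tandem copy of [x, y).
    """
    by_hap: dict[int, list[tuple[str, int, int]]] = {}
    for svc, hap, x, y in events:
        if not (extent[0] <= x < y <= extent[1]):
            raise ValueError(f"event ({svc},{x},{y}) outside extent {extent}")
        by_hap.setdefault(hap, []).append((svc.upper(), x, y))
    specs = []
    for hap, evs in sorted(by_hap.items()):
        evs.sort(key=lambda e: e[1])
        for (_, _, y0), (_, x1, _) in zip(evs, evs[1:]):
            if x1 < y0:
                raise ValueError("overlapping events on one haplotype")
        segs: list[Segment] = []
        cursor = extent[0]
        for svc, x, y in evs:
            if svc == "DEL":
                if x > cursor:
                    segs.append(Segment(chrom, cursor, x))
                cursor = y
            elif svc == "DUP":
                segs.append(Segment(chrom, cursor, y))
                segs.append(Segment(chrom, x, y))
                cursor = y
            elif svc == "INV":
                if x > cursor:
                    segs.append(Segment(chrom, cursor, x))
                segs.append(Segment(chrom, x, y, "reverse"))
                cursor = y
            else:
                raise ValueError(f"unsupported event class {svc}")
        if cursor < extent[1]:
            segs.append(Segment(chrom, cursor, extent[1]))
        specs.append(
            RearrangementSpec(name=f"scenario_hap{hap}", haplotype=hap, segments=segs)
        )
    return specs


def random_scenario(
    seed: int,
    n_svs: Optional[int] = None,
    purity: Optional[float] = None,
    n_partitions: int = 150_000,
) -> dict:
    """A randomized tumor/normal pair for parameter-recovery checks.

    Draws 2-4 well-separated events (DEL/DUP/INV, random haplotypes,
    spans 0.4-0.8 Mb) on a chromosome-scale extent, one phase block, and
    simulates both samples at the configured depth. Returns the samples
    plus the truth cis/trans relationship of every SV pair (same
    haplotype = cis, different = trans).
    """
    import numpy as np

    rng = np.random.default_rng(seed)
    chrom, extent = "chr1", (0, 160_000_000)
    n = int(n_svs) if n_svs is not None else int(rng.integers(2, 5))
    pur = float(purity) if purity is not None else float(rng.uniform(0.3, 0.5))
    classes = [("DEL", "DUP", "INV")[i] for i in rng.integers(0, 3, size=n)]
    haps = [int(h) for h in rng.integers(1, 3, size=n)]
    events = []
    cursor = 60_000_000
    for svc, hap in zip(classes, haps):
        span = int(rng.integers(400_000, 800_000))
        events.append((svc, hap, cursor, cursor + span))
        cursor += span + int(rng.integers(1_500_000, 2_500_000))
    specs = specs_from_events(chrom, extent, events)
    pad = 150_000
    windows = merge_regions(
        [(chrom, p - pad, p + pad) for _, _, x, y in events for p in (x, y)]
    )
    scaffold = build_reference_model(
        windows, snv_density=1e-3, phase_block_mean=1_000 * MB, seed=seed
    )
    normal = simulate_sample(
        scaffold, (), purity=0.0, mean_molecule_length=51_000,
        n_partitions=n_partitions, seed=seed * 2 + 1, sample="normal",
        genome_extent=[(chrom, *extent)], active_regions=windows,
    )
    tumor = simulate_sample(
        scaffold, specs, purity=pur, mean_molecule_length=45_000,
        n_partitions=n_partitions, seed=seed * 2 + 2, sample="tumor",
        genome_extent=[(chrom, *extent)], active_regions=windows,
    )
    truth_rel = {}
    svs = tumor.truth.sv_calls
    for i in range(len(svs)):
        for j in range(i + 1, len(svs)):
            hi = tumor.truth.sv_haplotype[svs[i].sv_id]
            hj = tumor.truth.sv_haplotype[svs[j].sv_id]
            truth_rel[(svs[i].sv_id, svs[j].sv_id)] = "cis" if hi == hj else "trans"
    return {
        "normal": normal,
        "tumor": tumor,
        "events": events,
        "purity": pur,
        "truth_relationships": truth_rel,
    }
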