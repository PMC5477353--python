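"""Shared simulation fixtures.

Simulations are session-scoped: each represents one study condition and
is reused across test modules. ``scripts/`` is importable so tests can
exercise the same target computations the acceptance script runs.
"""

import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "scripts"))

from bxsv.presets import simulate_preset, specs_from_events  # noqa: E402
from bxsv.reads import ReadStore  # noqa: E402
from bxsv.simulate import build_reference_model, merge_regions, simulate_sample  # noqa: E402

MB = 1_000_000


def _pair(events, seed, n_partitions=50_000, purity=0.4, extent=(0, 80 * MB),
          pad=250_000, chrom="chr1", misassignment=0.005):
    """Small tumor/normal pair around the given events."""
    specs = specs_from_events(chrom, extent, events)
    windows = merge_regions(
        [(chrom, p - pad, p + pad) for _, _, x, y in events for p in (x, y)]
    )
    scaffold = build_reference_model(
        windows, snv_density=1e-3, phase_block_mean=1_000 * MB, seed=seed
    )
    common = dict(
        n_partitions=n_partitions,
        genome_extent=[(chrom, *extent)],
        active_regions=windows,
        mean_molecule_length=45_000,
    )
    normal = simulate_sample(
        scaffold, (), purity=0.0, seed=seed * 2 + 1, sample="normal", **common
    )
    tumor = simulate_sample(
        scaffold, specs, purity=purity, seed=seed * 2 + 2, sample="tumor",
        snv_misassignment_rate=misassignment, **common,
    )
    return {"normal": normal, "tumor": tumor, "scaffold": scaffold,
            "events": events, "windows": windows}


@pytest.fixture(scope="session")
def small_pair():
    """A duplication on haplotype 1 and an inversion on haplotype 2 (trans)."""
    return _pair(
        [("DUP", 1, 60 * MB, 60 * MB + 500_000),
         ("INV", 2, 61_500_000, 62_000_000)],
        seed=5,
    )


@pytest.fixture(scope="session")
def small_del():
    """A single 400-kb deletion on haplotype 1."""
    return _pair([("DEL", 1, 60 * MB, 60_400_000)], seed=9)


@pytest.fixture(scope="session")
def small_normal(small_del):
    """Germline-only sample (no rearrangements)."""
    return small_del["normal"]


@pytest.fixture(scope="session")
def right_met():
    """The ninefold-duplicated deletion/inversion motif scenario."""
    return simulate_preset("right_met", seed=1)


@pytest.fixture(scope="session")
def left_met():
    """Five haplotype-1 events plus a haplotype-2 inversion nearby."""
    return simulate_preset("left_met", seed=1)


@pytest.fixture(scope="session")
def tumor_store(small_pair):
    return ReadStore(small_pair["tumor"].reads)


@pytest.fixture(scope="session")
def normal_store(small_pair):
    return ReadStore(small_pair["normal"].reads)
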