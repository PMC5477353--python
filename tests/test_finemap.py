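"""Molecule reconstruction, breakpoint fine-mapping, junction graphs,
and barcode-overlap matrices."""

import numpy as np
import pytest

from bxsv.finemap import (
    barcode_overlap_matrix,
    estimate_mean_molecule_length,
    finemap_breakpoint,
    infer_junction_graph,
    letter_labels,
    reconstruct_molecules,
)
from bxsv.model import BarcodedRead, SVCall, SVClass
from bxsv.phasing import sv_specific_barcodes
from bxsv.reads import ReadStore

MB = 1_000_000


def read(barcode, start, chrom="chr1", length=150):
    return BarcodedRead(
        read_id=f"r{barcode}{start}", sample="s", chrom=chrom, start=start,
        end=start + length, strand="+", barcode=barcode,
    )


class TestReconstructMolecules:
    def test_gap_rule_splits_clusters(self):
        reads = [read("A", p) for p in (10_000, 11_000, 12_000, 300_000, 301_000)]
        records = reconstruct_molecules(reads, gap_max=50_000)
        assert len(records) == 2
        assert sorted(len(m.clusters[0].reads) for m in records) == [2, 3]

    def test_sv_barcode_clusters_join_into_one_molecule(self):
        reads = [read("A", p) for p in (10_000, 11_000)] + [
            read("A", p) for p in (900_000, 901_000)
        ]
        (joined,) = reconstruct_molecules(
            reads, gap_max=50_000, sv_barcodes={"A"}, sv_id="DEL1"
        )
        assert len(joined.clusters) == 2 and joined.sv_ids == ["DEL1"]
        separate = reconstruct_molecules(reads, gap_max=50_000)
        assert len(separate) == 2

    def test_min_reads_per_cluster_filters(self):
        reads = [read("A", 10_000), read("B", 20_000), read("B", 21_000)]
        records = reconstruct_molecules(reads, min_reads_per_cluster=2)
        assert [m.barcode for m in records] == ["B"]

    def test_recovers_simulated_molecules(self, small_normal):
        """>=95% of 3+-read truth molecules are rebuilt with <=2 kb span
        error (bounded by the read spacing)."""
        truth = small_normal.truth
        records = reconstruct_molecules(ReadStore(small_normal.reads))
        clusters_by_bc = {}
        for m in records:
            clusters_by_bc.setdefault(m.barcode, []).extend(m.clusters)
        mol = truth.molecules
        targets = mol[mol["n_reads"] >= 3]
        ok = total = 0
        for _, t in targets.iterrows():
            (chrom, fs, fe, _), = truth.genomes[t["genome"]].map_interval(
                int(t["d_start"]), int(t["d_end"])
            )
            total += 1
            for c in clusters_by_bc.get(t["barcode"], []):
                if c.chrom == chrom and c.start >= fs - 1000 and c.end <= fe + 1000:
                    span_err = (fe - fs) - c.span
                    if 0 <= span_err <= 2_000:
                        ok += 1
                        break
        assert total > 500
        assert ok / total >= 0.95

    def test_partition_occupancy_bounds_molecules_per_barcode(self, small_normal):
        records = reconstruct_molecules(
            ReadStore(small_normal.reads),
            loci=[("chr1", 59_600_000, 60_800_000)],
        )
        per_bc = {}
        for m in records:
            per_bc[m.barcode] = per_bc.get(m.barcode, 0) + 1
        assert max(per_bc.values()) <= 5

    def test_mean_length_estimator_corrects_censoring(self, small_normal):
        records = reconstruct_molecules(ReadStore(small_normal.reads))
        mean, spacing = estimate_mean_molecule_length(records)
        assert abs(spacing - 1_000) < 150
        assert abs(mean - 45_000) / 45_000 < 0.10


class TestFinemapBreakpoint:
    def _profile_reads(self, counts, region_start, bin_size=1_000):
        reads = []
        for w, n in enumerate(counts):
            for b in range(n):
                reads.append(read(f"B{b}", region_start + w * bin_size + 400, length=100))
        barcodes = {f"B{b}" for b in range(max(counts))}
        return reads, barcodes

    def test_sharp_drop_places_edge(self):
        counts = [0, 0, 50, 48, 52, 49, 3, 1, 0]
        region_start = 1_000_000
        reads, barcodes = self._profile_reads(counts, region_start)
        # anchor the called breakpoint so the window grid starts at
        # region_start: the grid is centred on the call
        sv = SVCall("d", "chr1", region_start + 4_000, "chr1", 90_000_000, SVClass.DEL)
        p = finemap_breakpoint(sv, barcodes, reads, which_end=1,
                               region_size=9_000, bin_size=1_000)
        assert list(p.counts) == counts
        # edge between the 6th and 7th windows
        assert p.refined and p.refined_pos == region_start + 6_000
        assert p.support_side == "left"

    def test_uniform_counts_flag_unrefined(self):
        counts = [20] * 9
        region_start = 1_000_000
        reads, barcodes = self._profile_reads(counts, region_start)
        sv = SVCall("d", "chr1", region_start + 4_000, "chr1", 90_000_000, SVClass.DEL)
        p = finemap_breakpoint(sv, barcodes, reads, which_end=1,
                               region_size=9_000, bin_size=1_000)
        assert not p.refined and p.refined_pos == sv.x

    def test_too_few_barcodes_rejected(self):
        sv = SVCall("d", "chr1", 100_000, "chr1", 90_000_000, SVClass.DEL)
        with pytest.raises(ValueError, match="barcodes"):
            finemap_breakpoint(sv, {"A"}, [], which_end=1)

    def test_refinement_bounded_by_region(self, small_del):
        tumor = small_del["tumor"]
        store = ReadStore(tumor.reads)
        (sv,) = tumor.truth.sv_calls
        s = sv_specific_barcodes(sv, store, 100_000, mean_molecule_length=45_000)
        for end in (1, 2):
            p = finemap_breakpoint(sv, s, store, which_end=end)
            called = sv.breakpoints()[end - 1][1]
            assert abs(p.refined_pos - called) <= 250_000

    def test_simulated_deletion_refined_to_the_window(self, small_del):
        tumor = small_del["tumor"]
        store = ReadStore(tumor.reads)
        (sv,) = tumor.truth.sv_calls
        s = sv_specific_barcodes(sv, store, 100_000, mean_molecule_length=45_000)
        p1 = finemap_breakpoint(sv, s, store, which_end=1)
        p2 = finemap_breakpoint(sv, s, store, which_end=2)
        assert p1.refined and abs(p1.refined_pos - sv.x) <= 1_000
        assert p2.refined and abs(p2.refined_pos - sv.y) <= 1_000
        assert (p1.support_side, p2.support_side) == ("left", "right")


class TestJunctionGraph:
    def _molecules(self, sv_class, x, y, n=6):
        """Synthetic junction-spanning molecules with 20-kb overhangs."""
        mols = []
        for i in range(n):
            bc = f"J{i}"
            if sv_class == "DEL":
                reads = [read(bc, p) for p in range(x - 20_000, x, 1_000)]
                reads += [read(bc, p) for p in range(y, y + 20_000, 1_000)]
            elif sv_class == "INV":  # junction 1: left of x joins left of y
                reads = [read(bc, p) for p in range(x - 20_000, x, 1_000)]
                reads += [read(bc, p) for p in range(y - 20_000, y, 1_000)]
            mols.extend(
                reconstruct_molecules(reads, sv_barcodes={bc}, sv_id="sv")
            )
        return mols

    def test_deletion_yields_single_forward_edge(self):
        x, y = 1_000_000, 1_800_000
        g = infer_junction_graph(self._molecules("DEL", x, y),
                                 [("chr1", x), ("chr1", y)])
        ((a, b, d),) = list(g.edges(data=True))
        assert {a, b} == {f"chr1:{x}:left", f"chr1:{y}:right"}
        assert d["orientation"] == "forward" and d["support"] == 6

    def test_inversion_yields_reverse_edge(self):
        x, y = 1_000_000, 1_800_000
        g = infer_junction_graph(self._molecules("INV", x, y),
                                 [("chr1", x), ("chr1", y)])
        ((a, b, d),) = list(g.edges(data=True))
        assert {a, b} == {f"chr1:{x}:left", f"chr1:{y}:left"}
        assert d["orientation"] == "reverse"

    def test_no_sv_simulation_gives_empty_graph(self, small_normal):
        store = ReadStore(small_normal.reads)
        mols = reconstruct_molecules(
            store, loci=[("chr1", 59_900_000, 60_100_000),
                         ("chr1", 60_300_000, 60_500_000)]
        )
        g = infer_junction_graph(mols, [("chr1", 60_000_000), ("chr1", 60_400_000)])
        assert g.number_of_edges() == 0

    def test_right_met_motif_adjacency(self, right_met):
        """The duplication junction joins the right side of the motif
        start to the left side of the motif end (head-to-tail copies);
        the inner inversion joins same-side segment ends."""
        tumor = right_met["tumor"]
        store = ReadStore(tumor.reads)
        edges = {}
        for sv in tumor.truth.sv_calls:
            s = sv_specific_barcodes(sv, store, 100_000, mean_molecule_length=45_000)
            loci = [(sv.chrom1, sv.x - 250_000, sv.x + 250_000),
                    (sv.chrom2, sv.y - 250_000, sv.y + 250_000)]
            mols = [m for m in reconstruct_molecules(
                store, barcodes=s, loci=loci, sv_barcodes=s, sv_id=sv.sv_id)
                if len(m.clusters) >= 2]
            g = infer_junction_graph(mols, [(sv.chrom1, sv.x), (sv.chrom2, sv.y)])
            for a, b, d in g.edges(data=True):
                edges[frozenset((a, b))] = d["orientation"]
        dup = next(sv for sv in tumor.truth.sv_calls if sv.sv_class is SVClass.DUP)
        inv = next(sv for sv in tumor.truth.sv_calls
                   if sv.sv_class is SVClass.INV and sv.x == 123_750_000)
        assert edges[frozenset((f"chr10:{dup.x}:right",
                                f"chr10:{dup.y}:left"))] == "forward"
        assert edges[frozenset((f"chr10:{inv.x}:left",
                                f"chr10:{inv.y}:left"))] == "reverse"

    def test_letter_labels_follow_coordinates(self):
        import networkx as nx

        g = nx.Graph()
        g.add_edge("chr1:100:left", "chr1:900:right")
        labels = letter_labels(g)
        assert labels == {"chr1:100:left": "a", "chr1:900:right": "b"}


class TestOverlapMatrix:
    def test_counts_and_jaccard(self):
        reads = [read(f"S{i}", 5_000) for i in range(3)]  # shared in both bins
        reads += [read(f"S{i}", 15_000) for i in range(3)]
        reads += [read(f"A{i}", 6_000) for i in range(7)]  # bin-0 only: 10 total
        reads += [read(f"B{i}", 16_000) for i in range(9)]  # bin-1 only: 12 total
        m = barcode_overlap_matrix(reads, ("chr1", 0, 20_000), bin_size=10_000)
        assert m.matrix[0, 1] == 3
        assert m.matrix[0, 0] == 10 and m.matrix[1, 1] == 12
        j = barcode_overlap_matrix(reads, ("chr1", 0, 20_000), bin_size=10_000,
                                   normalize="jaccard")
        assert j.matrix[0, 1] == pytest.approx(3 / 19)

    def test_single_bin_region_rejected(self):
        with pytest.raises(ValueError, match="2 bins"):
            barcode_overlap_matrix([], ("chr1", 0, 10_000), bin_size=10_000)

    def test_symmetry_and_diagonal_dominance(self, small_normal):
        m = barcode_overlap_matrix(
            ReadStore(small_normal.reads), ("chr1", 59_800_000, 60_600_000)
        )
        assert np.allclose(m.matrix, m.matrix.T)
        assert all(m.matrix[i, i] == m.matrix[i].max() for i in range(m.n_bins))

    def test_sharing_decays_beyond_molecule_length(self, small_normal):
        m = barcode_overlap_matrix(
            ReadStore(small_normal.reads), ("chr1", 59_800_000, 60_600_000)
        ).matrix
        n = len(m)
        near = np.mean([m[i, i + 2] for i in range(n - 2)])  # 20 kb apart
        far = np.mean([m[i, i + 20] for i in range(n - 20)])  # 200 kb apart
        assert near > 5 * max(far, 0.2)

    def test_rearranged_bins_share_excess_barcodes(self, small_del):
        """Deletion-spanning molecules link the bins flanking the two
        breakpoints far beyond the background at that distance."""
        tumor = small_del["tumor"]
        (sv,) = tumor.truth.sv_calls  # DEL (60.0 Mb, 60.4 Mb)
        m = barcode_overlap_matrix(
            ReadStore(tumor.reads), ("chr1", 59_800_000, 60_600_000)
        ).matrix
        bin_of = lambda pos: (pos - 59_800_000) // 10_000
        junction = m[bin_of(sv.x) - 1, bin_of(sv.y) + 1]
        background = np.mean(
            [m[i, i + 40] for i in range(len(m) - 40) if i != bin_of(sv.x) - 1]
        )
        assert junction > 5 * max(background, 0.5)
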