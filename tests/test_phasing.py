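"""Barcode set algebra and cis/trans phasing.

Unit examples use hand-built reads and variants; simulation-backed
checks compare the recovered sets against the simulator's truth tables.
"""

import numpy as np
import pytest

from bxsv.model import BarcodedRead, PhasedVariant, SVCall, SVClass
from bxsv.phasing import (
    BreakpointsTooCloseError,
    allele_support_sets,
    assign_haplotype,
    background_rate,
    link_svs,
    phase_all_pairs,
    phase_sv_pair,
    sv_phasing_table,
    sv_specific_barcodes,
    window_barcodes,
)
from bxsv.reads import ReadStore


def read(barcode, start, chrom="chr1", length=150):
    return BarcodedRead(
        read_id=f"r{barcode}{start}", sample="s", chrom=chrom, start=start,
        end=start + length, strand="+", barcode=barcode,
    )


def variant(pos, hap_of_alt, bc_ref=(), bc_alt=(), phase_set="1", chrom="chr1"):
    return PhasedVariant(
        chrom=chrom, pos=pos, ref_allele="A", alt_allele="G",
        phase_set=phase_set, hap_of_alt=hap_of_alt,
        barcodes_ref=frozenset(bc_ref), barcodes_alt=frozenset(bc_alt),
    )


class TestWindowBarcodes:
    def test_reads_inside_window_only(self):
        reads = [read("A", 10_050), read("B", 10_060), read("C", 90_000)]
        assert window_barcodes(reads, "chr1", 10_000, w=2_000) == {"A", "B"}

    def test_window_arithmetic_is_half_open_centred(self):
        # point 92,790,688 with w=100 kb spans [92,740,688, 92,840,688)
        inside_low = read("L", 92_740_600)  # overlaps the left edge
        outside_high = read("H", 92_840_688)  # starts at the right edge
        inside_high = read("I", 92_840_500)
        b = window_barcodes(
            [inside_low, outside_high, inside_high], "chr1", 92_790_688, w=100_000
        )
        assert b == {"L", "I"}

    def test_zero_window_rejected(self):
        with pytest.raises(ValueError):
            window_barcodes([], "chr1", 100, w=0)

    def test_enlarging_w_never_shrinks_set(self, tumor_store):
        for w in (20_000, 60_000, 100_000):
            small = window_barcodes(tumor_store, "chr1", 60_000_000, w=w)
            big = window_barcodes(tumor_store, "chr1", 60_000_000, w=w + 40_000)
            assert small <= big


class TestSvSpecificBarcodes:
    def test_intersection_of_window_sets(self):
        reads = [read("A", 0), read("B", 10), read("C", 20),
                 read("B", 1_000_000), read("C", 1_000_010), read("D", 1_000_020)]
        call = SVCall("d", "chr1", 100, "chr1", 1_000_100, SVClass.DEL)
        s = sv_specific_barcodes(call, reads, w=1_000, min_span=500_000)
        assert s == {"B", "C"}

    def test_close_breakpoints_refused(self):
        call = SVCall("d", "chr1", 100_000, "chr1", 150_000, SVClass.DEL)
        with pytest.raises(BreakpointsTooCloseError, match="too close"):
            sv_specific_barcodes(call, [], w=10_000, mean_molecule_length=50_000)

    def test_interchromosomal_always_allowed(self):
        call = SVCall("t", "chr1", 100, "chr2", 200, SVClass.TRA)
        assert sv_specific_barcodes(call, [], w=1_000) == frozenset()

    def test_recovers_truth_spanning_molecules(self, small_pair, tumor_store):
        truth = small_pair["tumor"].truth
        for sv in truth.sv_calls:
            s = sv_specific_barcodes(sv, tumor_store, w=100_000,
                                     mean_molecule_length=45_000)
            spanning = truth.spanning_barcodes(sv.sv_id, min_overhang=2_000)
            assert len(spanning & s) >= 0.9 * len(spanning)
            assert len(s - truth.spanning_barcodes(sv.sv_id)) <= max(5, 0.3 * len(s))

    def test_normal_sample_yields_background_level_set(self, small_pair, normal_store):
        truth = small_pair["tumor"].truth
        _counts, threshold = background_rate(
            normal_store, w=100_000, n_samples=100, seed=0,
            mean_molecule_length=45_000,
        )
        for sv in truth.sv_calls:
            s_norm = sv_specific_barcodes(sv, normal_store, w=100_000,
                                          mean_molecule_length=45_000)
            assert len(s_norm) <= threshold + 2


class TestBackgroundRate:
    def test_median_zero_on_germline_library(self, normal_store):
        counts, _ = background_rate(normal_store, w=100_000, n_samples=100,
                                    seed=1, mean_molecule_length=45_000)
        assert np.median(counts) == 0

    def test_zero_samples_rejected(self, normal_store):
        with pytest.raises(ValueError):
            background_rate(normal_store, n_samples=0)

    def test_threshold_monotone_in_alpha(self, normal_store):
        _, t_strict = background_rate(normal_store, n_samples=100, seed=2,
                                      mean_molecule_length=45_000, alpha=0.01)
        _, t_loose = background_rate(normal_store, n_samples=100, seed=2,
                                     mean_molecule_length=45_000, alpha=0.2)
        assert t_strict >= t_loose


class TestLinkSvs:
    def test_shared_set_is_intersection(self):
        c, verdict = link_svs({"A", "B", "C"}, {"B", "C", "D"}, min_shared=2)
        assert c == {"B", "C"} and verdict == "cis_molecule"

    def test_identical_sets_link_fully(self):
        s = frozenset("ABCDE")
        c, verdict = link_svs(s, s)
        assert c == s and verdict == "cis_molecule"

    def test_single_shared_molecule_is_weak(self):
        _, verdict = link_svs({"A"}, {"A", "B"}, min_shared=2)
        assert verdict == "no_molecule_link"


class TestAlleleSupportSets:
    def test_tumor_barcodes_routed_by_normal_orientation(self):
        normal = [variant(50, hap_of_alt=1)]
        tumor = [variant(50, hap_of_alt=0, bc_alt={"A", "B"}, bc_ref={"C"})]
        sv = SVCall("s", "chr1", 0, "chr1", 1_000_000, SVClass.DEL)
        sets = allele_support_sets(sv, normal, tumor, w=1_000)
        h1, h2 = sets["1"]
        assert h1 == {"A", "B"} and h2 == {"C"}

    def test_phase_sets_are_not_merged(self):
        normal = [variant(50, 1, phase_set="1"),
                  variant(1_000_050, 2, phase_set="2")]
        tumor = [variant(50, 1, bc_alt={"A"}, phase_set="1"),
                 variant(1_000_050, 2, bc_alt={"B"}, phase_set="2")]
        sv = SVCall("s", "chr1", 0, "chr1", 1_000_000, SVClass.DEL)
        sets = allele_support_sets(sv, normal, tumor, w=1_000)
        assert set(sets) == {"1", "2"}
        assert sets["1"][0] == {"A"}
        assert sets["2"][1] == {"B"}  # alt on hap2 routes to H2

    def test_unphased_normal_records_excluded(self):
        normal = [variant(50, hap_of_alt=0)]
        tumor = [variant(50, 0, bc_alt={"A"})]
        sv = SVCall("s", "chr1", 0, "chr1", 1_000_000, SVClass.DEL)
        assert allele_support_sets(sv, normal, tumor, w=1_000) == {}

    def test_recovers_truth_haplotype_barcodes(self, small_pair):
        """H1 holds nearly all truth hap-1 molecule barcodes near the SV."""
        tumor = small_pair["tumor"]
        truth = tumor.truth
        sv = truth.sv_calls[0]
        sets = allele_support_sets(sv, small_pair["normal"].variants,
                                   tumor.variants, w=100_000)
        (h1, _h2), = sets.values()
        mol = truth.molecules
        windows = [(sv.chrom1, sv.x - 50_000, sv.x + 50_000),
                   (sv.chrom2, sv.y - 50_000, sv.y + 50_000)]
        snv_pos = truth.snvs[
            truth.snvs.apply(
                lambda r: any(c == r.chrom and s <= r.pos < e for c, s, e in windows),
                axis=1,
            )
        ]["pos"].to_numpy()
        expected = set()
        for _, m in mol[(mol["haplotype"] == 1) & (mol["n_reads"] > 0)].iterrows():
            g = truth.genomes[m["genome"]]
            for c, s, e, _st in g.map_interval(int(m["d_start"]), int(m["d_end"])):
                if ((snv_pos >= s) & (snv_pos < e)).any():
                    expected.add(m["barcode"])
                    break
        assert len(expected & set(h1)) >= 0.99 * len(expected)


class TestAssignHaplotype:
    @pytest.mark.parametrize(
        "r1,r2,call,frac",
        [
            (92, 0, "hap1", 1.0),       # unanimous support
            (200, 1, "hap1", 200 / 201),
            (37, 21, "mixed", 37 / 58),  # both haplotypes affected
            (3, 1, "unassigned", 0.75),  # below the support floor
            (0, 80, "hap2", 1.0),
        ],
    )
    def test_call_patterns(self, r1, r2, call, frac):
        s = {f"m{i}" for i in range(r1 + r2 + 10)}
        h1 = {f"m{i}" for i in range(r1)}
        h2 = {f"m{i}" for i in range(r1, r1 + r2)}
        sup = assign_haplotype(s, h1, h2)
        assert (sup.r1, sup.r2, sup.call) == (r1, r2, call)
        assert sup.fraction_major == pytest.approx(frac)
        assert sup.n_assignable <= sup.n_total_sv_molecules

    def test_empty_s_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            assign_haplotype(set(), {"A"}, {"B"})

    def test_barcodes_in_both_supports_are_unassignable(self):
        s = {"A", "B", "C", "D", "E", "F"}
        h1 = {"A", "B", "C", "D", "E", "F"}
        h2 = {"A"}  # droplet collision: A supports both haplotypes
        sup = assign_haplotype(s, h1, h2)
        assert sup.r1 == 5 and sup.r2 == 0

    def test_r1_r2_disjoint_under_zero_misassignment(self, small_del):
        tumor, normal = small_del["tumor"], small_del["normal"]
        (sv,) = tumor.truth.sv_calls
        s = sv_specific_barcodes(sv, ReadStore(tumor.reads), w=100_000,
                                 mean_molecule_length=45_000)
        sets = allele_support_sets(sv, normal.variants, tumor.variants, w=100_000)
        for h1, h2 in sets.values():
            ambiguous = set(h1) & set(h2)
            r1 = (set(h1) - ambiguous) & set(s)
            r2 = (set(h2) - ambiguous) & set(s)
            assert not (r1 & r2)
            # any ambiguity must be explained by droplet co-occupancy or
            # the 0.5% SNV misassignment, both rare
            assert len(ambiguous & set(s)) <= max(3, 0.1 * len(s))


class TestPhaseSvPair:
    SV_I = SVCall("i", "chr1", 0, "chr1", 5_000_000, SVClass.DEL)
    SV_J = SVCall("j", "chr1", 20_000_000, "chr1", 26_000_000, SVClass.DUP)

    def support(self, call, phase_set="1"):
        from bxsv.phasing import HaplotypeSupport

        return {
            phase_set: HaplotypeSupport(
                sv_id="x", phase_set=phase_set, n_total_sv_molecules=20,
                n_assignable=20, r1=20 if call == "hap1" else 0,
                r2=0 if call == "hap1" else 20, call=call, fraction_major=1.0,
            )
        }

    def test_shared_molecules_decide_cis(self):
        v = phase_sv_pair(self.SV_I, self.SV_J, {"A", "B", "C"}, {"B", "C"},
                          None, None)
        assert v.relationship == "cis_molecule" and v.shared_molecules == 2

    def test_same_haplotype_same_block_is_cis(self):
        v = phase_sv_pair(self.SV_I, self.SV_J, {"A"}, {"B"},
                          self.support("hap1"), self.support("hap1"))
        assert v.relationship == "cis_haplotype"

    def test_different_haplotypes_same_block_is_trans(self):
        v = phase_sv_pair(self.SV_I, self.SV_J, {"A"}, {"B"},
                          self.support("hap1"), self.support("hap2"))
        assert v.relationship == "trans"

    def test_different_phase_blocks_never_compared(self):
        v = phase_sv_pair(self.SV_I, self.SV_J, {"A"}, {"B"},
                          self.support("hap1", "1"), self.support("hap1", "2"))
        assert v.relationship == "unresolved"

    def test_mixed_call_does_not_phase(self):
        v = phase_sv_pair(self.SV_I, self.SV_J, {"A"}, {"B"},
                          self.support("mixed"), self.support("hap1"))
        assert v.relationship == "unresolved"


class TestPipeline:
    def test_definitional_subset_invariants(self, small_pair, tumor_store,
                                            normal_store):
        tumor, normal = small_pair["tumor"], small_pair["normal"]
        table, evidence = sv_phasing_table(
            tumor.truth.sv_calls, tumor_store, normal_store,
            normal.variants, tumor.variants, mean_molecule_length=45_000,
        )
        for sv in tumor.truth.sv_calls:
            ev = evidence[sv.sv_id]
            assert ev["S"] <= ev["B1"] and ev["S"] <= ev["B2"]
        ids = list(evidence)
        c, _ = link_svs(evidence[ids[0]]["S"], evidence[ids[1]]["S"])
        assert c <= evidence[ids[0]]["S"] and c <= evidence[ids[1]]["S"]

    def test_trans_configuration_recovered(self, small_pair, tumor_store,
                                           normal_store):
        tumor, normal = small_pair["tumor"], small_pair["normal"]
        table, evidence = sv_phasing_table(
            tumor.truth.sv_calls, tumor_store, normal_store,
            normal.variants, tumor.variants, mean_molecule_length=45_000,
        )
        calls = dict(zip(table["sv_id"], table["call"]))
        assert calls["DUP1"] == "hap1" and calls["INV1"] == "hap2"
        (verdict,) = phase_all_pairs(tumor.truth.sv_calls, evidence)
        assert verdict.relationship == "trans"

    def test_left_met_published_pattern(self, left_met):
        """Five hap-1 events; the inversion locus shows mixed support;
        the adjacent duplication and deletion share molecules (cis)."""
        tumor, normal = left_met["tumor"], left_met["normal"]
        table, evidence = sv_phasing_table(
            tumor.truth.sv_calls, tumor.reads, normal.reads,
            normal.variants, tumor.variants, mean_molecule_length=45_000,
        )
        calls = dict(zip(table["sv_id"], table["call"]))
        assert calls["DUP1"] == "hap1" and calls["DUP2"] == "hap1"
        assert calls["DEL1"] == "hap1" and calls["DEL2"] == "hap1"
        assert calls["INV1"] == "mixed"
        verdicts = {v.sv_pair: v for v in phase_all_pairs(tumor.truth.sv_calls, evidence)}
        assert verdicts[("DUP2", "DEL1")].relationship == "cis_molecule"
        assert verdicts[("DUP2", "DEL1")].shared_molecules >= 2

    def test_right_met_all_events_in_cis(self, right_met):
        tumor, normal = right_met["tumor"], right_met["normal"]
        table, evidence = sv_phasing_table(
            tumor.truth.sv_calls, tumor.reads, normal.reads,
            normal.variants, tumor.variants, mean_molecule_length=45_000,
        )
        assert (table["call"] == "hap1").all()
        assert (table["fraction_major"] >= 0.9).all()
        for v in phase_all_pairs(tumor.truth.sv_calls, evidence):
            assert v.relationship in ("cis_haplotype", "cis_molecule")
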