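"""Segment-list event algebra: conservation, junction motifs, truth oracles."""

import numpy as np
import pytest

from taqing.dna import revcomp
from taqing.errors import BreakpointError, EventConflictError, PlacementError
from taqing.genome_forge import GenomeSpec, generate_reference
from taqing.taq_simulator import (EventSpec, MutantGenome, apply_event,
                                  apply_events, compare_karyotypes,
                                  expected_taqi_spacing, realize_sequence,
                                  realized_length, sample_events, taqi_sites,
                                  truth_adjacencies, truth_copy_number,
                                  truth_dosage, virtual_pfge)


def _total_bp(genome):
    return sum(realized_length(genome, m) for m in genome.molecules)


def _site(genome, chrom, lo, hi, index=0):
    sites = taqi_sites(genome.reference.reference[chrom])
    inside = sites[(sites >= lo) & (sites < hi)]
    return int(inside[index])


@pytest.fixture(scope="module")
def wt():
    spec = GenomeSpec(n_chromosomes=2, chrom_lengths=(40_000, 40_000), seed=11)
    return MutantGenome.wild_type(generate_reference(spec))


class TestTaqiSites:
    def test_hand_case(self):
        assert list(taqi_sites("TTCGAA")) == [1]

    def test_no_site(self):
        assert list(taqi_sites("A" * 50)) == []

    def test_overlapping_scan_matches_brute_force(self):
        rng = np.random.default_rng(0)
        seq = "".join(rng.choice(list("ACGT"), size=5_000))
        brute = [i for i in range(len(seq) - 3) if seq[i:i + 4] == "TCGA"]
        assert list(taqi_sites(seq)) == brute

    def test_expected_spacing_uniform(self):
        assert expected_taqi_spacing() == pytest.approx(256.0)


class TestApplyEvent:
    def test_reciprocal_tl_conserves_bp_two_adjacencies(self, wt):
        pa = _site(wt, "chr1", 20_000, 30_000)
        pb = _site(wt, "chr2", 20_000, 30_000)
        ev = EventSpec("tl", "TL", "chr1_hap1", pa, "chr2_hap2", pb)
        mut = apply_event(wt, ev)
        assert _total_bp(mut) == _total_bp(wt)
        assert len(truth_adjacencies(mut)) == 2

    def test_nonreciprocal_tl_discards_tail(self, wt):
        pa = _site(wt, "chr1", 20_000, 30_000)
        pb = _site(wt, "chr2", 20_000, 30_000)
        ev = EventSpec("tl", "TL", "chr1_hap1", pa, "chr2_hap2", pb,
                       reciprocal=False)
        mut = apply_event(wt, ev)
        # the chr1 tail is orphaned: total shrinks by its (realized) length
        assert _total_bp(mut) < _total_bp(wt)
        assert len(truth_adjacencies(mut)) == 1

    def test_deletion_shrinks_and_junction_regenerates_tcga(self, wt):
        p = _site(wt, "chr1", 10_000, 15_000)
        q = _site(wt, "chr1", 20_000, 25_000)
        ev = EventSpec("del", "DEL", "chr1_hap1", p, pos_b=q)
        mut = apply_event(wt, ev)
        assert _total_bp(wt) - _total_bp(mut) == q - p
        mol = mut.molecule("chr1_hap1")
        seq = realize_sequence(mut, mol)
        joint = mol.segments[0].end  # realized position of the junction
        assert seq[joint - 1:joint + 3] == "TCGA"

    def test_bir_shifts_dosage_not_copy_number(self, wt):
        p = _site(wt, "chr1", 25_000, 30_000)
        ev = EventSpec("bir", "BIR", "chr1_hap1", p,
                       partner_molecule="chr1_hap3")
        mut = apply_event(wt, ev)
        ref = wt.reference
        for v in ref.variants_on("chr1"):
            if v.pos <= p - 1 or v.pos >= 39_000:
                continue
            assert truth_copy_number(mut, "chr1", v.pos) == 3
            assert truth_dosage(mut, "chr1", v.pos, 3) == 2
            assert truth_dosage(mut, "chr1", v.pos, 1) == 0
        # no novel adjacency: the joint is reference-contiguous
        assert truth_adjacencies(mut) == set()

    def test_gcv_copy_neutral_inside_tract_only(self, wt):
        p = _site(wt, "chr2", 10_000, 12_000)
        q = _site(wt, "chr2", 16_000, 18_000)
        ev = EventSpec("gcv", "GCV", "chr2_hap3", p, pos_b=q,
                       partner_molecule="chr2_hap1")
        mut = apply_event(wt, ev)
        for pos in range(5_000, 35_000, 1_000):
            assert truth_copy_number(mut, "chr2", pos) == 3
        assert truth_dosage(mut, "chr2", (p + q) // 2, 3) == 0
        assert truth_dosage(mut, "chr2", p - 100, 3) == 1
        assert truth_dosage(mut, "chr2", q + 100, 3) == 1

    def test_aneuploidy_whole_chromosome_cn4(self, wt):
        ev = EventSpec("an", "ANEUPLOIDY", "chr2_hap2", 0)
        mut = apply_event(wt, ev)
        for pos in (0, 20_000, 39_999):
            assert truth_copy_number(mut, "chr2", pos) == 4
        assert truth_copy_number(mut, "chr1", 20_000) == 3

    def test_partial_dup_telomere_capped_molecule(self, wt):
        p = _site(wt, "chr1", 30_000, 35_000)
        ev = EventSpec("pd", "PARTIAL_DUP", "chr1_hap2", p,
                       partner_molecule="chr1_hap2")
        mut = apply_event(wt, ev)
        assert truth_copy_number(mut, "chr1", p + 100) == 4
        assert truth_copy_number(mut, "chr1", p - 100) == 3
        new = mut.molecule("dup_pd")
        seq = realize_sequence(mut, new)
        unit = wt.reference.telomere_unit
        assert seq.startswith(revcomp(unit))
        assert seq.endswith(unit)

    def test_non_taqi_breakpoint_rejected(self, wt):
        pos = 20_000
        while wt.reference.reference["chr1"][pos:pos + 4] == "TCGA":
            pos += 1
        ev = EventSpec("bad", "DEL", "chr1_hap1", pos, pos_b=pos + 5_000)
        with pytest.raises(BreakpointError):
            apply_event(wt, ev)

    def test_overlapping_events_conflict(self, wt):
        p = _site(wt, "chr1", 10_000, 15_000)
        q = _site(wt, "chr1", 20_000, 25_000)
        r = _site(wt, "chr1", 15_000, 20_000)
        first = EventSpec("d1", "DEL", "chr1_hap1", p, pos_b=q)
        second = EventSpec("d2", "DEL", "chr1_hap1", r, pos_b=q)
        mut = apply_event(wt, first)
        with pytest.raises(EventConflictError):
            apply_event(mut, second)

    def test_order_independence_of_disjoint_events(self, wt):
        p = _site(wt, "chr1", 10_000, 12_000)
        q = _site(wt, "chr1", 15_000, 17_000)
        r = _site(wt, "chr2", 10_000, 12_000)
        events = [
            EventSpec("a", "DEL", "chr1_hap1", p, pos_b=q),
            EventSpec("b", "GCV", "chr2_hap3", r,
                      pos_b=_site(wt, "chr2", 15_000, 17_000),
                      partner_molecule="chr2_hap1"),
            EventSpec("c", "ANEUPLOIDY", "chr2_hap2", 0),
        ]
        m1 = apply_events(wt, events)
        m2 = apply_events(wt, events[::-1])
        segs1 = sorted(repr(m.segments) for m in m1.molecules)
        segs2 = sorted(repr(m.segments) for m in m2.molecules)
        assert segs1 == segs2


class TestRealization:
    def test_single_segment_equals_haplotype(self, wt):
        mol = wt.molecule("chr1_hap2")
        assert realize_sequence(wt, mol) == \
            wt.reference.haplotype_sequence("chr1", 2)

    def test_minus_strand_reverse_complement(self, wt):
        from taqing.taq_simulator import Molecule, Segment
        seg = Segment("chr1", 1, 1_000, 2_000, strand="-")
        mol = Molecule("m", [seg])
        expected = revcomp(wt.reference.reference["chr1"][1_000:2_000])
        assert realize_sequence(wt, mol) == expected


class TestVirtualPfge:
    def test_wild_type_bands(self, wt):
        profile = virtual_pfge(wt)
        assert len(profile.band_lengths) == 6  # 2 chroms x 3 haplotypes
        assert profile.band_lengths == sorted(profile.band_lengths,
                                              reverse=True)

    def test_deletion_creates_shorter_band(self, wt):
        p = _site(wt, "chr1", 10_000, 11_000)
        q = _site(wt, "chr1", 20_000, 21_000)
        mut = apply_event(wt, EventSpec("d", "DEL", "chr1_hap1", p, pos_b=q))
        diff = compare_karyotypes(virtual_pfge(mut), virtual_pfge(wt),
                                  resolution=0.02)
        assert len(diff["gained"]) == 1
        assert diff["gained"][0] < 40_000 - (q - p) + 500

    def test_reciprocal_tl_band_change_iff_tails_differ(self, wt):
        pa = _site(wt, "chr1", 20_000, 25_000)
        pb = _site(wt, "chr2", 10_000, 15_000)
        mut = apply_event(wt, EventSpec("t", "TL", "chr1_hap1", pa,
                                        "chr2_hap1", pb))
        diff = compare_karyotypes(virtual_pfge(mut), virtual_pfge(wt))
        assert len(diff["gained"]) == 2  # tails differ by >= 5 kb


class TestSampleEvents:
    def test_zero_counts_empty(self, wt):
        assert sample_events(wt, {}, seed=1) == []

    def test_seed_determinism(self, wt):
        counts = {"DEL": 1, "GCV": 1}
        a = sample_events(wt, counts, seed=5, margin=5_000,
                          size_ranges={"DEL": (3_000, 8_000)})
        b = sample_events(wt, counts, seed=5, margin=5_000,
                          size_ranges={"DEL": (3_000, 8_000)})
        assert a == b

    def test_sampled_deletions_at_taqi_sites_within_range(self):
        spec = GenomeSpec(n_chromosomes=4, chrom_lengths=(150_000,) * 4,
                          seed=21)
        wt = MutantGenome.wild_type(generate_reference(spec))
        events = []
        for s in range(12):
            events.extend(sample_events(
                wt, {"DEL": 2}, seed=s, size_ranges={"DEL": (10_000, 70_000)},
                margin=5_000))
        assert len(events) == 24
        for ev in events:
            chrom = ev.target_molecule.split("_")[0]
            sites = set(taqi_sites(wt.reference.reference[chrom]).tolist())
            assert ev.pos_a in sites and ev.pos_b in sites
            assert 10_000 <= ev.pos_b - ev.pos_a <= 70_000

    def test_impossible_placement_raises(self, wt):
        with pytest.raises(PlacementError):
            sample_events(wt, {"DEL": 50},
                          size_ranges={"DEL": (30_000, 39_000)})
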