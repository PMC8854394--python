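"""Breakend clustering, pairing geometry, motif annotation, filtering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from taqing.errors import CoordinateError
from taqing.evidence_layer import ClippedReadRecord
from taqing.junction_caller import (JunctionCall, annotate_taqi_motif,
                                    call_junctions, cluster_breakends,
                                    filter_calls, pair_and_classify)


def _clip(ca, pa, sa, cb=None, pb=None, sb=None):
    be_b = (cb, pb, sb) if cb is not None else None
    return ClippedReadRecord((ca, pa, sa), be_b)


class TestClusterBreakends:
    def test_identical_positions_one_cluster(self):
        clips = [_clip("chr1", 500, "right") for _ in range(5)]
        clusters, _ = cluster_breakends(clips, max_gap=10, min_support=3)
        (c,) = clusters
        assert (c.chromosome, c.pos, c.side, c.support) == \
            ("chr1", 500, "right", 5)

    def test_gap_contract_splits(self):
        clips = [_clip("chr1", 500, "right"), _clip("chr1", 1_500, "right")]
        clusters, _ = cluster_breakends(clips, max_gap=10, min_support=1)
        assert len(clusters) == 2
        clusters, _ = cluster_breakends(clips, max_gap=10, min_support=3)
        assert clusters == []

    def test_sides_cluster_separately(self):
        clips = [_clip("chr1", 500, "right"), _clip("chr1", 500, "left"),
                 _clip("chr1", 500, "right"), _clip("chr1", 500, "left")]
        clusters, _ = cluster_breakends(clips, max_gap=10, min_support=2)
        assert {c.side for c in clusters} == {"left", "right"}

    def test_jittered_clips_recover_two_breakends(self):
        rng = np.random.default_rng(12)
        truth = [("chr2", 10_000, "right"), ("chr2", 50_000, "left")]
        clips = []
        for _ in range(100):
            for chrom, pos, side in truth:
                clips.append(_clip(chrom, pos + int(rng.integers(-4, 5)),
                                   side))
        clusters, _ = cluster_breakends(clips, max_gap=10, min_support=3)
        assert len(clusters) == 2
        for cl, (chrom, pos, side) in zip(clusters, truth):
            assert abs(cl.pos - pos) <= 10


class TestPairAndClassify:
    def _paired_clips(self, be_a, be_b, n=5):
        return [ClippedReadRecord(be_a, be_b) for _ in range(n)]

    def test_translocation_geometry(self):
        clips = self._paired_clips(("chr1", 1_000, "right"),
                                   ("chr4", 9_000, "left"))
        calls = pair_and_classify([], clips)
        (call,) = calls
        assert call.klass == "translocation-type"
        assert call.support == 5

    def test_deletion_geometry(self):
        clips = self._paired_clips(("chr3", 10_000, "right"),
                                   ("chr3", 77_000, "left"))
        (call,) = pair_and_classify([], clips, min_size=1_000)
        assert call.klass == "deletion-type"

    def test_inversion_and_duplication_geometry(self):
        inv = self._paired_clips(("chr1", 10_000, "right"),
                                 ("chr1", 40_000, "right"))
        (call,) = pair_and_classify([], inv)
        assert call.klass == "inversion-type"
        dup = self._paired_clips(("chr1", 40_000, "right"),
                                 ("chr1", 10_000, "left"))
        (call,) = pair_and_classify([], dup)
        assert call.klass == "duplication-type"

    def test_unpaired_cluster_imprecise(self):
        clips = [_clip("chr1", 700, "left") for _ in range(4)]
        (call,) = pair_and_classify([], clips)
        assert call.imprecise and call.breakend_b is None

    @settings(derandomize=True, max_examples=200)
    @given(chrom_a=st.sampled_from(["chr1", "chr2"]),
           chrom_b=st.sampled_from(["chr1", "chr2"]),
           pos_a=st.integers(0, 10**6), pos_b=st.integers(0, 10**6),
           side_a=st.sampled_from(["left", "right"]),
           side_b=st.sampled_from(["left", "right"]))
    def test_classification_pure_function_of_geometry(
            self, chrom_a, chrom_b, pos_a, pos_b, side_a, side_b):
        from taqing.junction_caller import _classify
        be_a, be_b = (chrom_a, pos_a, side_a), (chrom_b, pos_b, side_b)
        klass = _classify(be_a, be_b, min_size=1_000)
        if chrom_a != chrom_b:
            assert klass == "translocation-type"
        elif side_a == side_b:
            assert klass == "inversion-type"
        else:
            right = pos_a if side_a == "right" else pos_b
            left = pos_b if side_a == "right" else pos_a
            if right <= left:
                assert klass in ("deletion-type", "small-deletion-type")
                assert (klass == "deletion-type") == (left - right >= 1_000)
            else:
                assert klass == "duplication-type"
        # invariant under argument swap
        assert _classify(be_b, be_a, 1_000) == klass


class TestMotifAnnotation:
    REF = {"chrM": "A" * 100 + "TCGA" + "A" * 100}

    def _call(self, pos_a, pos_b):
        return JunctionCall(("chrM", pos_a, "right"), ("chrM", pos_b, "left"),
                            support=5, klass="deletion-type")

    def test_motif_at_cut_site(self):
        # the religated junction breakend sits between T and CGA (pos 101)
        call = annotate_taqi_motif(self._call(101, 101), self.REF, window=5)
        assert call.motif_a and call.motif_b

    def test_no_motif_in_clean_region(self):
        call = annotate_taqi_motif(self._call(20, 50), self.REF, window=5)
        assert not call.motif_a and not call.motif_b

    def test_out_of_bounds_breakend(self):
        with pytest.raises(CoordinateError):
            annotate_taqi_motif(self._call(5_000, 10), self.REF)


class TestFilterCalls:
    def _calls(self):
        mk = lambda motif, support: JunctionCall(
            ("chr1", 100, "right"), ("chr1", 5_000, "left"), support,
            "deletion-type", motif_a=motif, motif_b=motif)
        return [mk(True, 10), mk(True, 8), mk(False, 12), mk(True, 2)]

    def test_motif_mode_any_drops_decoy(self):
        calls = self._calls()
        kept = filter_calls(calls, require_motif="any", min_support=1)
        assert len(kept) == 3 and all(c.motif_a for c in kept)

    def test_all_motif_calls_identity(self):
        calls = [c for c in self._calls() if c.motif_a]
        assert filter_calls(calls, require_motif="any") == calls

    def test_min_support_above_max_empties(self):
        assert filter_calls(self._calls(), None, min_support=99) == []


class TestEndToEndOnSimulation:
    def test_perfect_recovery_zero_jitter(self, demo_result):
        """On the default simulation, junction calls hit every truth
        adjacency exactly, with no extra calls."""
        from taqing.taq_simulator import truth_adjacencies
        truth = truth_adjacencies(demo_result.mutant)
        calls = [c for c in demo_result.junctions if not c.imprecise]
        called = {tuple(sorted((c.breakend_a, c.breakend_b))) for c in calls}
        assert called == truth

    def test_jitter_bounded_breakpoint_error(self, demo_result):
        from taqing.evidence_layer import simulate_evidence
        from taqing.taq_simulator import truth_adjacencies
        r = demo_result
        ev = simulate_evidence(r.wild_type, r.mutant, depth_per_copy=30,
                               jitter=4, seed=77)
        calls = call_junctions(ev.clips, r.reference.reference, max_gap=10,
                               min_support=3)
        truth_pos = {be: be[1]
                     for pair in truth_adjacencies(r.mutant) for be in pair}
        errors = []
        for c in calls:
            if c.imprecise:
                continue
            for be in (c.breakend_a, c.breakend_b):
                nearest = min(abs(be[1] - p) for p in truth_pos.values())
                errors.append(nearest)
        assert errors and float(np.median(errors)) <= 4
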