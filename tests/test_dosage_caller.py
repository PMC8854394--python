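"""Ratio normalization, CN segmentation, dosage classes, tract calling."""

import numpy as np
import pytest
from scipy.stats import binom, poisson

from taqing.dosage_caller import (CNSegment, call_cn_events, call_tracts,
                                  classify_site_dosage, classify_sites,
                                  classify_tract, normalize_ratio, segment_cn)
from taqing.errors import InputError
from taqing.evidence_layer import AlleleObservation, CoverageTrack


def _track(depths, window=1_000):
    lengths = {c: len(d) * window for c, d in depths.items()}
    return CoverageTrack(window=window,
                         depths={c: np.asarray(d, float)
                                 for c, d in depths.items()},
                         chrom_lengths=lengths)


class TestNormalizeRatio:
    def test_identical_tracks_all_ones(self):
        t = _track({"chr1": [30.0] * 50})
        ratio = normalize_ratio(t, t)
        assert np.allclose(ratio.ratios["chr1"], 1.0)

    def test_global_depth_difference_normalized_away(self):
        wt = _track({"chr1": [30.0] * 50})
        mut = _track({"chr1": [60.0] * 50})
        ratio = normalize_ratio(mut, wt)
        assert np.allclose(ratio.ratios["chr1"], 1.0)
        assert ratio.norm_factor == pytest.approx(2.0)

    def test_heterozygous_deletion_ratio_two_thirds(self):
        rng = np.random.default_rng(8)
        n, lam = 400, 3_000  # reads per window at CN3
        wt_d = rng.poisson(lam, n).astype(float)
        mut_d = rng.poisson(lam, n).astype(float)
        mut_d[150:250] = rng.poisson(lam * 2 / 3, 100)
        ratio = normalize_ratio(_track({"chr1": mut_d}), _track({"chr1": wt_d}))
        mean = float(np.mean(ratio.ratios["chr1"][150:250]))
        se = np.sqrt(2 / lam / 100)  # CLT bound from Poisson variance
        assert abs(mean - 2 / 3) < 5 * se

    def test_masked_windows_missing(self):
        t = _track({"chr1": [30.0] * 50})
        ratio = normalize_ratio(t, t, masked_regions=[("chr1", 10_000, 12_000)])
        assert np.isnan(ratio.ratios["chr1"][10:12]).all()

    def test_grid_mismatch_rejected(self):
        a = _track({"chr1": [30.0] * 50})
        b = _track({"chr1": [30.0] * 40})
        with pytest.raises(InputError):
            normalize_ratio(a, b)


class TestSegmentCN:
    def test_flat_ratio_single_cn3_segment(self):
        t = _track({"chr1": [30.0] * 60})
        segs = segment_cn(normalize_ratio(t, t), ploidy=3)
        assert [(s.chromosome, s.start, s.end, s.cn) for s in segs] == \
            [("chr1", 0, 60_000, 3)]

    def test_whole_chromosome_four_thirds_is_cn4(self):
        # median normalization needs a copy-neutral majority of windows
        wt = _track({c: [30.0] * 60 for c in ("chr1", "chr2", "chr3")})
        mut = _track({"chr1": [40.0] * 60, "chr2": [30.0] * 60,
                      "chr3": [30.0] * 60})
        segs = segment_cn(normalize_ratio(mut, wt), ploidy=3)
        by_chrom = {s.chromosome: s.cn for s in segs}
        assert by_chrom == {"chr1": 4, "chr2": 3, "chr3": 3}

    def test_short_runs_absorbed_by_nearest_ratio(self):
        wt = np.full(60, 30.0)
        mut = np.full(60, 30.0)
        mut[25] = 24.0  # one-window dip, below min_windows
        segs = segment_cn(normalize_ratio(_track({"c": mut}), _track({"c": wt})),
                          ploidy=3, min_windows=2)
        assert [s.cn for s in segs] == [3]

    def test_noise_free_deletion_matches_truth(self, demo_result):
        """segment_cn on exact truth ratios equals truth_copy_number."""
        from taqing.evidence_layer import _window_mean_cn
        from taqing.taq_simulator import cn_profile, truth_copy_number
        r = demo_result
        window = 5_000
        wt_depths, mut_depths, lengths = {}, {}, {}
        for chrom in r.reference.chromosomes:
            L = len(r.reference.reference[chrom])
            breaks, cn = cn_profile(r.mutant, chrom)
            mut_depths[chrom] = 10.0 * _window_mean_cn(breaks, cn, window, L)
            wt_depths[chrom] = np.full(len(mut_depths[chrom]), 30.0)
            lengths[chrom] = L
        mk = lambda d: CoverageTrack(window, d, dict(lengths))
        segs = segment_cn(normalize_ratio(mk(mut_depths), mk(wt_depths)),
                          ploidy=3, min_windows=2)
        for s in segs:
            for pos in range(s.start + window, s.end - window,
                             max(window, (s.end - s.start) // 7)):
                assert truth_copy_number(r.mutant, s.chromosome, pos) == s.cn


class TestCallCNEvents:
    LENGTHS = {"chr1": 100_000, "chr2": 100_000}

    def test_all_neutral_empty(self):
        segs = [CNSegment("chr1", 0, 100_000, 3, 1.0)]
        assert call_cn_events(segs, self.LENGTHS) == []

    def test_whole_chromosome_gain_is_aneuploidy(self):
        segs = [CNSegment("chr1", 0, 100_000, 4, 4 / 3)]
        (ev,) = call_cn_events(segs, self.LENGTHS)
        assert ev.kind == "Aneuploidy" and "Whole chromosome" in ev.note

    def test_terminal_gain_is_partial_duplication(self):
        segs = [CNSegment("chr1", 0, 60_000, 3, 1.0),
                CNSegment("chr1", 60_000, 100_000, 4, 4 / 3)]
        events = call_cn_events(segs, self.LENGTHS)
        assert [e.kind for e in events] == ["Partial duplication"]

    def test_interstitial_loss_is_deletion(self):
        segs = [CNSegment("chr1", 30_000, 50_000, 2, 2 / 3)]
        (ev,) = call_cn_events(segs, self.LENGTHS)
        assert ev.kind == "Deletion"


class TestClassifySiteDosage:
    def _obs(self, alt_wt, n_wt, alt_mut, n_mut):
        return AlleleObservation("chr1", 100, n_wt - alt_wt, alt_wt,
                                 n_mut - alt_mut, alt_mut)

    def test_one_to_two_thirds_shift(self):
        site = classify_site_dosage(self._obs(10, 30, 20, 30), ploidy=3,
                                    cn_local=3)
        assert (site.wt_class, site.mut_class, site.shifted) == (1, 2, True)
        # hand check: the binomial log-likelihood really prefers 2/3 at 20/30
        e = 0.01
        p1, p2 = (1 / 3) * (1 - e) + (2 / 3) * e, (2 / 3) * (1 - e) + (1 / 3) * e
        assert binom.logpmf(20, 30, p2) > binom.logpmf(20, 30, p1)

    def test_same_class_not_shifted(self):
        site = classify_site_dosage(self._obs(10, 30, 11, 30))
        assert site.mut_class == 1 and not site.shifted

    def test_allele_loss(self):
        site = classify_site_dosage(self._obs(10, 30, 0, 30))
        assert site.mut_class == 0 and site.shifted

    def test_below_min_depth_skipped(self):
        assert classify_site_dosage(self._obs(3, 9, 3, 9)) is None

    def test_error_rate_within_analytic_bound(self):
        """Empirical mutant-class error at depth 30, cn 3, error 0.01 stays
        within the exact enumeration of the ML decision regions."""
        n, ploidy, e = 30, 3, 0.01
        # oracle: exact misclassification mass by enumerating alt counts
        def decision(alt):
            lls = {k: binom.logpmf(alt, n, (k / 3) * (1 - e) + (1 - k / 3) * e)
                   for k in range(4)}
            return max(lls, key=lls.get)

        true_k = 1
        p_true = (true_k / 3) * (1 - e) + (1 - true_k / 3) * e
        bound = sum(binom.pmf(a, n, p_true) for a in range(n + 1)
                    if decision(a) != true_k)
        rng = np.random.default_rng(20)
        n_sim = 4_000
        errors = 0
        for alt in rng.binomial(n, p_true, size=n_sim):
            site = classify_site_dosage(
                self._obs(10, 30, int(alt), 30), margin_threshold=0.0)
            if site.mut_class != true_k:
                errors += 1
        emp = errors / n_sim
        assert emp <= bound + 4 * np.sqrt(bound * (1 - bound) / n_sim)


class TestCallTracts:
    def _sites(self, positions, shifted=True, chrom="chr1"):
        return [type("S", (), {"chromosome": chrom, "pos": p,
                               "shifted": shifted})() for p in positions]

    def test_no_shifted_sites_empty(self):
        assert call_tracts(self._sites(range(0, 10_000, 500),
                                       shifted=False)) == []

    def test_contiguous_run_single_tract(self):
        sites = self._sites(range(100_000, 130_000, 1_000))
        (t,) = call_tracts(sites, max_gap=20_000, min_sites=5)
        assert t == ("chr1", 100_000, 129_000, 30)

    def test_gap_splits_runs(self):
        sites = self._sites(list(range(0, 5_000, 500))
                            + list(range(60_000, 65_000, 500)))
        tracts = call_tracts(sites, max_gap=20_000, min_sites=5)
        assert len(tracts) == 2

    def test_taqi_refined_bounds(self):
        sites = self._sites(range(10_000, 20_000, 500))
        taqi = {"chr1": np.array([9_700, 20_100])}
        (t,) = call_tracts(sites, max_gap=20_000, min_sites=5,
                           taqi_positions=taqi)
        assert (t[1], t[2]) == (9_700, 20_100)

    def test_min_sites_monotone(self, demo_result):
        sites = classify_sites(demo_result.evidence.alleles,
                               demo_result.cn_segments)
        lo = {tuple(t) for t in call_tracts(sites, min_sites=5)}
        hi = {tuple(t[:1]) for t in call_tracts(sites, min_sites=10)}
        assert len(hi) <= len(lo)


class TestClassifyTract:
    CN_NEUTRAL = [CNSegment("chr1", 0, 300_000, 3, 1.0)]

    def test_terminal_copy_neutral_is_bir(self):
        t = classify_tract(("chr1", 250_000, 295_500, 40), self.CN_NEUTRAL,
                           chrom_length=300_000, end_tolerance=10_000)
        assert t.kind == "BIR" and t.reaches_end and t.copy_neutral

    def test_interstitial_copy_neutral_is_gcv(self):
        t = classify_tract(("chr1", 100_000, 105_000, 12), self.CN_NEUTRAL,
                           chrom_length=300_000, end_tolerance=10_000)
        assert t.kind == "GCV" and not t.reaches_end

    def test_tract_in_cn_loss_is_loh_deletion(self):
        segs = [CNSegment("chr1", 95_000, 140_000, 2, 2 / 3)]
        t = classify_tract(("chr1", 100_000, 130_000, 30), segs,
                           chrom_length=300_000)
        assert t.kind == "LOH-deletion" and not t.copy_neutral

    def test_tract_in_cn_gain_deferred(self):
        segs = [CNSegment("chr1", 0, 300_000, 4, 4 / 3)]
        assert classify_tract(("chr1", 50_000, 250_000, 99), segs,
                              chrom_length=300_000) is None

    def test_mask_adjacent_tract_flagged_around_rdna(self):
        t = classify_tract(("chr1", 100_000, 130_000, 30), self.CN_NEUTRAL,
                           chrom_length=300_000,
                           masked_regions=[("chr1", 128_000, 135_000)])
        assert t.imprecise and t.note == "Around rDNA"
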