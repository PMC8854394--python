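"""Copy number from mutant/WT coverage ratio; dosage tracts from SNV ratios.

In a triploid, heterozygous alt-allele fractions sit at 1/3 or 2/3; a
homologous rearrangement (break-induced repair or gene conversion) replaces
one allele by another, shifting the fraction class without changing copy
number, while deletions/duplications/aneuploidy change the mutant/WT depth
ratio.  This module mirrors that logic:

- :func:`normalize_ratio`      median-normalized mutant/WT depth per window
- :func:`segment_cn`           integer copy states by rounding ploidy x ratio
- :func:`call_cn_events`       deletion / aneuploidy / partial-duplication calls
- :func:`classify_site_dosage` per-site binomial ML dosage classes
- :func:`call_tracts`          runs of dosage-shifted sites
- :func:`classify_tract`       BIR vs GCV vs LOH-deletion
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import binom

from .errors import ConfigError, InputError
from .evidence_layer import AlleleObservation, CoverageTrack


@dataclass
class RatioTrack:
    window: int
    ratios: Dict[str, np.ndarray]       # NaN where missing/masked
    chrom_lengths: Dict[str, int]
    norm_factor: float                  # genome-wide median of raw ratios


@dataclass(frozen=True)
class CNSegment:
    chromosome: str
    start: int
    end: int
    cn: int
    mean_ratio: float


@dataclass(frozen=True)
class DosageSite:
    chromosome: str
    pos: int
    wt_class: int       # alt-allele dosage k of ploidy in the WT
    mut_class: int      # dosage k' of the local copy number in the mutant
    cn_local: int
    shifted: bool
    margin: float       # log-likelihood margin of the mutant class


@dataclass(frozen=True)
class TractCall:
    chromosome: str
    start: int
    end: int
    kind: str           # "GCV" | "BIR" | "LOH-deletion"
    n_sites: int
    copy_neutral: bool
    reaches_end: bool
    imprecise: bool = False
    note: str = ""


def normalize_ratio(mut: CoverageTrack, wt: CoverageTrack,
                    masked_regions: Sequence[Tuple[str, int, int]] = ()
                    ) -> RatioTrack:
    """Per-window mut/wt depth ratio, divided by the genome-wide median.

    After median normalization a copy-neutral genome sits at ratio 1
    regardless of the two libraries' absolute depths.  Windows with zero WT
    depth or inside masked repetitive regions are set to NaN.
    """
    if wt.window != mut.window or set(wt.depths) != set(mut.depths):
        raise InputError("WT and mutant coverage tracks must share one grid")
    raw: Dict[str, np.ndarray] = {}
    n_zero = n_tot = 0
    for chrom, wt_d in wt.depths.items():
        mut_d = mut.depths[chrom]
        if len(mut_d) != len(wt_d):
            raise InputError(f"window grid mismatch on {chrom}")
        with np.errstate(divide="ignore", invalid="ignore"):
            r = np.where(wt_d > 0, mut_d / np.maximum(wt_d, 1e-12), np.nan)
        n_zero += int(np.sum(wt_d == 0))
        n_tot += len(wt_d)
        for mc, ms, me in masked_regions:
            if mc == chrom:
                w0, w1 = ms // wt.window, -(-me // wt.window)
                r[w0:w1] = np.nan
        raw[chrom] = r
    if n_tot and n_zero > 0.1 * n_tot:
        raise InputError("WT depth is zero in more than 10% of windows")
    allr = np.concatenate(list(raw.values()))
    med = float(np.nanmedian(allr))
    if not math.isfinite(med) or med <= 0:
        raise InputError("cannot normalize: median raw ratio is not positive")
    return RatioTrack(window=wt.window,
                      ratios={c: r / med for c, r in raw.items()},
                      chrom_lengths=dict(wt.chrom_lengths), norm_factor=med)


def segment_cn(track: RatioTrack, ploidy: int = 3,
               min_windows: int = 2) -> List[CNSegment]:
    """Merge per-window rounded copy states into segments.

    Provisional state = round(ploidy x ratio), clipped to [0, 2 x ploidy];
    adjacent equal states merge; runs shorter than ``min_windows`` are
    absorbed into the flanking state with the nearer mean ratio; missing
    (NaN) windows are bridged when both flanks agree.
    """
    if min_windows < 1:
        raise ConfigError("min_windows must be >= 1")
    segments: List[CNSegment] = []
    for chrom, ratios in track.ratios.items():
        L = track.chrom_lengths[chrom]
        states = np.where(np.isnan(ratios), -1,
                          np.clip(np.round(ploidy * np.nan_to_num(ratios)),
                                  0, 2 * ploidy)).astype(int)
        # runs of (state, start_window, end_window)
        runs: List[List] = []
        for i, s in enumerate(states):
            if runs and runs[-1][0] == s:
                runs[-1][2] = i + 1
            else:
                runs.append([int(s), i, i + 1])
        # bridge missing runs with agreeing flanks
        changed = True
        while changed:
            changed = False
            for k, run in enumerate(runs):
                if run[0] != -1 or not (0 < k < len(runs) - 1):
                    continue
                if runs[k - 1][0] == runs[k + 1][0] != -1:
                    runs[k - 1][2] = runs[k + 1][2]
                    del runs[k:k + 2]
                    changed = True
                    break
        # absorb short runs into the nearest-ratio flank
        def mean_ratio(run) -> float:
            vals = ratios[run[1]:run[2]]
            vals = vals[~np.isnan(vals)]
            return float(np.mean(vals)) if len(vals) else float("nan")

        changed = True
        while changed:
            changed = False
            for k, run in enumerate(runs):
                if run[0] == -1 or run[2] - run[1] >= min_windows:
                    continue
                neighbors = [runs[j] for j in (k - 1, k + 1)
                             if 0 <= j < len(runs) and runs[j][0] != -1]
                if not neighbors:
                    continue
                r = mean_ratio(run)
                target = min(neighbors,
                             key=lambda nb: abs(nb[0] / ploidy - r))
                target[1] = min(target[1], run[1])
                target[2] = max(target[2], run[2])
                del runs[k]
                # re-merge equal adjacent states
                m = 0
                while m < len(runs) - 1:
                    if runs[m][0] == runs[m + 1][0]:
                        runs[m][2] = runs[m + 1][2]
                        del runs[m + 1]
                    else:
                        m += 1
                changed = True
                break
        for state, w0, w1 in runs:
            if state == -1:
                continue
            vals = ratios[w0:w1]
            vals = vals[~np.isnan(vals)]
            segments.append(CNSegment(
                chromosome=chrom, start=w0 * track.window,
                end=min(w1 * track.window, L), cn=int(state),
                mean_ratio=float(np.mean(vals)) if len(vals) else float("nan")))
    return segments


@dataclass(frozen=True)
class CNEvent:
    chromosome: str
    start: int
    end: int
    cn: int
    kind: str    # "Deletion" | "Aneuploidy" | "Partial duplication" |
                 # "Interstitial duplication"
    note: str = ""


def call_cn_events(segments: Sequence[CNSegment],
                   chrom_lengths: Dict[str, int], ploidy: int = 3,
                   arm_fraction: float = 0.10) -> List[CNEvent]:
    """Turn non-neutral CN segments into named events.

    CN below ploidy -> Deletion.  CN above ploidy covering >= 95% of the
    chromosome -> Aneuploidy ("Whole chromosome").  A terminal gained
    segment covering at least ``arm_fraction`` of the chromosome ->
    Partial duplication; other gains -> interstitial duplication.
    """
    events: List[CNEvent] = []
    for seg in segments:
        if seg.cn == ploidy:
            continue
        L = chrom_lengths[seg.chromosome]
        frac = (seg.end - seg.start) / L
        terminal = seg.start == 0 or seg.end >= L
        if seg.cn < ploidy:
            events.append(CNEvent(seg.chromosome, seg.start, seg.end, seg.cn,
                                  "Deletion"))
        elif frac >= 0.95:
            num = seg.chromosome.lstrip("chr")
            events.append(CNEvent(seg.chromosome, seg.start, seg.end, seg.cn,
                                  "Aneuploidy", note=f"Whole chromosome {num}"))
        elif terminal and frac >= arm_fraction:
            events.append(CNEvent(seg.chromosome, seg.start, seg.end, seg.cn,
                                  "Partial duplication"))
        else:
            events.append(CNEvent(seg.chromosome, seg.start, seg.end, seg.cn,
                                  "Interstitial duplication"))
    return events


def _class_loglik(alt: int, n: int, p_class: float, error_rate: float) -> float:
    p = p_class * (1 - error_rate) + (1 - p_class) * error_rate
    return float(binom.logpmf(alt, n, p))


def classify_site_dosage(obs: AlleleObservation, ploidy: int = 3,
                         cn_local: int = 3, error_rate: float = 0.01,
                         min_depth: int = 10, margin_threshold: float = 2.0
                         ) -> Optional[DosageSite]:
    """Maximum-likelihood dosage classes for one het site.

    The WT class is argmax over k in {1..ploidy-1} of the binomial
    log-likelihood of the WT alt count at p = k/ploidy (error-adjusted);
    the mutant class likewise over k' in {0..cn_local}.  ``shifted`` needs
    a changed allele fraction (k'/cn != k/ploidy) plus a log-likelihood
    margin over the runner-up class of at least ``margin_threshold`` nats
    on BOTH samples, so a single borderline count cannot fake a shift.
    Returns None below ``min_depth``.
    """
    n_wt = obs.ref_count_wt + obs.alt_count_wt
    n_mut = obs.ref_count_mut + obs.alt_count_mut
    if n_wt < min_depth or n_mut < min_depth or cn_local < 1:
        return None

    def argmax_margin(ll: Dict[int, float]) -> Tuple[int, float]:
        ranked = sorted(ll, key=ll.get, reverse=True)
        m = (ll[ranked[0]] - ll[ranked[1]]) if len(ranked) > 1 else float("inf")
        return ranked[0], m

    wt_ll = {k: _class_loglik(obs.alt_count_wt, n_wt, k / ploidy, error_rate)
             for k in range(1, ploidy)}
    wt_class, wt_margin = argmax_margin(wt_ll)
    mut_ll = {k: _class_loglik(obs.alt_count_mut, n_mut, k / cn_local, error_rate)
              for k in range(0, cn_local + 1)}
    mut_class, margin = argmax_margin(mut_ll)
    shifted = (not math.isclose(mut_class / cn_local, wt_class / ploidy)
               and margin >= margin_threshold
               and wt_margin >= margin_threshold)
    return DosageSite(chromosome=obs.chromosome, pos=obs.pos,
                      wt_class=wt_class, mut_class=mut_class,
                      cn_local=cn_local, shifted=shifted, margin=margin)


def classify_sites(alleles: Sequence[AlleleObservation],
                   cn_segments: Sequence[CNSegment], ploidy: int = 3,
                   error_rate: float = 0.01, min_depth: int = 10,
                   margin_threshold: float = 2.0) -> List[DosageSite]:
    """Classify every observation using the local CN from the segmentation."""
    seg_by_chrom: Dict[str, List[CNSegment]] = {}
    for s in cn_segments:
        seg_by_chrom.setdefault(s.chromosome, []).append(s)
    for segs in seg_by_chrom.values():
        segs.sort(key=lambda s: s.start)

    out: List[DosageSite] = []
    for obs in alleles:
        cn = ploidy
        for s in seg_by_chrom.get(obs.chromosome, ()):
            if s.start <= obs.pos < s.end:
                cn = s.cn
                break
        site = classify_site_dosage(obs, ploidy, cn, error_rate,
                                    min_depth, margin_threshold)
        if site is not None:
            out.append(site)
    out.sort(key=lambda s: (s.chromosome, s.pos))
    return out


def call_tracts(sites: Sequence[DosageSite], max_gap: int = 20_000,
                min_sites: int = 5,
                taqi_positions: Optional[Dict[str, np.ndarray]] = None
                ) -> List[Tuple[str, int, int, int]]:
    """Maximal runs of shifted sites: (chrom, start, end, n_sites).

    Runs with inter-site gaps <= ``max_gap`` and >= ``min_sites`` members
    are reported; bounds are the outermost shifted sites, extended outward
    to the nearest flanking TaqI site when one lies within ``max_gap``.
    """
    tracts: List[Tuple[str, int, int, int]] = []
    run: List[DosageSite] = []

    def flush():
        if len(run) >= min_sites:
            start, end = run[0].pos, run[-1].pos
            chrom = run[0].chromosome
            if taqi_positions is not None and chrom in taqi_positions:
                sites_arr = taqi_positions[chrom]
                left = sites_arr[sites_arr <= start]
                if len(left) and start - left[-1] <= max_gap:
                    start = int(left[-1])
                right = sites_arr[sites_arr >= end]
                if len(right) and right[0] - end <= max_gap:
                    end = int(right[0])
            tracts.append((chrom, start, end, len(run)))
        run.clear()

    for s in sites:
        if not s.shifted:
            continue
        if run and (s.chromosome != run[-1].chromosome
                    or s.pos - run[-1].pos > max_gap):
            flush()
        run.append(s)
    flush()
    return tracts


def classify_tract(tract: Tuple[str, int, int, int],
                   cn_segments: Sequence[CNSegment],
                   junction_calls=(), chrom_length: int = 0,
                   ploidy: int = 3, end_tolerance: int = 10_000,
                   masked_regions: Sequence[Tuple[str, int, int]] = ()
                   ) -> Optional[TractCall]:
    """Assign a dosage tract to BIR, GCV or LOH-deletion.

    A tract mostly inside a CN-loss segment is the allele-dosage footprint
    of that deletion (LOH-deletion; the CN caller owns the event).  A tract
    inside a CN-gain segment is the trivial footprint of the gain and is
    dropped (None).  Copy-neutral tracts are BIR when they reach a
    chromosome end (within ``end_tolerance``) or terminate at a
    junction-supported breakend, else GCV.
    """
    chrom, start, end, n_sites = tract

    def overlap(lo, hi):
        return max(0, min(end, hi) - max(start, lo))

    span = max(1, end - start)
    loss = gain = 0
    for s in cn_segments:
        if s.chromosome != chrom:
            continue
        if s.cn < ploidy:
            loss += overlap(s.start, s.end)
        elif s.cn > ploidy:
            gain += overlap(s.start, s.end)
    imprecise = any(mc == chrom and overlap(ms, me) > 0
                    or (mc == chrom and min(abs(start - me), abs(ms - end))
                        <= end_tolerance)
                    for mc, ms, me in masked_regions)
    note = "Around rDNA" if imprecise else ""
    if gain / span > 0.5:
        return None
    if loss / span > 0.5:
        return TractCall(chrom, start, end, "LOH-deletion", n_sites,
                         copy_neutral=False, reaches_end=False,
                         imprecise=imprecise, note=note)
    reaches_end = start <= end_tolerance or end >= chrom_length - end_tolerance
    at_junction = False
    for call in junction_calls:
        for be in (call.breakend_a, call.breakend_b):
            if be and be[0] == chrom and (abs(be[1] - start) <= end_tolerance
                                          or abs(be[1] - end) <= end_tolerance):
                at_junction = True
    kind = "BIR" if (reaches_end or at_junction) else "GCV"
    return TractCall(chrom, start, end, kind, n_sites, copy_neutral=True,
                     reaches_end=reaches_end, imprecise=imprecise, note=note)


def write_ratio_bed(track: RatioTrack, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#window={track.window}\tnorm_factor={track.norm_factor:.6g}\n")
        for chrom, ratios in track.ratios.items():
            L = track.chrom_lengths[chrom]
            for i, r in enumerate(ratios):
                s, e = i * track.window, min((i + 1) * track.window, L)
                val = "NA" if np.isnan(r) else f"{r:.4f}"
                fh.write(f"{chrom}\t{s}\t{e}\t{val}\n")


def write_cn_segments_bed(segments: Sequence[CNSegment], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tcn\tmean_ratio\n")
        for s in segments:
            fh.write(f"{s.chromosome}\t{s.start}\t{s.end}\t{s.cn}\t"
                     f"{s.mean_ratio:.4f}\n")


def write_tracts_bed(tracts: Sequence[TractCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom\tstart\tend\tkind\tn_sites\tcopy_neutral\t"
                 "reaches_end\timprecise\n")
        for t in tracts:
            fh.write(f"{t.chromosome}\t{t.start}\t{t.end}\t{t.kind}\t"
                     f"{t.n_sites}\t{int(t.copy_neutral)}\t"
                     f"{int(t.reaches_end)}\t{int(t.imprecise)}\n")
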