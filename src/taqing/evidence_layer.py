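"""Detector-facing evidence: coverage windows, allele counts, clipped reads.

The calling layer never sees raw reads — it consumes an :class:`EvidenceSet`
holding (i) WT and mutant coverage tracks on a shared window grid, (ii)
per-site allele counts at heterozygous truth sites, and (iii) clipped-read
breakend records.  The set is populated either statistically from a pair of
segment-list genomes (:func:`simulate_evidence`, the desk-scale default,
standing in for deep short-read sequencing plus alignment) or from real
coordinate-sorted SAM/BAM alignments (:func:`ingest_sam`).

Coordinate conventions (0-based, half-open): a right-clip breakend sits at
the reference position one past the last aligned base; a left-clip breakend
sits at the first aligned base.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .errors import ConfigError, FormatError, InputError
from .genome_forge import TriploidReference
from .taq_simulator import (MutantGenome, adjacency_carriers, cn_profile,
                            dosage_profile, realize_sequence)


@dataclass
class CoverageTrack:
    """Mean read depth per fixed-size window, one array per chromosome."""

    window: int
    depths: Dict[str, np.ndarray]
    chrom_lengths: Dict[str, int]

    def windows(self, chrom: str):
        d = self.depths[chrom]
        L = self.chrom_lengths[chrom]
        for i, depth in enumerate(d):
            yield i * self.window, min((i + 1) * self.window, L), float(depth)


@dataclass(frozen=True)
class AlleleObservation:
    chromosome: str
    pos: int
    ref_count_wt: int
    alt_count_wt: int
    ref_count_mut: int
    alt_count_mut: int


@dataclass(frozen=True)
class ClippedReadRecord:
    breakend_a: Tuple[str, int, str]            # (chrom, pos, "left"|"right")
    breakend_b: Optional[Tuple[str, int, str]]  # None if partner unresolved
    source: str = "simulated"                   # "simulated" | "sam"


@dataclass
class EvidenceSet:
    coverage_wt: CoverageTrack
    coverage_mut: CoverageTrack
    alleles: List[AlleleObservation]
    clips: List[ClippedReadRecord]
    meta: Dict = field(default_factory=dict)


def _window_mean_cn(breaks: np.ndarray, cn: np.ndarray, window: int,
                    length: int) -> np.ndarray:
    """Mean copy number per window from a step function (breaks, cn)."""
    n_win = -(-length // window)
    # cumulative integral of cn at each break
    widths = np.diff(breaks)
    cumint = np.concatenate([[0], np.cumsum(widths * cn)])

    def integral(x: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(breaks, x, side="right") - 1
        idx = np.clip(idx, 0, len(cn) - 1)
        return cumint[idx] + (x - breaks[idx]) * cn[idx]

    edges = np.minimum(np.arange(n_win + 1) * window, length)
    vals = integral(edges)
    sizes = np.diff(edges).astype(float)
    sizes[sizes == 0] = 1.0
    return np.diff(vals) / sizes


def simulate_evidence(wt: MutantGenome, mut: MutantGenome,
                      depth_per_copy: float = 30.0, window: int = 5_000,
                      error_rate: float = 0.01,
                      junction_capture: float = 0.5,
                      read_length: int = 150, jitter: int = 0,
                      seed: int = 0) -> EvidenceSet:
    """Statistical sequencing model over a (WT, mutant) genome pair.

    Window depth is Poisson at rate depth_per_copy x truth copy number,
    drawn at read granularity (counts of `read_length`-bp reads).  Allele
    counts at truth het SNV sites are Binomial around dosage/CN with a
    symmetric base-flip error.  Each novel adjacency emits
    Poisson(depth_per_copy x carrier molecules x junction_capture) clip
    records at the exact breakends (plus optional jitter).
    """
    if wt.reference is not mut.reference and wt.reference.chromosomes != \
            mut.reference.chromosomes:
        raise InputError("WT and mutant genomes must share one reference")
    if depth_per_copy <= 0:
        raise ConfigError("depth_per_copy must be > 0")
    rng = np.random.default_rng([seed, 7])
    ref = wt.reference

    chrom_lengths = {c: len(ref.reference[c]) for c in ref.chromosomes}
    masked = ref.masked_regions

    def coverage_for(genome: MutantGenome) -> CoverageTrack:
        depths = {}
        for chrom in ref.chromosomes:
            breaks, cn = cn_profile(genome, chrom)
            mean_cn = _window_mean_cn(breaks, cn, window, chrom_lengths[chrom])
            lam = depth_per_copy * mean_cn * window / read_length
            reads = rng.poisson(lam)
            depths[chrom] = reads * read_length / window
        return CoverageTrack(window=window, depths=depths,
                             chrom_lengths=dict(chrom_lengths))

    cov_wt = coverage_for(wt)
    cov_mut = coverage_for(mut)

    # per-site dosage via per-haplotype step functions
    def dosage_lookup(genome: MutantGenome):
        profiles = {}
        for chrom in ref.chromosomes:
            cb, ccn = cn_profile(genome, chrom)
            per_hap = {h: dosage_profile(genome, chrom, h)
                       for h in range(1, ref.ploidy + 1)}
            profiles[chrom] = (cb, ccn, per_hap)
        return profiles

    prof_wt = dosage_lookup(wt)
    prof_mut = dosage_lookup(mut)

    def step_at(breaks, vals, pos):
        i = np.searchsorted(breaks, pos, side="right") - 1
        return int(vals[min(max(i, 0), len(vals) - 1)])

    def site_counts(profiles, chrom, pos, carriers):
        cb, ccn, per_hap = profiles[chrom]
        cn = step_at(cb, ccn, pos)
        dosage = sum(step_at(*per_hap[h], pos) for h in carriers)
        n = rng.poisson(depth_per_copy * cn)
        p = dosage / cn if cn > 0 else 0.0
        p_err = p * (1 - error_rate) + (1 - p) * error_rate
        alt = rng.binomial(n, p_err) if n > 0 else 0
        return n - alt, alt

    def in_mask(chrom, pos):
        return any(c == chrom and s <= pos < e for c, s, e in masked)

    alleles: List[AlleleObservation] = []
    for chrom in ref.chromosomes:
        for v in ref.variants_on(chrom):
            if v.kind != "SNV" or in_mask(chrom, v.pos):
                continue
            rw, aw = site_counts(prof_wt, chrom, v.pos, v.carrier_haplotypes)
            rm, am = site_counts(prof_mut, chrom, v.pos, v.carrier_haplotypes)
            alleles.append(AlleleObservation(chrom, v.pos, rw, aw, rm, am))

    clips: List[ClippedReadRecord] = []
    for (be_a, be_b), carriers in sorted(adjacency_carriers(mut).items()):
        n = rng.poisson(depth_per_copy * carriers * junction_capture)
        for _ in range(n):
            if jitter > 0:
                ja = int(rng.integers(-jitter, jitter + 1))
                jb = int(rng.integers(-jitter, jitter + 1))
            else:
                ja = jb = 0
            clips.append(ClippedReadRecord(
                breakend_a=(be_a[0], be_a[1] + ja, be_a[2]),
                breakend_b=(be_b[0], be_b[1] + jb, be_b[2]),
                source="simulated"))

    meta = {"depth_per_copy": depth_per_copy, "window": window,
            "error_rate": error_rate, "junction_capture": junction_capture,
            "read_length": read_length, "jitter": jitter, "seed": seed}
    return EvidenceSet(coverage_wt=cov_wt, coverage_mut=cov_mut,
                       alleles=alleles, clips=clips, meta=meta)


# ---------------------------------------------------------------------------
# SAM/BAM ingestion

def _require_sorted(af) -> None:
    hd = af.header.to_dict().get("HD", {})
    if hd.get("SO") != "coordinate":
        raise FormatError(f"{af.filename.decode()}: not coordinate-sorted "
                          "(HD SO tag missing or not 'coordinate')")


def _cigar_ref_span(cigar: str) -> int:
    import re as _re
    span = 0
    for n, op in _re.findall(r"(\d+)([MIDNSHP=X])", cigar):
        if op in "MDN=X":
            span += int(n)
    return span


def _sa_breakend(sa_tag: str) -> Optional[Tuple[str, int, str]]:
    import re as _re
    first = sa_tag.split(";")[0]
    if not first:
        return None
    rname, pos, _strand, cigar, _mapq, _nm = first.split(",")
    pos0 = int(pos) - 1
    if _re.match(r"\d+S", cigar):
        # leading soft clip in the supplementary alignment -> its aligned
        # part starts at pos0 (left-clip side)
        return (rname, pos0, "left")
    return (rname, pos0 + _cigar_ref_span(cigar), "right")


def ingest_sam(wt_alignments, mut_alignments, het_sites,
               min_clip: int = 20, min_mapq: int = 20,
               window: int = 5_000) -> EvidenceSet:
    """Build an EvidenceSet from coordinate-sorted SAM/BAM plus a het VCF.

    Coverage comes from aligned read spans, clip records from CIGAR
    soft-clip operations of at least ``min_clip`` bases (partner breakend
    resolved from the first SA-tag entry when present), and allele counts
    from base pileups at the VCF het sites.  Reads below ``min_mapq`` are
    ignored throughout.
    """
    import os

    import pysam

    if not os.path.exists(str(het_sites)):
        raise InputError(f"het-site file not found: {het_sites}")

    def open_af(path):
        af = pysam.AlignmentFile(str(path))
        if not af.header.references:
            raise FormatError(f"{path}: missing sequence header")
        _require_sorted(af)
        return af

    af_wt = open_af(wt_alignments)
    af_mut = open_af(mut_alignments)
    chrom_lengths = {r: l for r, l in zip(af_wt.references, af_wt.lengths)}

    # SNV het sites, collected up front so one sequential pass suffices
    # (plain SAM has no index for random access)
    sites: List[Tuple[str, int, str, str]] = []
    vcf = pysam.VariantFile(str(het_sites))
    for rec in vcf.fetch():
        if len(rec.ref) == 1 and len(rec.alts or ()) == 1 \
                and len(rec.alts[0]) == 1:
            sites.append((rec.chrom, rec.pos - 1, rec.ref, rec.alts[0]))
    site_lookup: Dict[str, Dict[int, int]] = {}
    for i, (chrom, pos0, _r, _a) in enumerate(sites):
        site_lookup.setdefault(chrom, {})[pos0] = i

    def scan(af):
        depths = {c: np.zeros(-(-l // window)) for c, l in chrom_lengths.items()}
        clips: List[ClippedReadRecord] = []
        base_counts = [dict() for _ in sites]  # base -> count per site
        for read in af.fetch(until_eof=True):
            if (read.is_unmapped or read.mapping_quality < min_mapq
                    or read.cigartuples is None):
                continue
            chrom = read.reference_name
            start, end = read.reference_start, read.reference_end
            w0, w1 = start // window, (end - 1) // window
            for w in range(w0, w1 + 1):
                lo = max(start, w * window)
                hi = min(end, (w + 1) * window)
                depths[chrom][w] += hi - lo
            lookup = site_lookup.get(chrom)
            if lookup:
                seq = read.query_sequence
                for qpos, rpos in read.get_aligned_pairs(matches_only=True):
                    idx = lookup.get(rpos)
                    if idx is not None and seq is not None:
                        base = seq[qpos]
                        base_counts[idx][base] = base_counts[idx].get(base, 0) + 1
            sa = read.get_tag("SA") if read.has_tag("SA") else None
            partner = _sa_breakend(sa) if sa else None
            first_op, first_len = read.cigartuples[0]
            last_op, last_len = read.cigartuples[-1]
            if first_op == 4 and first_len >= min_clip:
                clips.append(ClippedReadRecord(
                    breakend_a=(chrom, start, "left"),
                    breakend_b=partner, source="sam"))
            if last_op == 4 and last_len >= min_clip:
                clips.append(ClippedReadRecord(
                    breakend_a=(chrom, end, "right"),
                    breakend_b=partner, source="sam"))
        for c, l in chrom_lengths.items():
            sizes = np.minimum((np.arange(len(depths[c])) + 1) * window, l) \
                - np.arange(len(depths[c])) * window
            depths[c] = depths[c] / sizes
        track = CoverageTrack(window=window, depths=depths,
                              chrom_lengths=dict(chrom_lengths))
        return track, clips, base_counts

    cov_wt, _wt_clips, counts_wt = scan(af_wt)
    cov_mut, clips, counts_mut = scan(af_mut)

    alleles: List[AlleleObservation] = []
    for i, (chrom, pos0, ref_b, alt_b) in enumerate(sites):
        alleles.append(AlleleObservation(
            chrom, pos0,
            counts_wt[i].get(ref_b, 0), counts_wt[i].get(alt_b, 0),
            counts_mut[i].get(ref_b, 0), counts_mut[i].get(alt_b, 0)))

    meta = {"min_clip": min_clip, "min_mapq": min_mapq, "window": window,
            "source": "sam"}
    return EvidenceSet(coverage_wt=cov_wt, coverage_mut=cov_mut,
                       alleles=alleles, clips=clips, meta=meta)


# ---------------------------------------------------------------------------
# read emission (optional integration path to external aligners)

def emit_reads(genome: MutantGenome, depth: float, read_length: int,
               seed: int, path) -> int:
    """Write uniformly sampled single-end FASTQ reads; returns read count."""
    rng = np.random.default_rng([seed, 11])
    n_total = 0
    with open(path, "w") as fh:
        if depth <= 0:
            return 0
        for mol in genome.molecules:
            seq = realize_sequence(genome, mol)
            if read_length >= len(seq):
                raise ConfigError(
                    f"read_length {read_length} >= molecule {mol.id} length")
            n = rng.poisson(depth * len(seq) / read_length)
            if n == 0:
                continue
            starts = rng.integers(0, len(seq) - read_length + 1, size=n)
            for i, s in enumerate(starts):
                fh.write(f"@{mol.id}_{n_total + i}\n{seq[s:s + read_length]}\n"
                         f"+\n{'I' * read_length}\n")
            n_total += n
    return n_total


# ---------------------------------------------------------------------------
# TSV round trip

def write_evidence(evidence: EvidenceSet, prefix) -> None:
    """Write the coverage/alleles/clips TSVs plus a JSON metadata sidecar."""
    prefix = str(prefix)
    cov = evidence.coverage_wt
    with open(prefix + ".coverage.tsv", "w") as fh:
        fh.write("chrom\tstart\tend\twt_depth\tmut_depth\n")
        for chrom in cov.depths:
            mut_d = evidence.coverage_mut.depths[chrom]
            for i, (s, e, d) in enumerate(cov.windows(chrom)):
                fh.write(f"{chrom}\t{s}\t{e}\t{d:.4f}\t{mut_d[i]:.4f}\n")
    with open(prefix + ".alleles.tsv", "w") as fh:
        fh.write("chrom\tpos\tref_wt\talt_wt\tref_mut\talt_mut\n")
        for a in evidence.alleles:
            fh.write(f"{a.chromosome}\t{a.pos}\t{a.ref_count_wt}\t"
                     f"{a.alt_count_wt}\t{a.ref_count_mut}\t{a.alt_count_mut}\n")
    with open(prefix + ".clips.tsv", "w") as fh:
        fh.write("chrom_a\tpos_a\tside_a\tchrom_b\tpos_b\tside_b\tsource\n")
        for c in evidence.clips:
            b = c.breakend_b or (".", ".", ".")
            fh.write(f"{c.breakend_a[0]}\t{c.breakend_a[1]}\t{c.breakend_a[2]}"
                     f"\t{b[0]}\t{b[1]}\t{b[2]}\t{c.source}\n")
    with open(prefix + ".meta.json", "w") as fh:
        json.dump(evidence.meta, fh, indent=1, sort_keys=True)
        fh.write("\n")


def read_evidence(prefix) -> EvidenceSet:
    """Read back the three-TSV + JSON representation of an EvidenceSet."""
    prefix = str(prefix)
    with open(prefix + ".meta.json") as fh:
        meta = json.load(fh)
    window = int(meta["window"])
    wt_d: Dict[str, list] = {}
    mut_d: Dict[str, list] = {}
    lengths: Dict[str, int] = {}
    with open(prefix + ".coverage.tsv") as fh:
        fh.readline()
        for line in fh:
            chrom, s, e, dw, dm = line.split("\t")
            wt_d.setdefault(chrom, []).append(float(dw))
            mut_d.setdefault(chrom, []).append(float(dm))
            lengths[chrom] = max(lengths.get(chrom, 0), int(e))
    cov_wt = CoverageTrack(window, {c: np.array(v) for c, v in wt_d.items()},
                           dict(lengths))
    cov_mut = CoverageTrack(window, {c: np.array(v) for c, v in mut_d.items()},
                            dict(lengths))
    alleles = []
    with open(prefix + ".alleles.tsv") as fh:
        fh.readline()
        for line in fh:
            chrom, pos, rw, aw, rm, am = line.split("\t")
            alleles.append(AlleleObservation(chrom, int(pos), int(rw),
                                             int(aw), int(rm), int(am)))
    clips = []
    with open(prefix + ".clips.tsv") as fh:
        fh.readline()
        for line in fh:
            ca, pa, sa, cb, pb, sb, src = line.rstrip("\n").split("\t")
            be_b = None if cb == "." else (cb, int(pb), sb)
            clips.append(ClippedReadRecord((ca, int(pa), sa), be_b, src))
    return EvidenceSet(coverage_wt=cov_wt, coverage_mut=cov_mut,
                       alleles=alleles, clips=clips, meta=meta)
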