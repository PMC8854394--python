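"""Rearrangement events at TaqI sites on a segment-list genome model.

A mutant chromosome is a :class:`Molecule`: an ordered list of oriented
reference intervals (:class:`Segment`).  Because molecules are views over
the reference rather than mutated strings, copy number, allele dosage and
novel adjacencies are analytic functions of the segment lists, and sequence
realization is a pure view.

TaqI chemistry: the enzyme recognizes the palindrome TCGA and cuts between
T and CGA, leaving 5'-CG overhangs; religation of two cut ends regenerates
an intact TCGA spanning the junction.  Events specified at a site offset
``p`` (the T of TCGA) therefore cut the reference at ``p + 1``, so every
NHEJ-created junction realizes ...T + CGA... by construction.

Event kinds (reference coordinates, 0-based):

- ``TL``   translocation: exchange molecule tails at (pos_a, pos_b);
  nonreciprocal mode keeps head_a+tail_b and the truncated partner head.
- ``DEL``  deletion of [pos_a+1, pos_b+1) from the target molecule.
- ``BIR``  break-induced repair: the target is rewritten from pos_a to the
  chromosome end with the donor haplotype's interval (copy-neutral,
  terminal allele-dosage shift).
- ``GCV``  gene conversion: interstitial copy-neutral replacement of
  [pos_a, pos_b) by the donor haplotype.
- ``ANEUPLOIDY``   append a full extra copy of the target molecule.
- ``PARTIAL_DUP``  append a new telomere-capped molecule carrying the
  donor's terminal interval [pos_a, chromosome end).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .dna import revcomp
from .errors import (BreakpointError, ConfigError, CoordinateError,
                     EventConflictError, PlacementError)
from .genome_forge import TriploidReference

EVENT_KINDS = ("TL", "DEL", "BIR", "GCV", "ANEUPLOIDY", "PARTIAL_DUP")

Breakend = Tuple[str, int, str]  # (chromosome, 0-based pos, "left" | "right")


@dataclass(frozen=True)
class Segment:
    chromosome: str
    haplotype: int
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise CoordinateError(
                f"segment [{self.start}, {self.end}) is empty or negative")
        if self.strand not in "+-":
            raise ConfigError("segment strand must be '+' or '-'")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class Molecule:
    id: str
    segments: List[Segment]
    left_cap: str = ""   # realized sequence prepended (telomere caps)
    right_cap: str = ""

    def __post_init__(self):
        if not self.segments:
            raise ConfigError(f"molecule {self.id}: segment list is empty")

    def reference_length(self) -> int:
        return sum(len(s) for s in self.segments)


@dataclass(frozen=True)
class EventSpec:
    id: str
    kind: str
    target_molecule: str
    pos_a: int
    partner_molecule: Optional[str] = None
    pos_b: Optional[int] = None
    reciprocal: bool = True
    at_taqi_sites: bool = True

    def validate(self) -> None:
        if self.kind not in EVENT_KINDS:
            raise ConfigError(f"event {self.id}: unknown kind {self.kind!r}")
        if self.kind in ("DEL", "GCV"):
            if self.pos_b is None or not (self.pos_a < self.pos_b):
                raise ConfigError(
                    f"event {self.id}: {self.kind} requires pos_a < pos_b")
        if self.kind == "TL" and (self.partner_molecule is None or self.pos_b is None):
            raise ConfigError(f"event {self.id}: TL requires partner and pos_b")
        if self.kind in ("BIR", "GCV", "PARTIAL_DUP") and self.partner_molecule is None:
            raise ConfigError(f"event {self.id}: {self.kind} requires a donor molecule")


@dataclass
class MutantGenome:
    reference: TriploidReference
    molecules: List[Molecule]
    provenance: List[EventSpec] = field(default_factory=list)

    @classmethod
    def wild_type(cls, reference: TriploidReference) -> "MutantGenome":
        mols = [
            Molecule(id=f"{chrom}_hap{hap}",
                     segments=[Segment(chrom, hap, 0, len(reference.reference[chrom]))])
            for chrom in reference.chromosomes
            for hap in range(1, reference.ploidy + 1)
        ]
        return cls(reference=reference, molecules=mols)

    def molecule(self, mol_id: str) -> Molecule:
        for m in self.molecules:
            if m.id == mol_id:
                return m
        raise ConfigError(f"unknown molecule id {mol_id!r}")


@dataclass
class KaryotypeProfile:
    """Virtual PFGE profile: descending multiset of molecule lengths (bp)."""
    band_lengths: List[int]


def taqi_sites(sequence: str) -> np.ndarray:
    """Ascending offsets of every TCGA occurrence (palindromic, strand-free)."""
    return np.array([m.start() for m in re.finditer("TCGA", sequence)],
                    dtype=np.int64)


def expected_taqi_spacing(base_probs: Sequence[float] = (0.25,) * 4) -> float:
    """Expected bp between TCGA sites under iid bases: 1 / P(TCGA).

    With uniform base composition this is 4**4 = 256, i.e. one site per
    256 bp of genome.
    """
    p = dict(zip("ACGT", base_probs))
    prob = p["T"] * p["C"] * p["G"] * p["A"]
    return 1.0 / prob


# ---------------------------------------------------------------------------
# event application

def _occupied_interval(event: EventSpec) -> Tuple[str, int, Optional[int]]:
    """(molecule, start, end) reference interval an event rearranges.

    ``end=None`` means to the molecule/chromosome end.  ANEUPLOIDY and the
    donor side of copy events occupy nothing (they only read).
    """
    if event.kind == "DEL" or event.kind == "GCV":
        return (event.target_molecule, event.pos_a, event.pos_b)
    if event.kind == "BIR":
        return (event.target_molecule, event.pos_a, None)
    if event.kind == "TL":
        return (event.target_molecule, event.pos_a, None)
    return (event.target_molecule, -1, -1)  # no rearranged interval


def _check_overlap(genome: MutantGenome, event: EventSpec) -> None:
    def intervals(ev: EventSpec):
        yield _occupied_interval(ev)
        if ev.kind == "TL":
            yield (ev.partner_molecule, ev.pos_b, None)

    new = list(intervals(event))
    for prior in genome.provenance:
        for mol_p, s_p, e_p in intervals(prior):
            if s_p == -1:
                continue
            for mol_n, s_n, e_n in new:
                if s_n == -1 or mol_p != mol_n:
                    continue
                e_p_ = float("inf") if e_p is None else e_p
                e_n_ = float("inf") if e_n is None else e_n
                if s_n < e_p_ and s_p < e_n_:
                    raise EventConflictError(
                        f"event {event.id} overlaps {prior.id} on {mol_p}")


def _require_taqi(genome: MutantGenome, chrom: str, pos: int, event_id: str) -> None:
    ref = genome.reference.reference[chrom]
    if ref[pos:pos + 4] != "TCGA":
        raise BreakpointError(
            f"event {event_id}: breakpoint {chrom}:{pos} is not a TaqI site")


def _split(molecule: Molecule, chrom: str, cut: int
           ) -> Tuple[List[Segment], List[Segment]]:
    """Split a molecule's segment list at reference coordinate `cut`."""
    for i, seg in enumerate(molecule.segments):
        if seg.chromosome != chrom or seg.strand != "+":
            continue
        if seg.start < cut < seg.end:
            left = molecule.segments[:i] + [replace(seg, end=cut)]
            right = [replace(seg, start=cut)] + molecule.segments[i + 1:]
            return left, right
        if cut == seg.start:
            return molecule.segments[:i], molecule.segments[i:]
    raise CoordinateError(
        f"molecule {molecule.id}: no plus-strand segment of {chrom} spans {cut}")


def _donor_haplotype(genome: MutantGenome, mol_id: str, chrom: str, pos: int) -> int:
    donor = genome.molecule(mol_id)
    for seg in donor.segments:
        if seg.chromosome == chrom and seg.start <= pos < seg.end:
            return seg.haplotype
    raise CoordinateError(
        f"donor molecule {mol_id} does not cover {chrom}:{pos}")


def apply_event(genome: MutantGenome, event: EventSpec) -> MutantGenome:
    """Return a new genome with `event` applied (the input is not mutated)."""
    event.validate()
    _check_overlap(genome, event)
    target = genome.molecule(event.target_molecule)
    chrom = target.segments[0].chromosome
    ref_len = len(genome.reference.reference[chrom])
    mols = [Molecule(m.id, list(m.segments), m.left_cap, m.right_cap)
            for m in genome.molecules]
    out = MutantGenome(reference=genome.reference, molecules=mols,
                       provenance=list(genome.provenance) + [event])
    target = out.molecule(event.target_molecule)

    if event.kind == "TL":
        partner = out.molecule(event.partner_molecule)
        chrom_b = partner.segments[0].chromosome
        if event.at_taqi_sites:
            _require_taqi(out, chrom, event.pos_a, event.id)
            _require_taqi(out, chrom_b, event.pos_b, event.id)
        head_a, tail_a = _split(target, chrom, event.pos_a + 1)
        head_b, tail_b = _split(partner, chrom_b, event.pos_b + 1)
        target.segments = head_a + tail_b
        if event.reciprocal:
            partner.segments = head_b + tail_a
        else:
            partner.segments = head_b  # tail_a is the discarded acentric piece

    elif event.kind == "DEL":
        if event.at_taqi_sites:
            _require_taqi(out, chrom, event.pos_a, event.id)
            _require_taqi(out, chrom, event.pos_b, event.id)
        head, rest = _split(target, chrom, event.pos_a + 1)
        mid_mol = Molecule(id="_tmp", segments=rest)
        _, tail = _split(mid_mol, chrom, event.pos_b + 1)
        target.segments = head + tail

    elif event.kind == "BIR":
        if event.at_taqi_sites:
            _require_taqi(out, chrom, event.pos_a, event.id)
        donor_hap = _donor_haplotype(out, event.partner_molecule, chrom, event.pos_a)
        head, _ = _split(target, chrom, event.pos_a)
        target.segments = head + [Segment(chrom, donor_hap, event.pos_a, ref_len)]

    elif event.kind == "GCV":
        if event.at_taqi_sites:
            _require_taqi(out, chrom, event.pos_a, event.id)
            _require_taqi(out, chrom, event.pos_b, event.id)
        donor_hap = _donor_haplotype(out, event.partner_molecule, chrom, event.pos_a)
        head, rest = _split(target, chrom, event.pos_a)
        mid_mol = Molecule(id="_tmp", segments=rest)
        _, tail = _split(mid_mol, chrom, event.pos_b)
        target.segments = (head
                           + [Segment(chrom, donor_hap, event.pos_a, event.pos_b)]
                           + tail)

    elif event.kind == "ANEUPLOIDY":
        copy = Molecule(id=f"{target.id}_extra",
                        segments=list(target.segments),
                        left_cap=target.left_cap, right_cap=target.right_cap)
        out.molecules.append(copy)

    elif event.kind == "PARTIAL_DUP":
        donor = out.molecule(event.partner_molecule)
        chrom_d = donor.segments[0].chromosome
        if event.at_taqi_sites:
            _require_taqi(out, chrom_d, event.pos_a, event.id)
        donor_hap = _donor_haplotype(out, event.partner_molecule, chrom_d, event.pos_a)
        ref_len_d = len(out.reference.reference[chrom_d])
        unit = out.reference.telomere_unit
        new = Molecule(
            id=f"dup_{event.id}",
            segments=[Segment(chrom_d, donor_hap, event.pos_a, ref_len_d)],
            left_cap=revcomp(unit) * 10)
        out.molecules.append(new)

    return out


# ---------------------------------------------------------------------------
# analytic truth

def _segment_iter(genome: MutantGenome) -> Iterable[Tuple[Molecule, Segment]]:
    for mol in genome.molecules:
        for seg in mol.segments:
            yield mol, seg


def truth_copy_number(genome: MutantGenome, chromosome: str, pos: int) -> int:
    """Number of molecule segments covering (chromosome, pos)."""
    return sum(1 for _, s in _segment_iter(genome)
               if s.chromosome == chromosome and s.start <= pos < s.end)


def truth_dosage(genome: MutantGenome, chromosome: str, pos: int,
                 haplotype: int) -> int:
    """Copies of `haplotype` covering (chromosome, pos)."""
    return sum(1 for _, s in _segment_iter(genome)
               if s.chromosome == chromosome and s.haplotype == haplotype
               and s.start <= pos < s.end)


def _junction_breakends(a: Segment, b: Segment) -> Tuple[Breakend, Breakend]:
    be_a = (a.chromosome, a.end, "right") if a.strand == "+" else \
        (a.chromosome, a.start, "left")
    be_b = (b.chromosome, b.start, "left") if b.strand == "+" else \
        (b.chromosome, b.end, "right")
    return be_a, be_b


def _is_reference_contiguous(a: Segment, b: Segment) -> bool:
    if a.chromosome != b.chromosome or a.strand != b.strand:
        return False
    if a.strand == "+":
        return a.end == b.start
    return b.end == a.start


def truth_adjacencies(genome: MutantGenome
                      ) -> Set[Tuple[Breakend, Breakend]]:
    """Novel adjacencies: consecutive segment pairs not reference-contiguous.

    Haplotype switches at contiguous coordinates (BIR/GCV joints) are NOT
    novel adjacencies — no clipped read would see them.  Pairs are stored
    sorted so reciprocal products compare canonically.
    """
    out: Set[Tuple[Breakend, Breakend]] = set()
    for mol in genome.molecules:
        for a, b in zip(mol.segments, mol.segments[1:]):
            if not _is_reference_contiguous(a, b):
                be = _junction_breakends(a, b)
                out.add(tuple(sorted(be)))
    return out


def adjacency_carriers(genome: MutantGenome
                       ) -> Dict[Tuple[Breakend, Breakend], int]:
    """Novel adjacency -> number of molecules carrying it."""
    counts: Dict[Tuple[Breakend, Breakend], int] = {}
    for mol in genome.molecules:
        for a, b in zip(mol.segments, mol.segments[1:]):
            if not _is_reference_contiguous(a, b):
                key = tuple(sorted(_junction_breakends(a, b)))
                counts[key] = counts.get(key, 0) + 1
    return counts


def cn_profile(genome: MutantGenome, chromosome: str
               ) -> Tuple[np.ndarray, np.ndarray]:
    """Copy-number step function for one chromosome.

    Returns (breaks, cn): ``cn[i]`` holds on [breaks[i], breaks[i+1]).
    """
    length = len(genome.reference.reference[chromosome])
    deltas: Dict[int, int] = {0: 0, length: 0}
    for _, s in _segment_iter(genome):
        if s.chromosome != chromosome:
            continue
        deltas[s.start] = deltas.get(s.start, 0) + 1
        deltas[s.end] = deltas.get(s.end, 0) - 1
    breaks = np.array(sorted(deltas), dtype=np.int64)
    cn = np.cumsum([deltas[b] for b in breaks[:-1]])
    return breaks, cn


def dosage_profile(genome: MutantGenome, chromosome: str, haplotype: int
                   ) -> Tuple[np.ndarray, np.ndarray]:
    """Like :func:`cn_profile` but counting one haplotype only."""
    length = len(genome.reference.reference[chromosome])
    deltas: Dict[int, int] = {0: 0, length: 0}
    for _, s in _segment_iter(genome):
        if s.chromosome != chromosome or s.haplotype != haplotype:
            continue
        deltas[s.start] = deltas.get(s.start, 0) + 1
        deltas[s.end] = deltas.get(s.end, 0) - 1
    breaks = np.array(sorted(deltas), dtype=np.int64)
    cn = np.cumsum([deltas[b] for b in breaks[:-1]])
    return breaks, cn


# ---------------------------------------------------------------------------
# realization and karyotype

def realize_sequence(genome: MutantGenome, molecule: Molecule) -> str:
    """Concatenate oriented haplotype substrings (plus any telomere caps)."""
    parts = [molecule.left_cap]
    for seg in molecule.segments:
        s = genome.reference.haplotype_sequence(
            seg.chromosome, seg.haplotype, seg.start, seg.end)
        parts.append(s if seg.strand == "+" else revcomp(s))
    parts.append(molecule.right_cap)
    return "".join(parts)


def realized_length(genome: MutantGenome, molecule: Molecule) -> int:
    n = len(molecule.left_cap) + len(molecule.right_cap)
    for seg in molecule.segments:
        n += len(genome.reference.haplotype_sequence(
            seg.chromosome, seg.haplotype, seg.start, seg.end))
    return n


def virtual_pfge(genome: MutantGenome) -> KaryotypeProfile:
    lengths = sorted((realized_length(genome, m) for m in genome.molecules),
                     reverse=True)
    return KaryotypeProfile(band_lengths=lengths)


def compare_karyotypes(mutant: KaryotypeProfile, wild_type: KaryotypeProfile,
                       resolution: float = 0.02
                       ) -> Dict[str, List[int]]:
    """Bands gained/lost in the mutant at a relative size resolution.

    Bands differing by less than ``resolution`` (fractional) are considered
    the same band; matching is greedy from the largest band down.
    """
    wt = list(wild_type.band_lengths)
    gained: List[int] = []
    for band in mutant.band_lengths:
        match = None
        for w in wt:
            if abs(w - band) <= resolution * max(w, band):
                match = w
                break
        if match is None:
            gained.append(band)
        else:
            wt.remove(match)
    return {"gained": gained, "lost": wt}


# ---------------------------------------------------------------------------
# random scenario generation

_DEFAULT_SIZE_RANGES = {
    "DEL": (10_000, 70_000),
    "GCV": (2_000, 10_000),
    "BIR": (50_000, 120_000),      # distance from breakpoint to chromosome end
    "PARTIAL_DUP": (40_000, 90_000),
    "TL": (50_000, 250_000),       # tail length exchanged, per chromosome
}

# the same ranges as fractions of a 300 kb chromosome, used to scale
# scenarios onto shorter or longer chromosomes
_SIZE_FRACTIONS = {k: (lo / 300_000, hi / 300_000)
                   for k, (lo, hi) in _DEFAULT_SIZE_RANGES.items()}


def scaled_size_ranges(chrom_length: int) -> Dict[str, Tuple[int, int]]:
    """Event size ranges proportional to chromosome length.

    At the default 300 kb chromosome these equal the standard scenario
    (deletions 10-70 kb, conversions 2-10 kb, ...).
    """
    return {k: (max(500, int(lo * chrom_length)), int(hi * chrom_length))
            for k, (lo, hi) in _SIZE_FRACTIONS.items()}


def sample_events(genome: MutantGenome, counts: Dict[str, int],
                  size_ranges: Optional[Dict[str, Tuple[int, int]]] = None,
                  seed: int = 0, min_het_sites: int = 0,
                  margin: int = 25_000, max_tries: int = 500
                  ) -> List[EventSpec]:
    """Draw a non-overlapping event scenario at TaqI sites.

    Breakpoints are drawn uniformly from TaqI sites of the reference that
    have no truth variant within 100 bp (so the site is intact on every
    haplotype and event coordinates lift over trivially).  Placement
    constraints keep the scenario analyzable: at most one copy-number
    event per chromosome, no event inside another event's interval plus
    ``margin``, and (optionally) at least ``min_het_sites`` truth variants
    inside every dosage-visible tract.

    Homologous events (BIR/GCV) always pair the divergent haplotype with
    one of the alike pair — recombination between identical haplotypes is
    invisible and would be unrecoverable by construction.
    """
    if any(v < 0 for v in counts.values()):
        raise ConfigError("event counts must be >= 0")
    rng = np.random.default_rng([seed, 99])
    ranges = dict(_DEFAULT_SIZE_RANGES)
    if size_ranges:
        ranges.update(size_ranges)
    ref = genome.reference
    ploidy = ref.ploidy
    div_hap = ploidy

    clean_sites: Dict[str, np.ndarray] = {}
    for chrom in ref.chromosomes:
        sites = taqi_sites(ref.reference[chrom])
        var_pos = np.array([v.pos for v in ref.variants_on(chrom)], dtype=np.int64)
        if len(var_pos):
            lo = np.searchsorted(var_pos, sites - 100)
            hi = np.searchsorted(var_pos, sites + 104)
            sites = sites[lo == hi]
        for c, ms, me in ref.masked_regions:
            if c == chrom and len(sites):
                sites = sites[(sites < ms - 100) | (sites >= me + 100)]
        clean_sites[chrom] = sites

    var_positions = {
        chrom: np.array([v.pos for v in ref.variants_on(chrom)], dtype=np.int64)
        for chrom in ref.chromosomes}

    occupied: Dict[str, List[Tuple[int, int]]] = {c: [] for c in ref.chromosomes}
    cn_event_chroms: Set[str] = set()
    events: List[EventSpec] = []
    eid = 0

    def is_free(chrom: str, start: int, end: int) -> bool:
        for s, e in occupied[chrom]:
            if start < e + margin and s - margin < end:
                return False
        return True

    def sites_in(chrom: str, lo: int, hi: int) -> np.ndarray:
        s = clean_sites[chrom]
        return s[(s >= lo) & (s < hi)]

    def het_count(chrom: str, lo: int, hi: int) -> int:
        vp = var_positions[chrom]
        return int(np.searchsorted(vp, hi) - np.searchsorted(vp, lo))

    def pick_hap_pair() -> Tuple[int, int]:
        alike = int(rng.integers(1, ploidy))
        if rng.random() < 0.5:
            return div_hap, alike  # target divergent, donor alike
        return alike, div_hap

    order = ["ANEUPLOIDY", "PARTIAL_DUP", "BIR", "TL", "DEL", "GCV"]
    for kind in order:
        for _ in range(counts.get(kind, 0)):
            placed = False
            for _try in range(max_tries):
                chrom = ref.chromosomes[int(rng.integers(len(ref.chromosomes)))]
                length = len(ref.reference[chrom])

                if kind == "ANEUPLOIDY":
                    if chrom in cn_event_chroms or occupied[chrom]:
                        continue
                    hap = int(rng.integers(1, ploidy + 1))
                    events.append(EventSpec(
                        id=f"ev{eid}", kind=kind,
                        target_molecule=f"{chrom}_hap{hap}", pos_a=0))
                    occupied[chrom].append((0, length))
                    cn_event_chroms.add(chrom)
                    placed = True
                    break

                if kind in ("BIR", "PARTIAL_DUP"):
                    lo_sz, hi_sz = ranges[kind]
                    cand = sites_in(chrom, length - hi_sz, length - lo_sz)
                    if kind == "PARTIAL_DUP" and chrom in cn_event_chroms:
                        continue
                    if len(cand) == 0:
                        continue
                    pos = int(cand[int(rng.integers(len(cand)))])
                    if not is_free(chrom, pos, length):
                        continue
                    if min_het_sites and het_count(chrom, pos, length) < min_het_sites:
                        continue
                    if kind == "BIR":
                        t_hap, d_hap = pick_hap_pair()
                        events.append(EventSpec(
                            id=f"ev{eid}", kind=kind,
                            target_molecule=f"{chrom}_hap{t_hap}", pos_a=pos,
                            partner_molecule=f"{chrom}_hap{d_hap}"))
                    else:
                        hap = int(rng.integers(1, ploidy + 1))
                        events.append(EventSpec(
                            id=f"ev{eid}", kind=kind,
                            target_molecule=f"{chrom}_hap{hap}", pos_a=pos,
                            partner_molecule=f"{chrom}_hap{hap}"))
                        cn_event_chroms.add(chrom)
                    occupied[chrom].append((pos, length))
                    placed = True
                    break

                if kind == "TL":
                    chrom_b = ref.chromosomes[int(rng.integers(len(ref.chromosomes)))]
                    if chrom_b == chrom:
                        continue
                    lo_sz, hi_sz = ranges["TL"]
                    len_b = len(ref.reference[chrom_b])
                    ca = sites_in(chrom, length - hi_sz, length - lo_sz)
                    cb = sites_in(chrom_b, len_b - hi_sz, len_b - lo_sz)
                    if len(ca) == 0 or len(cb) == 0:
                        continue
                    pos_a = int(ca[int(rng.integers(len(ca)))])
                    pos_b = int(cb[int(rng.integers(len(cb)))])
                    if not (is_free(chrom, pos_a, length)
                            and is_free(chrom_b, pos_b, len_b)):
                        continue
                    hap_a = int(rng.integers(1, ploidy + 1))
                    hap_b = int(rng.integers(1, ploidy + 1))
                    events.append(EventSpec(
                        id=f"ev{eid}", kind=kind,
                        target_molecule=f"{chrom}_hap{hap_a}", pos_a=pos_a,
                        partner_molecule=f"{chrom_b}_hap{hap_b}", pos_b=pos_b))
                    occupied[chrom].append((pos_a, length))
                    occupied[chrom_b].append((pos_b, len_b))
                    placed = True
                    break

                if kind in ("DEL", "GCV"):
                    lo_sz, hi_sz = ranges[kind]
                    cand = sites_in(chrom, margin, length - margin - lo_sz)
                    if kind == "DEL" and chrom in cn_event_chroms:
                        continue
                    if len(cand) == 0:
                        continue
                    pos_a = int(cand[int(rng.integers(len(cand)))])
                    ends = sites_in(chrom, pos_a + lo_sz, min(pos_a + hi_sz,
                                                              length - margin))
                    if len(ends) == 0:
                        continue
                    pos_b = int(ends[int(rng.integers(len(ends)))])
                    if not is_free(chrom, pos_a, pos_b):
                        continue
                    if min_het_sites and het_count(chrom, pos_a, pos_b) < min_het_sites:
                        continue
                    if kind == "DEL":
                        hap = int(rng.integers(1, ploidy + 1))
                        events.append(EventSpec(
                            id=f"ev{eid}", kind=kind,
                            target_molecule=f"{chrom}_hap{hap}",
                            pos_a=pos_a, pos_b=pos_b))
                        cn_event_chroms.add(chrom)
                    else:
                        t_hap, d_hap = pick_hap_pair()
                        events.append(EventSpec(
                            id=f"ev{eid}", kind=kind,
                            target_molecule=f"{chrom}_hap{t_hap}",
                            pos_a=pos_a, pos_b=pos_b,
                            partner_molecule=f"{chrom}_hap{d_hap}"))
                    occupied[chrom].append((pos_a, pos_b))
                    placed = True
                    break

            if not placed:
                raise PlacementError(
                    f"could not place a {kind} event after {max_tries} tries")
            eid += 1
    return events


def apply_events(genome: MutantGenome, events: Iterable[EventSpec]) -> MutantGenome:
    for ev in events:
        genome = apply_event(genome, ev)
    return genome


# ---------------------------------------------------------------------------
# tabular IO

def write_events_tsv(events: Sequence[EventSpec], path) -> None:
    with open(path, "w") as fh:
        fh.write("id\tkind\ttarget_molecule\tpos_a\tpartner_molecule\t"
                 "pos_b\treciprocal\n")
        for ev in events:
            fh.write(f"{ev.id}\t{ev.kind}\t{ev.target_molecule}\t{ev.pos_a}\t"
                     f"{ev.partner_molecule or '.'}\t"
                     f"{'.' if ev.pos_b is None else ev.pos_b}\t"
                     f"{int(ev.reciprocal)}\n")


def read_events_tsv(path) -> List[EventSpec]:
    events = []
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("id\t"):
            raise ConfigError(f"{path}: missing events header")
        for line in fh:
            f = line.rstrip("\n").split("\t")
            events.append(EventSpec(
                id=f[0], kind=f[1], target_molecule=f[2], pos_a=int(f[3]),
                partner_molecule=None if f[4] == "." else f[4],
                pos_b=None if f[5] == "." else int(f[5]),
                reciprocal=bool(int(f[6]))))
    return events


def write_adjacencies_bedpe(genome: MutantGenome, path) -> None:
    """Truth novel adjacencies as BEDPE (0-based half-open, 1 bp intervals)."""
    with open(path, "w") as fh:
        for (ca, pa, sa), (cb, pb, sb) in sorted(truth_adjacencies(genome)):
            fh.write(f"{ca}\t{pa}\t{pa + 1}\t{cb}\t{pb}\t{pb + 1}\t"
                     f"{sa}/{sb}\n")


def write_karyotype_tsv(profile: KaryotypeProfile, path) -> None:
    with open(path, "w") as fh:
        fh.write("band\tlength_bp\n")
        for i, l in enumerate(profile.band_lengths, 1):
            fh.write(f"{i}\t{l}\n")


def write_mutant_fasta(genome: MutantGenome, path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for mol in genome.molecules:
            fh.write(f">{mol.id}\n")
            seq = realize_sequence(genome, mol)
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
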