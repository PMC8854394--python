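"""Synthetic triploid reference genomes with haplotype variant structure.

The forge emulates the genome of an asexual industrial (torula) yeast:
triploid, six chromosomes, telomeric GGGTGTCT repeats at both ends, and a
haplotype structure in which two of the three alleles carry near-identical
SNV/InDel patterns while the third diverges.  Everything is generated from a
single integer seed; per-chromosome child RNG streams are derived from
``(seed, chromosome_index)`` so adding chromosomes never reshuffles earlier
ones.

Coordinates are 0-based half-open on the reference haplotype (haplotype 1).
Truth variants are normalized so the reference string always carries the ref
allele; under the default "two-alike" pattern this places every alt allele on
the divergent haplotype (the highest index), while the generating mutation
process ("shared" between the alike pair vs "divergent") is retained in the
variant's ``origin`` field.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .dna import BASES, random_sequence, revcomp
from .errors import ConfigError, CoordinateError

# minimum spacing between truth variants, so VCF-style anchored alleles
# never overlap and interval realization stays unambiguous
_MIN_VARIANT_SPACING = 12
_MAX_INDEL = 10


@dataclass(frozen=True)
class GenomeSpec:
    """Parameters of the synthetic triploid genome.

    ``het_snv_rate`` / ``het_indel_rate`` are expected variants per bp per
    haplotype-pattern class (the "shared" pair process and the "divergent"
    third-haplotype process each run at this rate).
    """

    n_chromosomes: int = 6
    chrom_lengths: Tuple[int, ...] = None  # default: 300 kb each
    ploidy: int = 3
    base_probs: Tuple[float, float, float, float] = (0.25, 0.25, 0.25, 0.25)
    het_snv_rate: float = 2e-3
    het_indel_rate: float = 2e-4
    pattern: str = "two-alike"
    telomere_unit: str = "GGGTGTCT"
    telomere_units: Tuple[int, int] = (5, 20)
    repeat_array: Optional[Tuple[int, int, int, Tuple[int, ...]]] = None
    extra_chromosome: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.chrom_lengths is None:
            object.__setattr__(
                self, "chrom_lengths", (300_000,) * self.n_chromosomes
            )
        else:
            object.__setattr__(self, "chrom_lengths",
                               tuple(int(x) for x in self.chrom_lengths))

    def validate(self) -> None:
        if self.n_chromosomes < 1:
            raise ConfigError("n_chromosomes must be >= 1")
        if len(self.chrom_lengths) != self.n_chromosomes:
            raise ConfigError("chrom_lengths length must equal n_chromosomes")
        if any(l <= 0 for l in self.chrom_lengths):
            raise ConfigError("chrom_lengths entries must be > 0")
        if self.ploidy < 2:
            raise ConfigError("ploidy must be >= 2")
        if abs(sum(self.base_probs) - 1.0) > 1e-9 or any(p < 0 for p in self.base_probs):
            raise ConfigError("base_probs must be non-negative and sum to 1")
        if not (0 <= self.het_snv_rate < 1) or not (0 <= self.het_indel_rate < 1):
            raise ConfigError("het_snv_rate/het_indel_rate must lie in [0, 1)")
        if self.pattern != "two-alike":
            raise ConfigError(f"pattern: unknown scheme {self.pattern!r}")
        if not self.telomere_unit or set(self.telomere_unit) - set(BASES):
            raise ConfigError("telomere_unit must be a non-empty ACGT string")
        lo, hi = self.telomere_units
        if lo < 0 or hi < lo:
            raise ConfigError("telomere_units must satisfy 0 <= min <= max")
        if self.seed < 0:
            raise ConfigError("seed must be >= 0")


@dataclass(frozen=True)
class TruthVariant:
    """A heterozygous truth variant against the reference haplotype.

    ``pos`` is 0-based; ``ref_allele``/``alt_allele`` follow VCF anchoring
    for indels.  ``carrier_haplotypes`` are the 1-based haplotype indices
    carrying the alt allele; ``origin`` names the generating process.
    """

    chromosome: str
    pos: int
    ref_allele: str
    alt_allele: str
    carrier_haplotypes: frozenset
    kind: str  # "SNV" | "InDel"
    origin: str = "divergent"  # "shared" | "divergent" | "array"

    def __post_init__(self):
        if self.ref_allele == self.alt_allele:
            raise ConfigError("TruthVariant: ref_allele must differ from alt_allele")
        if not self.carrier_haplotypes:
            raise ConfigError("TruthVariant: carrier set must be non-empty")


@dataclass
class TriploidReference:
    """Haplotype-resolved genome: reference strings plus truth variants.

    Haplotype sequences are materialized on demand by applying each
    haplotype's variants to the reference slice, so reference coordinates
    remain the single coordinate system.
    """

    chromosomes: List[str]
    reference: Dict[str, str]
    variants: List[TruthVariant]
    ploidy: int = 3
    reference_haplotype: int = 1
    telomere_unit: str = "GGGTGTCT"
    masked_regions: List[Tuple[str, int, int]] = field(default_factory=list)
    spec: Optional[GenomeSpec] = None

    def __post_init__(self):
        self._by_chrom: Dict[str, List[TruthVariant]] = {c: [] for c in self.chromosomes}
        for v in self.variants:
            self._by_chrom[v.chromosome].append(v)
        for vs in self._by_chrom.values():
            vs.sort(key=lambda v: v.pos)

    def chrom_length(self, chrom: str) -> int:
        return len(self.reference[chrom])

    def variants_on(self, chrom: str) -> List[TruthVariant]:
        return self._by_chrom[chrom]

    def haplotype_sequence(self, chrom: str, haplotype: int,
                           start: int = 0, end: Optional[int] = None) -> str:
        """Realize haplotype `haplotype` over reference interval [start, end).

        Variants whose anchored ref allele is not wholly inside the interval
        are skipped (variants are sparse and kept >= 12 bp apart, so this
        only affects interval edges).
        """
        ref = self.reference[chrom]
        if end is None:
            end = len(ref)
        if not (0 <= start <= end <= len(ref)):
            raise CoordinateError(
                f"interval [{start}, {end}) out of bounds for {chrom}")
        if haplotype == self.reference_haplotype:
            base = ref[start:end]
        else:
            parts: List[str] = []
            cursor = start
            for v in self._by_chrom[chrom]:
                if v.pos < start or haplotype not in v.carrier_haplotypes:
                    continue
                if v.pos + len(v.ref_allele) > end:
                    break
                parts.append(ref[cursor:v.pos])
                parts.append(v.alt_allele)
                cursor = v.pos + len(v.ref_allele)
            parts.append(ref[cursor:end])
            base = "".join(parts)
        return base

    @property
    def sequences(self) -> Dict[Tuple[str, int], str]:
        """Mapping (chromosome, haplotype) -> full haplotype string."""
        return {
            (c, h): self.haplotype_sequence(c, h)
            for c in self.chromosomes
            for h in range(1, self.ploidy + 1)
        }

    def chrom_lengths_per_haplotype(self) -> Dict[Tuple[str, int], int]:
        return {k: len(s) for k, s in self.sequences.items()}


def plant_telomeres(sequence: str, unit: str, n_left: int, n_right: int) -> str:
    """Cap a sequence with telomeric repeats.

    The left cap is the reverse complement of the unit (plus-strand
    convention for the left chromosome end); the right cap is the unit
    itself, tandemly repeated.
    """
    if not unit:
        raise ConfigError("telomere unit must be non-empty")
    if n_left < 0 or n_right < 0:
        raise ConfigError("telomere unit counts must be >= 0")
    return revcomp(unit) * n_left + sequence + unit * n_right


def _chrom_rng(seed: int, chrom_index: int, stream: int = 0) -> np.random.Generator:
    # documented child-stream derivation: entropy = (seed, stream, chrom_index)
    return np.random.default_rng([seed, stream, chrom_index])


def generate_reference(spec: GenomeSpec) -> TriploidReference:
    """Generate the seeded synthetic triploid genome with truth tables."""
    spec.validate()
    unit = spec.telomere_unit
    chroms = [f"chr{i + 1}" for i in range(spec.n_chromosomes)]
    reference: Dict[str, str] = {}
    variants: List[TruthVariant] = []
    divergent_hap = spec.ploidy  # highest index diverges under "two-alike"

    for ci, (chrom, length) in enumerate(zip(chroms, spec.chrom_lengths)):
        rng = _chrom_rng(spec.seed, ci)
        lo, hi = spec.telomere_units
        n_left = int(rng.integers(lo, hi + 1))
        n_right = int(rng.integers(lo, hi + 1))
        core_len = length - (n_left + n_right) * len(unit)
        if core_len <= 2 * _MIN_VARIANT_SPACING:
            raise ConfigError(
                f"chrom_lengths[{ci}] too short for the telomere caps")
        core = random_sequence(core_len, rng, spec.base_probs)
        ref = plant_telomeres(core, unit, n_left, n_right)
        reference[chrom] = ref

        # variants confined to the non-telomeric interior, with a small pad
        int_start = n_left * len(unit) + _MIN_VARIANT_SPACING
        int_end = length - n_right * len(unit) - 2 * _MAX_INDEL
        span = int_end - int_start
        candidates: List[Tuple[int, str, str]] = []
        for origin in ("shared", "divergent"):
            for kind, rate in (("SNV", spec.het_snv_rate),
                               ("InDel", spec.het_indel_rate)):
                n = rng.binomial(span, rate) if rate > 0 else 0
                if n == 0:
                    continue
                pos = rng.choice(span, size=n, replace=False) + int_start
                candidates.extend((int(p), origin, kind) for p in pos)
        candidates.sort(key=lambda t: t[0])

        last = -_MIN_VARIANT_SPACING
        for pos, origin, kind in candidates:
            if pos - last < _MIN_VARIANT_SPACING:
                continue
            last = pos
            ref_b = ref[pos]
            if kind == "SNV":
                others = BASES.replace(ref_b, "")
                ref_a, alt_a = ref_b, others[int(rng.integers(len(others)))]
            else:
                size = int(rng.integers(1, _MAX_INDEL + 1))
                if rng.random() < 0.5:  # deletion on the carrier haplotype
                    ref_a = ref[pos:pos + size + 1]
                    alt_a = ref_b
                else:  # insertion
                    ref_a = ref_b
                    alt_a = ref_b + random_sequence(size, rng, spec.base_probs)
            variants.append(TruthVariant(
                chromosome=chrom, pos=pos, ref_allele=ref_a, alt_allele=alt_a,
                carrier_haplotypes=frozenset({divergent_hap}), kind=kind,
                origin=origin))

    genome = TriploidReference(
        chromosomes=chroms, reference=reference, variants=variants,
        ploidy=spec.ploidy, telomere_unit=unit, spec=spec)
    if spec.repeat_array is not None:
        ci, pos, unit_len, copies = spec.repeat_array
        genome = plant_repeat_array(genome, chroms[ci], pos, unit_len, copies)
    return genome


def plant_repeat_array(genome: TriploidReference, chromosome: str, pos: int,
                       unit_len: int, copies_per_haplotype: Sequence[int]
                       ) -> TriploidReference:
    """Insert an rDNA-like tandem array at `pos` on every haplotype.

    The reference haplotype receives its own copy count in the reference
    string; haplotypes with different counts are represented by a single
    large insertion/deletion variant at the array edge (``origin="array"``).
    The inserted interval is recorded as a masked repetitive region.
    """
    ref = genome.reference[chromosome]
    if not (0 < pos < len(ref)):
        raise CoordinateError(f"repeat array pos {pos} out of bounds for {chromosome}")
    copies = tuple(int(c) for c in copies_per_haplotype)
    if len(copies) != genome.ploidy or any(c < 0 for c in copies):
        raise ConfigError("copies_per_haplotype must give a count >= 0 per haplotype")

    ci = genome.chromosomes.index(chromosome)
    seed = genome.spec.seed if genome.spec is not None else 0
    rng = _chrom_rng(seed, ci, stream=1)
    unit = random_sequence(unit_len, rng)
    ref_copies = copies[genome.reference_haplotype - 1]
    ins = unit * ref_copies
    new_ref = ref[:pos] + ins + ref[pos:]

    shifted: List[TruthVariant] = []
    for v in genome.variants:
        if v.chromosome == chromosome and v.pos >= pos:
            shifted.append(replace(v, pos=v.pos + len(ins)))
        else:
            shifted.append(v)

    for hap in range(1, genome.ploidy + 1):
        delta = copies[hap - 1] - ref_copies
        if delta == 0 or hap == genome.reference_haplotype:
            continue
        if delta > 0:
            anchor = pos + len(ins) - 1
            ref_a = new_ref[anchor]
            alt_a = ref_a + unit * delta
        else:
            anchor = pos - 1
            ref_a = new_ref[anchor:anchor + unit_len * (-delta) + 1]
            alt_a = new_ref[anchor]
        shifted.append(TruthVariant(
            chromosome=chromosome, pos=anchor, ref_allele=ref_a,
            alt_allele=alt_a, carrier_haplotypes=frozenset({hap}),
            kind="InDel", origin="array"))

    reference = dict(genome.reference)
    reference[chromosome] = new_ref
    masked = list(genome.masked_regions) + [(chromosome, pos, pos + len(ins))]
    return TriploidReference(
        chromosomes=list(genome.chromosomes), reference=reference,
        variants=shifted, ploidy=genome.ploidy,
        reference_haplotype=genome.reference_haplotype,
        telomere_unit=genome.telomere_unit, masked_regions=masked,
        spec=genome.spec)


# ---------------------------------------------------------------------------
# writers

def write_reference_fasta(genome: TriploidReference, path, width: int = 70) -> None:
    """Reference-haplotype-only FASTA, headers ``chrN``."""
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            fh.write(f">{chrom}\n")
            seq = genome.reference[chrom]
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_haplotype_fasta(genome: TriploidReference, path, width: int = 70) -> None:
    """All-haplotype FASTA, headers ``chrN_hapK``."""
    with open(path, "w") as fh:
        for chrom in genome.chromosomes:
            for hap in range(1, genome.ploidy + 1):
                fh.write(f">{chrom}_hap{hap}\n")
                seq = genome.haplotype_sequence(chrom, hap)
                for i in range(0, len(seq), width):
                    fh.write(seq[i:i + width] + "\n")


def write_truth_vcf(genome: TriploidReference, path) -> None:
    """Minimal truth VCF (1-based positions, carriers/origin in INFO)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom in genome.chromosomes:
            fh.write(f"##contig=<ID={chrom},length={len(genome.reference[chrom])}>\n")
        fh.write('##INFO=<ID=CARRIERS,Number=.,Type=Integer,'
                 'Description="1-based haplotype indices carrying ALT">\n')
        fh.write('##INFO=<ID=ORIGIN,Number=1,Type=String,'
                 'Description="Generating mutation process">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for v in sorted(genome.variants,
                        key=lambda v: (genome.chromosomes.index(v.chromosome), v.pos)):
            carriers = ",".join(str(h) for h in sorted(v.carrier_haplotypes))
            fh.write(f"{v.chromosome}\t{v.pos + 1}\t.\t{v.ref_allele}\t"
                     f"{v.alt_allele}\t.\tPASS\t"
                     f"CARRIERS={carriers};ORIGIN={v.origin};KIND={v.kind}\n")


def write_masked_bed(genome: TriploidReference, path) -> None:
    """Masked repetitive regions as 0-based half-open BED."""
    with open(path, "w") as fh:
        for chrom, start, end in genome.masked_regions:
            fh.write(f"{chrom}\t{start}\t{end}\trepeat_array\n")
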