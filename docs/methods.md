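# Methods

## Genome model

The synthetic reference emulates a triploid, six-chromosome asexual yeast.
Each chromosome is an iid random base string (default uniform 25% per
base, so the TaqI motif TCGA occurs once per 4⁴ = 256 bp in expectation;
real genomes have different GC content, and `base_probs` is configurable)
capped with telomeric repeats: 5–20 tandem copies of `GGGTGTCT` on the
right end and of its reverse complement on the left, drawn per chromosome.
Desk-scale chromosomes default to 300 kb — long enough that every event
class fits with safety margins, short enough that a full
simulate-and-detect cycle takes seconds.

Haplotype structure follows the "two-alike" pattern: two of the three
alleles carry near-identical SNV/InDel patterns while the third diverges.
Haplotype 1 is the alignment/reporting reference.  Two mutation processes
run at `het_snv_rate` = 2×10⁻³ SNVs/bp and `het_indel_rate` = 2×10⁻⁴
InDels/bp each: one shared by the alike pair, one private to the divergent
haplotype.  Truth variants are normalized so the reference string always
carries the ref allele; against reference haplotype 1 both processes
produce records whose alt allele sits on the divergent haplotype (dosage
1 of 3), with the generating process kept in an `origin` field.  This
normalization is what a variant caller on real data would see; the
consequence — that recombination between the two identical haplotypes is
invisible — is a property of the biology being modeled, and the event
sampler therefore always pairs the divergent haplotype with one of the
alike pair for homologous events.  Truth InDels are ≤ 10 bp and variants
are kept ≥ 12 bp apart so anchored alleles never overlap.  An optional
rDNA-like tandem array can be planted with per-haplotype copy numbers; its
interval is recorded as a masked region that the callers exclude, and
events touching it are annotated "Around rDNA" and flagged imprecise.

## Rearrangement model

A mutant chromosome is a *molecule*: an ordered list of oriented reference
intervals.  Copy number, allele dosage and novel adjacencies are computed
purely from segment lists; sequence realization is a view that substitutes
haplotype variants into reference slices.  TaqI chemistry is modeled as a
cut between T and CGA with religation regenerating the site: an event at
site offset p cuts the reference at p+1, so every junction created by
end-joining realizes `...T + CGA...` and carries an intact TCGA — the
motif signature used downstream.  No junction scars are added by default.

Event semantics: reciprocal translocations exchange molecule tails
(conserving total bp); the nonreciprocal mode keeps one product and the
truncated partner, discarding the acentric tail.  Deletions remove
[p+1, q+1).  BIR rewrites a molecule from the breakpoint to the
chromosome end with the donor haplotype (copy-neutral, terminal dosage
shift, no clipped-read signal because the joint is reference-contiguous);
gene conversion does the same interstitially.  Aneuploidy appends a full
molecule copy; partial duplication appends a telomere-capped terminal
fragment.  Events are specified in original reference coordinates and may
not overlap a previously rearranged interval, which keeps the truth
functions exact without liftover chaining.

The scenario sampler draws breakpoints uniformly from TaqI sites that have
no truth variant within 100 bp (the site is then intact on every
haplotype).  It enforces one copy-number event per chromosome, a 25 kb
margin between events (larger than the 20 kb tract-merging gap, so
adjacent tracts cannot fuse), and optionally a minimum number of het
sites inside dosage-visible tracts (the demo uses 10), making the default
scenario unambiguous by construction.  Event size ranges scale with
chromosome length; at 300 kb they are deletions 10–70 kb, conversions
2–10 kb, BIR tails 50–120 kb, duplicated arms 40–90 kb, translocation
tails 50–250 kb.

## Evidence model

The detectors consume an `EvidenceSet` — never raw reads — so the calling
layer is testable without an aligner.  Simulated evidence: window depth is
Poisson at rate `depth_per_copy × truth copy number`, drawn at
read-length granularity (150 bp); allele counts at truth het SNV sites are
Binomial(Poisson site depth, dosage/CN) with a symmetric base-flip error
(default 1%); each novel adjacency emits Poisson(depth_per_copy × carrier
molecules × junction_capture) clip records at the exact breakends, with
optional positional jitter (default 0 — breakend extraction from a clean
aligner is base-precise; jitter exists to test clustering tolerance).
Defaults: 30× per copy (≈90× per locus in the triploid; the real
experiments sequenced far deeper), 5 kb windows, junction capture 0.5.

Real data enter through `ingest_sam`: coverage from aligned spans,
breakends from CIGAR soft clips ≥ 20 bp (partner resolved from the first
SA-tag entry when present), allele counts from base pileups at VCF het
sites, all filtered at mapping quality ≥ 20.  The clip-length and mapq
floors are common split-read-calling practice, surfaced in the config; the
original procedure's exact values are unpublished.  Coordinates are
0-based half-open internally; a right-clip breakend sits one past the last
aligned base, a left-clip at the first aligned base.

## Detection

**Junctions.**  Breakend observations are single-linkage clustered per
(chromosome, side) with gap ≤ 10 bp and support ≥ 3; clusters linked by
reads carrying both breakends are paired (ties resolved by shared support,
then distance; pairing must be mutual).  Classification is a pure function
of geometry: different chromosomes ⇒ translocation-type; same chromosome
with right-clip upstream of left-clip and span ≥ 1 kb ⇒ deletion-type
(smaller spans are left to small-variant territory); equal sides ⇒
inversion-type; inverted order ⇒ duplication-type.  Each breakpoint is
annotated with TCGA presence within ±5 bp on the reference — checking the
reference rather than a junction consensus mirrors the published
extraction step, and the motif's palindromy makes the check strand-free.
The default filter requires the motif at ≥ 1 breakend.

**Copy number.**  Per-window mutant/WT depth ratios are divided by the
genome-wide median ratio, so copy-neutral sits at 1 regardless of library
depths; this assumes a copy-neutral majority of windows, which holds
whenever at most a minority of the genome is aneuploid.  Integer states
are `round(ploidy × ratio)` clipped to [0, 2·ploidy]; equal adjacent
windows merge, runs shorter than `min_windows` (2) are absorbed into the
nearest-ratio flank, and missing windows are bridged when both flanks
agree.  A deliberately transparent rounding segmentation was chosen over
change-point methods: the quantity of interest is an integer state at
≈ 30-fold per-copy depth, where the per-window ratio noise (≲ 2%) is far
from the 1/(2·ploidy) decision boundary.  Gains covering ≥ 95% of a
chromosome are reported as aneuploidy ("Whole chromosome ..."), terminal
gains ≥ 10% of the chromosome as partial duplication, losses as deletion.

**Dosage tracts.**  At each het site with ≥ 10 reads in both samples, the
WT class k ∈ {1..ploidy−1} and mutant class k′ ∈ {0..local CN} are chosen
by binomial maximum likelihood with error-adjusted class fractions.  A
site is *shifted* when the class fractions differ and the best class beats
the runner-up by ≥ 2 nats in both samples; the two-sided margin
requirement suppresses borderline-count false shifts, whose rate would
otherwise be ~10⁻³ per site at 90× and can extend tract boundaries.  Runs
of shifted sites with gaps ≤ 20 kb and ≥ 5 sites become tracts, with
bounds refined to the nearest flanking TaqI site within the gap.  Tracts
mostly inside a copy-loss segment are the dosage footprint of that
deletion (LOH-deletion; the CN caller owns the event); tracts inside gains
are the trivial footprint of the gain and are dropped; copy-neutral tracts
are BIR when they reach a chromosome end within 2 windows (10 kb) or
terminate at a junction-supported breakend, else GCV.  The run-length rule
replaces genome-wide multiple-testing correction — tract contiguity is the
signal — which is a documented limitation for isolated single-site events.

## Reporting and scoring

Report rows use 1-based inclusive coordinates and the closed vocabulary
Translocation / Deletion / Aneuploidy / Partial duplication / Break
induced repair / Gene conversion / SNV / InDel; whole-chromosome rows
leave positions blank.  A deletion seen by several evidence tiers emits
one row, junction coordinates taking precedence over CN windows over
tract bounds.  Reciprocal translocations are reported per novel adjacency
(two rows), since both products carry a detectable junction.  Scoring
matches calls to analytic truth greedily by type and nearest breakpoints
within a tolerance (default 25 kb, chosen above the worst-case tract-bound
error); unmatched calls/truth count as false positives/negatives, and
coordinate-compatible type mismatches populate a confusion matrix.

## Determinism and problem sizes

All randomness flows from one integer seed: the forge uses it directly
(with per-chromosome child streams, so adding chromosomes never reshuffles
earlier ones), event sampling uses seed+1, evidence simulation seed+2.
Identical seeds give byte-identical outputs, and the staged CLI reproduces
the one-shot pipeline bit-for-bit.  The shipped test suite and the
reproduction script run the full scenario at six 300 kb chromosomes and
30× per copy — a scale at which every statistical check (binomial motif
intervals, 4σ variant counts, CLT ratio bounds, exact-enumeration dosage
error bounds) retains comfortable margins while a complete run stays
within seconds.

## What the simulation does and does not show

Passing the recovery tests demonstrates that the detector logic is correct
on evidence matching its own model: Poisson coverage, binomial allele
counts, exact breakends, events at clean TaqI sites, and a well-separated
event scenario.  Real resequencing adds alignment artifacts, GC and
mappability bias, duplicated and repetitive regions beyond the single
modeled rDNA-like array, overlapping or clustered events, and
sub-clonal states — none of which the synthetic evidence contains.  The
SAM ingestion path exists precisely so the same callers can be pointed at
real alignments, but accuracy there is bounded by those unmodeled effects.
Small-variant discovery is intentionally out of scope: the het-site list
comes from the simulator's truth table or a user-supplied VCF.
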