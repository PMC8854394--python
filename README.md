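# taqing

Simulation and detection of restriction-enzyme-induced genome
rearrangements in a triploid industrial yeast.

Transient activation of the TaqI endonuclease inside living cells cuts the
genome at its 4-bp palindromic recognition site TCGA (one site every
4⁴ = 256 bp under uniform base usage) and lets repair re-join the pieces.
In an asexual, triploid yeast such as torula yeast (*Cyberlindnera
jadinii*), this produces strains carrying translocations, large deletions,
break-induced repairs (BIR), gene conversions (GCV), aneuploidies and
partial duplications — without introducing any foreign DNA.  Detecting
those events from short-read resequencing of a mutant against its parent
rests on three signals:

- **novel adjacencies** — soft-clipped/split reads whose two ends map to
  discordant reference positions; religation of TaqI cuts (`T^CGA`)
  regenerates an intact TCGA spanning the junction, so true junctions carry
  the motif at the breakpoint;
- **copy number** — the mutant/WT depth ratio, median-normalized, rounded
  to integer copy states `round(ploidy × ratio)`;
- **allele dosage** — at a heterozygous site in a triploid the alt-read
  fraction sits near k/3; homologous repair (BIR, GCV) moves a site from
  k/3 to k′/3 without changing depth, so runs of dosage-shifted sites mark
  copy-neutral recombination tracts (terminal ⇒ BIR, interstitial ⇒ GCV).

The package implements all three detectors plus a fully analytic simulator
to drive them: a synthetic triploid genome with telomeric `GGGTGTCT`
repeats and a "two alleles alike, one divergent" haplotype structure, a
segment-list representation of rearranged chromosomes (so copy number,
dosage and adjacencies are exact bookkeeping, never approximations), a
statistical sequencing-evidence model, a virtual pulsed-field-gel
karyotype, and a report layer producing per-mutant event tables in the
standard published format.  A packaged copy of the published AG4/AG9 event
table is included for count-level checks, along with two wet-lab utility
formulas (β-galactosidase activity `OD420/(T×V×OD600)` with T = 15 min,
V = 1.144 ml, and CFU viability normalization).

## Worked example

```sh
taqing demo --seed 42 --out demo_out
```

runs the default scenario — six 300 kb triploid chromosomes, 30×/copy
sequencing, and one event scenario containing 1 translocation, 2 deletions
(10–70 kb), 2 BIRs, 3 gene conversions (2–10 kb), 1 aneuploidy and
1 partial duplication — then detects everything back and scores the calls
against the analytic truth.  It prints:

```
precision	1.000000
recall	1.000000
```

and exits nonzero if recovery is imperfect.  `demo_out/` contains the
reference and haplotype FASTA, truth variant VCF, truth adjacency BEDPE,
evidence TSVs, junction calls (BEDPE), copy-number segments, dosage
tracts, and the final event table, e.g.:

```
Mutant ID  Start chrom  Start pos  End chrom  End pos  Type                  Note                Imprecise
demo       chr1         206268     chr3       163585   Translocation                             0
demo       chr2         110774     chr2       145658   Deletion                                  0
demo       chr4                    chr4                Aneuploidy            Whole chromosome 4  0
demo       chr5         210001     chr5       300000   Partial duplication                       0
demo       chr2         235048     chr2       299536   Break induced repair                      0
demo       chr1         35620      chr1       40266    Gene conversion                           0
...
```

Translocation and deletion rows come from clipped-read junctions
(base-precise, TCGA at both breakpoints); the aneuploidy and partial
duplication from the depth-ratio segmentation; BIR/GCV rows from
dosage-shift tracts.  The same stages are available separately as
`taqing forge | mutate | observe | ingest | call | report | score`, and
`ingest` accepts real coordinate-sorted SAM/BAM plus a het-site VCF in
place of the simulator.

The library surface mirrors the CLI: `taqing.generate_reference`,
`taqing.sample_events` / `apply_event`, `taqing.simulate_evidence`,
`taqing.call_junctions`, `taqing.segment_cn` / `call_tracts`, and
`taqing.compile_event_table`.  See `docs/methods.md` for the model and its
assumptions.

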