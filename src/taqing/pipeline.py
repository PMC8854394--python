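"""Forge -> mutate -> observe -> call -> report, as replayable stages.

All randomness flows from one root seed with documented per-stage offsets:
the genome forge uses ``seed``, event sampling ``seed + 1``, and evidence
simulation ``seed + 2``.  Each stage writes plain-text files so any stage
can be rerun or swapped for real data.
"""

from __future__ import annotations

import logging
import os
import time
from dataclasses import dataclass, field
from typing import Dict, List, Optional

from . import dosage_caller as dc
from . import evidence_layer as el
from . import genome_forge as gf
from . import junction_caller as jc
from . import reporter as rp
from . import taq_simulator as ts
from .config import DEFAULTS, load_config, write_config

log = logging.getLogger("taqing")

SEED_OFFSET_EVENTS = 1
SEED_OFFSET_EVIDENCE = 2


@dataclass
class PipelineResult:
    config: Dict
    reference: gf.TriploidReference
    wild_type: ts.MutantGenome
    events: List[ts.EventSpec]
    mutant: ts.MutantGenome
    evidence: el.EvidenceSet
    junctions: List[jc.JunctionCall]
    cn_segments: List[dc.CNSegment]
    cn_events: List[dc.CNEvent]
    tracts: List[dc.TractCall]
    records: List[rp.EventRecord]
    truth: List[rp.EventRecord]
    score: rp.ScoreReport
    outputs: Dict[str, str] = field(default_factory=dict)


def genome_spec_from_config(cfg: Dict, seed: int) -> gf.GenomeSpec:
    g = cfg["genome"]
    return gf.GenomeSpec(
        n_chromosomes=g["n_chromosomes"],
        chrom_lengths=(g["chrom_length"],) * g["n_chromosomes"],
        ploidy=g["ploidy"], base_probs=tuple(g["base_probs"]),
        het_snv_rate=g["het_snv_rate"], het_indel_rate=g["het_indel_rate"],
        pattern=g["pattern"], telomere_unit=g["telomere_unit"],
        telomere_units=tuple(g["telomere_units"]), seed=seed)


def forge_stage(cfg: Dict, seed: int) -> gf.TriploidReference:
    t0 = time.perf_counter()
    ref = gf.generate_reference(genome_spec_from_config(cfg, seed))
    log.info("forge: %d chromosomes x %d haplotypes, %d truth variants "
             "(%.1fs)", len(ref.chromosomes), ref.ploidy, len(ref.variants),
             time.perf_counter() - t0)
    return ref


def mutate_stage(cfg: Dict, ref: gf.TriploidReference, seed: int):
    wt = ts.MutantGenome.wild_type(ref)
    ev_cfg = dict(cfg["events"])
    min_het = ev_cfg.pop("min_het_sites")
    counts = {k: v for k, v in ev_cfg.items()}
    ranges = ts.scaled_size_ranges(cfg["genome"]["chrom_length"])
    events = ts.sample_events(wt, counts, size_ranges=ranges,
                              seed=seed + SEED_OFFSET_EVENTS,
                              min_het_sites=min_het)
    mut = ts.apply_events(wt, events)
    log.info("mutate: %d events applied, %d molecules", len(events),
             len(mut.molecules))
    return wt, events, mut


def observe_stage(cfg: Dict, wt: ts.MutantGenome, mut: ts.MutantGenome,
                  seed: int) -> el.EvidenceSet:
    e = cfg["evidence"]
    ev = el.simulate_evidence(
        wt, mut, depth_per_copy=e["depth_per_copy"], window=e["window"],
        error_rate=e["error_rate"], junction_capture=e["junction_capture"],
        read_length=e["read_length"], jitter=e["jitter"],
        seed=seed + SEED_OFFSET_EVIDENCE)
    log.info("observe: %d allele sites, %d clip records", len(ev.alleles),
             len(ev.clips))
    return ev


def call_stage(cfg: Dict, ref: gf.TriploidReference, evidence: el.EvidenceSet,
               mutant_id: str = "demo"):
    j, d = cfg["junction"], cfg["dosage"]
    ploidy = ref.ploidy
    junctions = jc.call_junctions(
        evidence.clips, ref.reference, max_gap=j["max_gap"],
        min_support=j["min_support"], min_size=j["min_size"],
        motif_window=j["motif_window"], require_motif=j["require_motif"])
    ratio = dc.normalize_ratio(evidence.coverage_mut, evidence.coverage_wt,
                               ref.masked_regions)
    cn_segments = dc.segment_cn(ratio, ploidy, d["min_windows"])
    chrom_lengths = {c: len(ref.reference[c]) for c in ref.chromosomes}
    cn_events = dc.call_cn_events(cn_segments, chrom_lengths, ploidy,
                                  d["arm_fraction"])
    sites = dc.classify_sites(
        evidence.alleles, cn_segments, ploidy,
        error_rate=cfg["evidence"]["error_rate"], min_depth=d["min_depth"],
        margin_threshold=d["margin_threshold"])
    taqi_pos = {c: ts.taqi_sites(ref.reference[c]) for c in ref.chromosomes}
    raw_tracts = dc.call_tracts(sites, d["max_gap"], d["min_sites"], taqi_pos)
    tracts = []
    for t in raw_tracts:
        call = dc.classify_tract(t, cn_segments, junctions,
                                 chrom_lengths[t[0]], ploidy,
                                 d["end_tolerance"], ref.masked_regions)
        if call is not None:
            tracts.append(call)
    records = rp.compile_event_table(junctions, cn_events, tracts,
                                     mutant_id=mutant_id)
    log.info("call: %d junctions, %d CN events, %d tracts -> %d rows",
             len(junctions), len(cn_events), len(tracts), len(records))
    return junctions, cn_segments, cn_events, tracts, records, ratio


def run_demo(seed: int = 42, outdir: Optional[str] = None,
             config_path: Optional[str] = None,
             overrides: Optional[Dict] = None) -> PipelineResult:
    """End-to-end default scenario: every rearrangement class, then detect.

    Returns the full in-memory result; when ``outdir`` is given, writes
    FASTA/truth/evidence/calls/report files plus the effective config.
    """
    cfg = load_config(config_path, overrides)
    ref = forge_stage(cfg, seed)
    wt, events, mut = mutate_stage(cfg, ref, seed)
    evidence = observe_stage(cfg, wt, mut, seed)
    junctions, cn_segments, cn_events, tracts, records, ratio = \
        call_stage(cfg, ref, evidence)
    truth = rp.truth_event_records(events, mut, mutant_id="demo")
    score = rp.score_against_truth(records, truth,
                                   cfg["score"]["pos_tolerance"])
    log.info("score: precision %.3f recall %.3f mean |bp error| %.1f",
             score.precision, score.recall, score.mean_abs_bp_error)

    outputs: Dict[str, str] = {}
    if outdir is not None:
        os.makedirs(outdir, exist_ok=True)

        def p(name: str) -> str:
            outputs[name] = os.path.join(outdir, name)
            return outputs[name]

        write_config({**cfg, "seed": seed}, p("effective_config.yaml"))
        gf.write_reference_fasta(ref, p("reference.fasta"))
        gf.write_haplotype_fasta(ref, p("haplotypes.fasta"))
        gf.write_truth_vcf(ref, p("truth_variants.vcf"))
        gf.write_masked_bed(ref, p("masked.bed"))
        ts.write_events_tsv(events, p("truth_events_specs.tsv"))
        ts.write_adjacencies_bedpe(mut, p("truth_adjacencies.bedpe"))
        ts.write_karyotype_tsv(ts.virtual_pfge(mut), p("karyotype_mut.tsv"))
        ts.write_karyotype_tsv(ts.virtual_pfge(wt), p("karyotype_wt.tsv"))
        el.write_evidence(evidence, os.path.join(outdir, "evidence"))
        for suffix in (".coverage.tsv", ".alleles.tsv", ".clips.tsv",
                       ".meta.json"):
            outputs["evidence" + suffix] = os.path.join(
                outdir, "evidence" + suffix)
        jc.write_calls_bedpe(junctions, p("junctions.bedpe"))
        dc.write_cn_segments_bed(cn_segments, p("cn_segments.bed"))
        dc.write_tracts_bed(tracts, p("tracts.bed"))
        rp.write_event_table(records, p("events.tsv"))
        rp.write_event_table(truth, p("truth_events.tsv"))
        with open(p("score.txt"), "w") as fh:
            fh.write(f"precision\t{score.precision:.6f}\n"
                     f"recall\t{score.recall:.6f}\n"
                     f"mean_abs_bp_error\t{score.mean_abs_bp_error:.2f}\n"
                     f"tp\t{score.n_tp}\nfp\t{score.n_fp}\nfn\t{score.n_fn}\n")

    return PipelineResult(
        config=cfg, reference=ref, wild_type=wt, events=events, mutant=mut,
        evidence=evidence, junctions=junctions, cn_segments=cn_segments,
        cn_events=cn_events, tracts=tracts, records=records, truth=truth,
        score=score, outputs=outputs)
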