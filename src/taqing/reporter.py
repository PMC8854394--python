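"""Event tables, summary counts, truth scoring, and two assay formulas.

The report row format mirrors the published per-mutant rearrangement
tables: 1-based inclusive coordinates, a closed type vocabulary
(Translocation, Deletion, Aneuploidy, Partial duplication, Break induced
repair, Gene conversion, SNV, InDel), and a free-text note column
("Around rDNA", "Whole chromosome ...", allele strings).  Internally every
coordinate is 0-based half-open; conversion happens only here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .dosage_caller import CNEvent, TractCall
from .errors import InputError, VocabularyError
from .junction_caller import JunctionCall
from .taq_simulator import EventSpec, MutantGenome, truth_adjacencies

EVENT_TYPES = ("Translocation", "Deletion", "Aneuploidy",
               "Partial duplication", "Break induced repair",
               "Gene conversion", "SNV", "InDel")
_TYPE_ORDER = {t: i for i, t in enumerate(EVENT_TYPES)}

_HEADER = ("Mutant ID\tStart chrom\tStart pos\tEnd chrom\tEnd pos\t"
           "Type\tNote\tImprecise")


@dataclass(frozen=True)
class EventRecord:
    mutant_id: str
    chrom_start: str
    pos_start: Optional[int]   # 1-based; None for whole-chromosome rows
    chrom_end: str
    pos_end: Optional[int]
    type: str
    note: str = ""
    imprecise: bool = False

    def __post_init__(self):
        if self.type not in EVENT_TYPES:
            raise VocabularyError(f"unknown event type {self.type!r}")
        for p in (self.pos_start, self.pos_end):
            if p is not None and p < 1:
                raise VocabularyError("positions must be >= 1 (1-based)")


@dataclass
class ScoreReport:
    precision: float
    recall: float
    mean_abs_bp_error: float
    n_tp: int
    n_fp: int
    n_fn: int
    confusion: Dict[Tuple[str, str], int] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# coordinate conversion helpers (single, tested functions)

def breakend_to_1based(breakend: Tuple[str, int, str]) -> int:
    """1-based position of the last/first aligned base at a breakend.

    A right-clip breakend at 0-based half-open position p means the last
    aligned base is p-1 (0-based) = p (1-based); a left-clip breakend at p
    means the first aligned base is p (0-based) = p+1 (1-based).
    """
    _chrom, pos, side = breakend
    return pos if side == "right" else pos + 1


def interval_to_1based(start0: int, end0: int) -> Tuple[int, int]:
    """0-based half-open [start, end) -> 1-based inclusive (start, end)."""
    return start0 + 1, end0


# ---------------------------------------------------------------------------
# table compilation

def _junction_records(junctions: Iterable[JunctionCall], mutant_id: str
                      ) -> List[EventRecord]:
    out: List[EventRecord] = []
    for call in junctions:
        if call.imprecise or call.breakend_b is None:
            continue
        a, b = call.breakend_a, call.breakend_b
        if call.klass == "translocation-type":
            out.append(EventRecord(
                mutant_id, a[0], breakend_to_1based(a),
                b[0], breakend_to_1based(b), "Translocation"))
        elif call.klass == "deletion-type":
            right, left = (a, b) if a[2] == "right" else (b, a)
            # deleted tract: first missing base .. last missing base
            out.append(EventRecord(
                mutant_id, right[0], right[1] + 1, left[0], left[1],
                "Deletion"))
    return out


def _cn_records(cn_events: Iterable[CNEvent], mutant_id: str
                ) -> List[EventRecord]:
    out = []
    for ev in cn_events:
        if ev.kind == "Aneuploidy":
            out.append(EventRecord(mutant_id, ev.chromosome, None,
                                   ev.chromosome, None, "Aneuploidy",
                                   note=ev.note))
        elif ev.kind in ("Deletion", "Partial duplication"):
            s1, e1 = interval_to_1based(ev.start, ev.end)
            out.append(EventRecord(mutant_id, ev.chromosome, s1,
                                   ev.chromosome, e1, ev.kind, note=ev.note))
        # interstitial duplications have no printed-table counterpart;
        # reported as Partial duplication rows with a note
        elif ev.kind == "Interstitial duplication":
            s1, e1 = interval_to_1based(ev.start, ev.end)
            out.append(EventRecord(mutant_id, ev.chromosome, s1,
                                   ev.chromosome, e1, "Partial duplication",
                                   note="Interstitial"))
    return out


def _tract_records(tracts: Iterable[TractCall], mutant_id: str
                   ) -> List[EventRecord]:
    kind_map = {"BIR": "Break induced repair", "GCV": "Gene conversion",
                "LOH-deletion": "Deletion"}
    out = []
    for t in tracts:
        out.append(EventRecord(
            mutant_id, t.chromosome, t.start + 1, t.chromosome, t.end + 1,
            kind_map[t.kind], note=t.note, imprecise=t.imprecise))
    return out


def _overlap_frac(a: EventRecord, b: EventRecord) -> float:
    if a.chrom_start != b.chrom_start or None in (a.pos_start, a.pos_end,
                                                  b.pos_start, b.pos_end):
        return 0.0
    inter = min(a.pos_end, b.pos_end) - max(a.pos_start, b.pos_start) + 1
    if inter <= 0:
        return 0.0
    return inter / max(a.pos_end - a.pos_start + 1,
                       b.pos_end - b.pos_start + 1)


def compile_event_table(junctions: Sequence[JunctionCall] = (),
                        cn_events: Sequence[CNEvent] = (),
                        tracts: Sequence[TractCall] = (),
                        small_variants: Sequence[EventRecord] = (),
                        mutant_id: str = "mutant") -> List[EventRecord]:
    """Merge all caller outputs into a deduplicated, sorted event table.

    A deletion seen by several evidence tiers emits one row; junction
    coordinates take precedence over CN segmentation over dosage tracts
    (junction breakpoints are base-precise, windows are not).
    """
    jr = _junction_records(junctions, mutant_id)
    cr = _cn_records(cn_events, mutant_id)
    tr = _tract_records(tracts, mutant_id)

    # deduplicate Deletion rows across evidence tiers by reciprocal overlap
    deletions: List[Tuple[int, EventRecord]] = []  # (precedence, record)
    others: List[EventRecord] = []
    for prec, records in ((0, jr), (1, cr), (2, tr)):
        for r in records:
            if r.type == "Deletion":
                deletions.append((prec, r))
            else:
                others.append(r)
    merged: List[EventRecord] = []
    deletions.sort(key=lambda pr: pr[0])
    for prec, r in deletions:
        dup = next((m for m in merged
                    if m.type == "Deletion" and _overlap_frac(m, r) >= 0.5),
                   None)
        if dup is None:
            merged.append(r)
    records = merged + others + list(small_variants)
    records.sort(key=lambda r: (r.mutant_id, _TYPE_ORDER[r.type],
                                r.chrom_start, r.pos_start or 0))
    return records


def summarize_counts(records: Sequence[EventRecord]
                     ) -> Dict[Tuple[str, str], int]:
    """Exact counts per (mutant id, type), zero-filled over the vocabulary."""
    mutants = sorted({r.mutant_id for r in records})
    counts = {(m, t): 0 for m in mutants for t in EVENT_TYPES}
    for r in records:
        counts[(r.mutant_id, r.type)] += 1
    return counts


# ---------------------------------------------------------------------------
# truth scoring

def truth_event_records(events: Sequence[EventSpec], genome: MutantGenome,
                        mutant_id: str = "truth") -> List[EventRecord]:
    """Expected report rows for a simulated scenario, derived analytically.

    Junction-borne events are expressed through the same breakend -> 1-based
    conversion the detector output uses, so a perfect detector scores
    zero breakpoint error.  Reciprocal translocations yield one row per
    novel adjacency (both products carry a detectable junction).
    """
    ref = genome.reference
    out: List[EventRecord] = []
    for ev in events:
        chrom = genome.molecule(ev.target_molecule).segments[0].chromosome \
            if ev.kind != "PARTIAL_DUP" else None
        if ev.kind == "TL":
            partner_chrom = genome.molecule(ev.partner_molecule).segments[0].chromosome
            pairs = [((chrom, ev.pos_a + 1, "right"),
                      (partner_chrom, ev.pos_b + 1, "left"))]
            if ev.reciprocal:
                pairs.append(((partner_chrom, ev.pos_b + 1, "right"),
                              (chrom, ev.pos_a + 1, "left")))
            for be_pair in pairs:
                a, b = sorted(be_pair)
                out.append(EventRecord(
                    mutant_id, a[0], breakend_to_1based(a),
                    b[0], breakend_to_1based(b), "Translocation"))
        elif ev.kind == "DEL":
            out.append(EventRecord(mutant_id, chrom, ev.pos_a + 2,
                                   chrom, ev.pos_b + 1, "Deletion"))
        elif ev.kind == "BIR":
            L = len(ref.reference[chrom])
            out.append(EventRecord(mutant_id, chrom, ev.pos_a + 1, chrom, L,
                                   "Break induced repair"))
        elif ev.kind == "GCV":
            out.append(EventRecord(mutant_id, chrom, ev.pos_a + 1,
                                   chrom, ev.pos_b, "Gene conversion"))
        elif ev.kind == "ANEUPLOIDY":
            num = chrom.lstrip("chr")
            out.append(EventRecord(mutant_id, chrom, None, chrom, None,
                                   "Aneuploidy",
                                   note=f"Whole chromosome {num}"))
        elif ev.kind == "PARTIAL_DUP":
            d_chrom = genome.molecule(ev.partner_molecule).segments[0].chromosome
            L = len(ref.reference[d_chrom])
            out.append(EventRecord(mutant_id, d_chrom, ev.pos_a + 1,
                                   d_chrom, L, "Partial duplication"))
    return out


def _record_distance(a: EventRecord, b: EventRecord) -> float:
    if (a.chrom_start, a.chrom_end) != (b.chrom_start, b.chrom_end):
        return math.inf
    if a.pos_start is None or b.pos_start is None:
        return 0.0 if (a.pos_start is None) == (b.pos_start is None) else math.inf
    return (abs(a.pos_start - b.pos_start) + abs(a.pos_end - b.pos_end)) / 2


def score_against_truth(records: Sequence[EventRecord],
                        truth: Sequence[EventRecord],
                        pos_tolerance: int = 25_000) -> ScoreReport:
    """Greedy matching by type then nearest breakpoints within tolerance.

    Unmatched calls count as false positives and unmatched truth rows as
    false negatives; leftover coordinate-compatible pairs with differing
    types populate the off-diagonal of the confusion counts.
    """
    unmatched_calls = list(records)
    unmatched_truth = list(truth)
    confusion: Dict[Tuple[str, str], int] = {}
    errors: List[float] = []
    n_tp = 0

    pairs = []
    for i, r in enumerate(unmatched_calls):
        for j, t in enumerate(unmatched_truth):
            if r.type != t.type:
                continue
            d = _record_distance(r, t)
            if d <= pos_tolerance:
                pairs.append((d, i, j))
    used_i, used_j = set(), set()
    for d, i, j in sorted(pairs):
        if i in used_i or j in used_j:
            continue
        used_i.add(i)
        used_j.add(j)
        n_tp += 1
        errors.append(d)
        t = unmatched_truth[j].type
        confusion[(t, t)] = confusion.get((t, t), 0) + 1
    calls_left = [r for i, r in enumerate(unmatched_calls) if i not in used_i]
    truth_left = [t for j, t in enumerate(unmatched_truth) if j not in used_j]

    for r in calls_left:
        t = next((t for t in truth_left
                  if _record_distance(r, t) <= pos_tolerance), None)
        if t is not None:
            confusion[(t.type, r.type)] = confusion.get((t.type, r.type), 0) + 1

    precision = n_tp / len(records) if records else 1.0
    recall = n_tp / len(truth) if truth else 1.0
    return ScoreReport(
        precision=precision, recall=recall,
        mean_abs_bp_error=float(sum(errors) / len(errors)) if errors else 0.0,
        n_tp=n_tp, n_fp=len(records) - n_tp, n_fn=len(truth) - n_tp,
        confusion=confusion)


# ---------------------------------------------------------------------------
# TSV round trip and the published-table fixture

def write_event_table(records: Sequence[EventRecord], path) -> None:
    with open(path, "w") as fh:
        fh.write(_HEADER + "\n")
        for r in records:
            ps = "" if r.pos_start is None else str(r.pos_start)
            pe = "" if r.pos_end is None else str(r.pos_end)
            fh.write(f"{r.mutant_id}\t{r.chrom_start}\t{ps}\t{r.chrom_end}\t"
                     f"{pe}\t{r.type}\t{r.note}\t{int(r.imprecise)}\n")


def read_event_table(path_or_text) -> List[EventRecord]:
    if isinstance(path_or_text, str) and "\n" in path_or_text:
        lines = path_or_text.splitlines()
    else:
        with open(path_or_text) as fh:
            lines = fh.read().splitlines()
    if not lines or lines[0] != _HEADER:
        raise InputError("event table: unexpected header")
    out = []
    for line in lines[1:]:
        if not line:
            continue
        m, cs, ps, ce, pe, typ, note, imp = line.split("\t")
        out.append(EventRecord(
            mutant_id=m, chrom_start=cs,
            pos_start=int(ps) if ps else None, chrom_end=ce,
            pos_end=int(pe) if pe else None, type=typ, note=note,
            imprecise=bool(int(imp))))
    return out


def load_published_table() -> List[EventRecord]:
    """The packaged fixture of the published AG4/AG9 rearrangement table."""
    text = resources.files("taqing").joinpath("data/published_events.tsv") \
        .read_text()
    return read_event_table(text)


# ---------------------------------------------------------------------------
# wet-lab utility formulas

@dataclass(frozen=True)
class AssayMeasurement:
    od420: float = 0.0
    od600: float = 1.0
    t_minutes: float = 15.0
    v_ml: float = 1.144
    cfu_sample: int = 0
    cfu_control: int = 1

    def validate(self) -> None:
        if self.od420 < 0 or self.od600 < 0:
            raise InputError("absorbances must be >= 0")
        if self.t_minutes <= 0 or self.v_ml <= 0:
            raise InputError("reaction time and volume must be > 0")


def beta_gal_activity(m: AssayMeasurement, slope: float = 1.0,
                      intercept: float = 0.0) -> float:
    """Normalized colorimetric units: OD420 / (T x V x OD600).

    T is the reaction time in minutes (default 15) and V the assay volume
    in ml (default 1.144).  ``slope``/``intercept`` apply an optional
    linear standard-curve conversion to activity units.
    """
    m.validate()
    if m.od600 <= 0:
        raise InputError("od600 must be > 0")
    od = m.od420 / (m.t_minutes * m.v_ml * m.od600)
    return slope * od + intercept


def viability_percent(m: AssayMeasurement) -> float:
    """CFU relative to the untreated control, as a percentage."""
    if m.cfu_control <= 0:
        raise InputError("cfu_control must be > 0")
    return 100.0 * m.cfu_sample / m.cfu_control


def frequency_percent(count: int, total: int) -> float:
    """Percentage of ``count`` events among ``total`` screened."""
    if total <= 0:
        raise InputError("total must be > 0")
    return 100.0 * count / total


def fold_change(value: float, baseline: float) -> float:
    if baseline <= 0:
        raise InputError("baseline must be > 0")
    return value / baseline
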