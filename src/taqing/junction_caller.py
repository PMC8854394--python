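"""Cluster clipped-read breakends into classified junction calls.

The caller follows the chimeric-read logic of split-read SV detection:
breakend observations are single-linkage clustered per (chromosome, clip
side), clusters linked by reads that carry both breakends are paired, and
each pair is classified from chromosome identity, side geometry and
distance.  Breakpoints are annotated with the presence of the TaqI
recognition motif (TCGA) on the reference near the breakend — the signature
of a restriction-cut-and-religated junction.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .errors import CoordinateError
from .evidence_layer import ClippedReadRecord

Breakend = Tuple[str, int, str]


@dataclass(frozen=True)
class BreakendCluster:
    chromosome: str
    pos: int          # median of member positions
    side: str         # "left" | "right"
    support: int

    @property
    def breakend(self) -> Breakend:
        return (self.chromosome, self.pos, self.side)


@dataclass(frozen=True)
class JunctionCall:
    breakend_a: Breakend
    breakend_b: Optional[Breakend]
    support: int
    klass: Optional[str]   # deletion-/translocation-/duplication-/inversion-type
    motif_a: bool = False
    motif_b: bool = False
    imprecise: bool = False


def cluster_breakends(clips: Sequence[ClippedReadRecord], max_gap: int = 10,
                      min_support: int = 3
                      ) -> Tuple[List[BreakendCluster],
                                 Dict[int, Tuple[Optional[int], Optional[int]]]]:
    """Single-linkage clustering of breakend observations per (chrom, side).

    Returns the clusters (coordinate-sorted, support >= min_support) and a
    mapping from clip index to the cluster indices of its two breakends
    (None where the breakend is unknown or its cluster was dropped).
    """
    obs: Dict[Tuple[str, str], List[Tuple[int, int, int]]] = {}
    for ci, clip in enumerate(clips):
        for slot, be in enumerate((clip.breakend_a, clip.breakend_b)):
            if be is None:
                continue
            chrom, pos, side = be
            obs.setdefault((chrom, side), []).append((pos, ci, slot))

    clusters: List[BreakendCluster] = []
    assignment: Dict[Tuple[int, int], int] = {}
    for (chrom, side), members in sorted(obs.items()):
        members.sort()
        run: List[Tuple[int, int, int]] = []

        def flush(run):
            if not run:
                return
            if len(run) >= min_support:
                med = int(np.median([p for p, _, _ in run]))
                idx = len(clusters)
                clusters.append(BreakendCluster(chrom, med, side, len(run)))
                for _, ci, slot in run:
                    assignment[(ci, slot)] = idx
            run.clear()

        for item in members:
            if run and item[0] - run[-1][0] > max_gap:
                flush(run)
            run.append(item)
        flush(run)

    order = sorted(range(len(clusters)),
                   key=lambda i: (clusters[i].chromosome, clusters[i].pos,
                                  clusters[i].side))
    remap = {old: new for new, old in enumerate(order)}
    clusters = [clusters[i] for i in order]
    clip_clusters = {}
    for ci in range(len(clips)):
        a = assignment.get((ci, 0))
        b = assignment.get((ci, 1))
        clip_clusters[ci] = (None if a is None else remap[a],
                             None if b is None else remap[b])
    return clusters, clip_clusters


def _classify(be_a: Breakend, be_b: Breakend, min_size: int) -> str:
    (ca, pa, sa), (cb, pb, sb) = be_a, be_b
    if ca != cb:
        return "translocation-type"
    if sa == sb:
        return "inversion-type"
    # orient: right-clip breakend should sit upstream of the left-clip one
    right, left = (pa, pb) if sa == "right" else (pb, pa)
    if right <= left:
        return "deletion-type" if left - right >= min_size else "small-deletion-type"
    return "duplication-type"


def pair_and_classify(clusters: Sequence[BreakendCluster],
                      clips: Sequence[ClippedReadRecord],
                      min_size: int = 1_000,
                      clip_clusters: Optional[Dict[int, Tuple[Optional[int],
                                                              Optional[int]]]] = None,
                      max_gap: int = 10, min_support: int = 3
                      ) -> List[JunctionCall]:
    """Pair clusters linked by dual-breakend clips and classify the pairs.

    Ties (a cluster linked to several partners) resolve by highest shared
    read support, then nearest coordinate.  Unpaired clusters are emitted
    as imprecise single-breakend calls.
    """
    if clip_clusters is None:
        _clusters, clip_clusters = cluster_breakends(
            clips, max_gap=max_gap, min_support=min_support)
        clusters = _clusters

    pair_support: Dict[Tuple[int, int], int] = {}
    for ci in range(len(clips)):
        a, b = clip_clusters.get(ci, (None, None))
        if a is None or b is None or a == b:
            continue
        key = (min(a, b), max(a, b))
        pair_support[key] = pair_support.get(key, 0) + 1

    partner: Dict[int, Tuple[int, int]] = {}  # cluster -> (partner, support)
    for (a, b), sup in sorted(pair_support.items()):
        for x, y in ((a, b), (b, a)):
            cur = partner.get(x)
            if cur is None:
                partner[x] = (y, sup)
                continue
            dist_new = abs(clusters[x].pos - clusters[y].pos)
            dist_cur = abs(clusters[x].pos - clusters[cur[0]].pos)
            if (sup, -dist_new) > (cur[1], -dist_cur):
                partner[x] = (y, sup)

    calls: List[JunctionCall] = []
    emitted = set()
    for i, cl in enumerate(clusters):
        p = partner.get(i)
        if p is None:
            calls.append(JunctionCall(
                breakend_a=cl.breakend, breakend_b=None,
                support=cl.support, klass=None, imprecise=True))
            continue
        j, sup = p
        # mutual best pairing only; a one-sided preference stays unpaired
        if partner.get(j, (None,))[0] != i:
            calls.append(JunctionCall(
                breakend_a=cl.breakend, breakend_b=None,
                support=cl.support, klass=None, imprecise=True))
            continue
        key = (min(i, j), max(i, j))
        if key in emitted:
            continue
        emitted.add(key)
        a, b = clusters[key[0]], clusters[key[1]]
        calls.append(JunctionCall(
            breakend_a=a.breakend, breakend_b=b.breakend,
            support=sup, klass=_classify(a.breakend, b.breakend, min_size)))
    calls.sort(key=lambda c: (c.breakend_a[0], c.breakend_a[1]))
    return calls


def annotate_taqi_motif(call: JunctionCall, reference: Dict[str, str],
                        window: int = 5) -> JunctionCall:
    """Flag breakends with a TCGA occurrence within +- window bp.

    The check runs on the reference (not a junction consensus): the motif
    is a palindrome, so no strand handling is needed.
    """
    def has_motif(be: Optional[Breakend]) -> bool:
        if be is None:
            return False
        chrom, pos, _side = be
        seq = reference[chrom]
        if not (0 <= pos <= len(seq)):
            raise CoordinateError(f"breakend {chrom}:{pos} outside reference")
        lo = max(0, pos - window - 3)
        hi = min(len(seq), pos + window + 3)
        return "TCGA" in seq[lo:hi]

    return replace(call, motif_a=has_motif(call.breakend_a),
                   motif_b=has_motif(call.breakend_b))


def filter_calls(calls: Sequence[JunctionCall],
                 require_motif: Optional[str] = "any",
                 min_support: int = 1) -> List[JunctionCall]:
    """Keep calls satisfying the motif mode ("any" | "both" | None) and
    the support floor; input order is preserved."""
    out = []
    for c in calls:
        if c.support < min_support:
            continue
        if require_motif == "any" and not (c.motif_a or c.motif_b):
            continue
        if require_motif == "both" and not (c.motif_a and c.motif_b):
            continue
        out.append(c)
    return out


def call_junctions(clips: Sequence[ClippedReadRecord],
                   reference: Dict[str, str], max_gap: int = 10,
                   min_support: int = 3, min_size: int = 1_000,
                   motif_window: int = 5,
                   require_motif: Optional[str] = "any"
                   ) -> List[JunctionCall]:
    """cluster -> pair/classify -> motif-annotate -> filter, in one step."""
    clusters, clip_clusters = cluster_breakends(clips, max_gap, min_support)
    calls = pair_and_classify(clusters, clips, min_size,
                              clip_clusters=clip_clusters)
    calls = [annotate_taqi_motif(c, reference, motif_window) for c in calls]
    precise = [c for c in calls if not c.imprecise]
    return filter_calls(precise, require_motif, min_support) + \
        [c for c in calls if c.imprecise]


def write_calls_bedpe(calls: Sequence[JunctionCall], path) -> None:
    with open(path, "w") as fh:
        fh.write("#chrom_a\tstart_a\tend_a\tchrom_b\tstart_b\tend_b\t"
                 "support\tklass\tmotif_a\tmotif_b\timprecise\n")
        for c in calls:
            ca, pa, sa = c.breakend_a
            cb, pb, sb = c.breakend_b or (".", -1, ".")
            fh.write(f"{ca}\t{pa}\t{pa + 1}\t{cb}\t{pb}\t{pb + 1}\t"
                     f"{c.support}\t{c.klass or 'unpaired'}\t"
                     f"{int(c.motif_a)}\t{int(c.motif_b)}\t{int(c.imprecise)}\n")
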