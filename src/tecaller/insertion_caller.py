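"""Clustering of mapped evidence into TE insertion calls.

Pipeline: classified reads are placed on the reference, coordinate-sorted,
chained into 2 kb windows (clusters), split into per-breakpoint
subclusters, and each subcluster becomes a candidate insertion whose TSD
is the reference interval where left- and right-flank alignments overlap.
Three cleaning rules then remove low-quality candidates, and survivors
with junction evidence on one side plus any evidence on the other are
reported as confident.

A *left* junction is a flank that sits genomically upstream of the
element (its alignment ends at the last base of the first TSD copy); a
*right* junction sits downstream (its alignment starts at the first base
of the second TSD copy).  When both exist and overlap, the overlap is the
TSD.
"""

from __future__ import annotations

import logging
import time
from collections import Counter
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

from .genome_mapper import (GenomeAlignment, GenomeIndex, MapTask,
                            align_to_reference, map_sequences, sort_alignments)
from .io_formats import (AnnotatedRepeat, GffRecord, ReadPair, ReferenceGenome,
                         RunConfig, TELibrary)
from .repeat_matcher import (FULL_TE, JUNCTION, SUPPORTING, TE_3PRIME,
                             TE_5PRIME, ClassifiedRead, LibraryIndex,
                             classify_pair)

logger = logging.getLogger(__name__)

CONFIDENT = "CONFIDENT"
RAW_ONLY = "RAW_ONLY"

__all__ = ["InsertionCluster", "SubCluster", "CandidateInsertion",
           "build_clusters", "refine_subclusters", "call_insertion",
           "apply_filters", "run_pipeline", "PipelineResult",
           "CONFIDENT", "RAW_ONLY"]


@dataclass
class InsertionCluster:
    chrom: str
    start: int
    end: int
    members: List[GenomeAlignment] = field(default_factory=list)


@dataclass
class SubCluster:
    chrom: str
    te_family: str
    left_junctions: List[GenomeAlignment] = field(default_factory=list)
    right_junctions: List[GenomeAlignment] = field(default_factory=list)
    left_support: List[GenomeAlignment] = field(default_factory=list)
    right_support: List[GenomeAlignment] = field(default_factory=list)

    @property
    def breakpoints(self) -> List[int]:
        return ([junction_breakpoint(a) for a in self.left_junctions]
                + [junction_breakpoint(a) for a in self.right_junctions])

    @property
    def center(self) -> int:
        bps = sorted(self.breakpoints)
        return bps[len(bps) // 2]


@dataclass
class CandidateInsertion:
    chrom: str
    start: int               # 0-based half-open; TSD interval when called,
    end: int                 # else a single-base insertion point
    te_family: str
    strand: str              # '+', '-' or '.'
    tsd_seq: Optional[str]   # None when no TSD called
    left_junction: int
    right_junction: int
    left_support: int
    right_support: int
    max_junction_mapq: int
    confidence: str


def junction_is_left(a: GenomeAlignment) -> bool:
    """Genomic side of a junction flank, from read layout and strand."""
    return a.flank_left_of_te == (a.strand == "+")


def junction_breakpoint(a: GenomeAlignment) -> int:
    """0-based breakpoint: last aligned base of a left junction, first of
    a right junction."""
    return a.end - 1 if junction_is_left(a) else a.start


def _te_strand_vote(a: GenomeAlignment) -> str:
    left = junction_is_left(a)
    five = a.te_side == TE_5PRIME
    return "+" if left == five else "-"


def build_clusters(alignments: Sequence[GenomeAlignment],
                   cfg: RunConfig) -> List[InsertionCluster]:
    """Chain coordinate-sorted alignments: a start within ``window_bp`` of
    the running span joins the cluster; clusters without any junction
    alignment are discarded."""
    clusters: List[InsertionCluster] = []
    cur: Optional[InsertionCluster] = None
    for a in alignments:
        if cur is None or a.chrom != cur.chrom or a.start - cur.end > cfg.window_bp:
            cur = InsertionCluster(a.chrom, a.start, a.end, [a])
            clusters.append(cur)
        else:
            cur.members.append(a)
            cur.end = max(cur.end, a.end)
    return [c for c in clusters
            if any(m.category == JUNCTION for m in c.members)]


def refine_subclusters(cluster: InsertionCluster,
                       cfg: RunConfig) -> List[SubCluster]:
    """Group junction alignments by family and breakpoint (within
    ``tsd_slack_bp``), then attach each supporting read to the nearest
    subcluster within ``window_bp``."""
    junctions = [m for m in cluster.members if m.category == JUNCTION]
    supports = [m for m in cluster.members if m.category == SUPPORTING]

    keyed = sorted(junctions,
                   key=lambda a: (a.te_family or "", junction_breakpoint(a)))
    subs: List[SubCluster] = []
    for a in keyed:
        bp = junction_breakpoint(a)
        if (subs and subs[-1].te_family == a.te_family
                and bp - max(subs[-1].breakpoints) <= cfg.tsd_slack_bp):
            pass
        else:
            subs.append(SubCluster(cluster.chrom, a.te_family or ""))
        (subs[-1].left_junctions if junction_is_left(a)
         else subs[-1].right_junctions).append(a)

    if subs:
        centers = [s.center for s in subs]
        for s in supports:
            # distance from the read interval to each subcluster centre
            best_i, best_d = -1, None
            for i, c in enumerate(centers):
                d = max(s.start - c, c - (s.end - 1), 0)
                if best_d is None or d < best_d:
                    best_i, best_d = i, d
            if best_d is not None and best_d <= cfg.window_bp:
                # a '+' supporting read faces the insertion on its right,
                # so it supports the left side, and vice versa
                (subs[best_i].left_support if s.strand == "+"
                 else subs[best_i].right_support).append(s)
    return subs


def _modal(values: List[int], prefer_high: bool) -> int:
    counts = Counter(values)
    best = max(counts.items(),
               key=lambda kv: (kv[1], kv[0] if prefer_high else -kv[0]))
    return best[0]


def call_insertion(sub: SubCluster, ref: ReferenceGenome,
                   cfg: RunConfig) -> CandidateInsertion:
    """Turn one subcluster into a candidate insertion with TSD when both
    flanks overlap.

    The per-side breakpoint is the modal value among that side's junction
    reads (ties resolved outward); a single read whose TE/flank boundary
    is shifted by a base-call error at the junction then cannot distort
    the TSD.
    """
    lj, rj = sub.left_junctions, sub.right_junctions
    bp_left = _modal([junction_breakpoint(a) for a in lj], True) if lj else None
    bp_right = _modal([junction_breakpoint(a) for a in rj], False) if rj else None

    tsd_seq: Optional[str] = None
    if bp_left is not None and bp_right is not None:
        if bp_right <= bp_left:
            start, end = bp_right, bp_left + 1
            tsd_seq = ref.sequences[sub.chrom][start:end]
        else:
            mid = (bp_left + bp_right) // 2
            start, end = mid, mid + 1
    elif bp_left is not None:
        start, end = bp_left, bp_left + 1
    else:
        start, end = bp_right, bp_right + 1

    strand = "."
    if lj and rj:
        votes = {_te_strand_vote(a) for a in lj + rj}
        if len(votes) == 1:
            strand = votes.pop()

    nlj, nrj = len(lj), len(rj)
    nls, nrs = len(sub.left_support), len(sub.right_support)
    confident = ((nlj >= 1 and nrj + nrs >= 1) or (nrj >= 1 and nlj + nls >= 1))
    return CandidateInsertion(
        chrom=sub.chrom, start=start, end=end, te_family=sub.te_family,
        strand=strand, tsd_seq=tsd_seq,
        left_junction=nlj, right_junction=nrj,
        left_support=nls, right_support=nrs,
        max_junction_mapq=max(a.mapq for a in lj + rj),
        confidence=CONFIDENT if confident else RAW_ONLY)


def _near_annotation(c: CandidateInsertion, by_chrom: Dict[str, List[Tuple[int, int]]],
                     prox: int) -> bool:
    for s, e in by_chrom.get(c.chrom, ()):
        if c.start < e + prox and s - prox < c.end:
            return True
    return False


def apply_filters(candidates_by_cluster: Sequence[Sequence[CandidateInsertion]],
                  annotation: Sequence[AnnotatedRepeat],
                  cfg: RunConfig
                  ) -> Tuple[List[CandidateInsertion], List[CandidateInsertion]]:
    """The three cleaning rules.

    (i)  drop candidates whose best junction mapq < ``mapq_min``;
    (iii) drop junction-only candidates (no supporting reads) within
          ``annot_proximity_bp`` of an annotated reference TE;
    (ii) within one cluster window, drop candidates with fewer than
         ``min_cluster_junctions`` junction reads when another candidate
         in the window survives (i) and (iii).
    Returns (confident survivors, all raw candidates).
    """
    by_chrom: Dict[str, List[Tuple[int, int]]] = {}
    for rep in annotation:
        by_chrom.setdefault(rep.chrom, []).append((rep.start, rep.end))

    raw: List[CandidateInsertion] = []
    confident: List[CandidateInsertion] = []
    for group in candidates_by_cluster:
        raw.extend(group)
        eligible = []
        for c in group:
            if c.max_junction_mapq < cfg.mapq_min:
                continue
            if (c.left_support + c.right_support == 0
                    and _near_annotation(c, by_chrom, cfg.annot_proximity_bp)):
                continue
            eligible.append(c)
        for c in eligible:
            if len(eligible) > 1:
                nj = (max(c.left_junction, c.right_junction)
                      if cfg.rule2_per_flank
                      else c.left_junction + c.right_junction)
                if nj < cfg.min_cluster_junctions:
                    continue
            if c.confidence == CONFIDENT:
                confident.append(c)
    key = lambda c: (c.chrom, c.start, c.end, c.te_family)
    return sorted(confident, key=key), sorted(raw, key=key)


# ---------------------------------------------------------------------------
# end-to-end pipeline


@dataclass
class PipelineResult:
    confident: List[CandidateInsertion]
    raw: List[CandidateInsertion]
    summary: Dict[str, object]

    def confident_gff(self) -> List[GffRecord]:
        return [candidate_to_gff(c) for c in self.confident]

    def raw_gff(self) -> List[GffRecord]:
        return [candidate_to_gff(c) for c in self.raw]


def candidate_to_gff(c: CandidateInsertion) -> GffRecord:
    return GffRecord(
        chrom=c.chrom, start=c.start, end=c.end,
        type="transposable_element_insertion_site",
        strand=c.strand if c.strand in "+-" else ".",
        attributes={
            "TE": c.te_family,
            "TSD": c.tsd_seq if c.tsd_seq else "NA",
            "left_junction_reads": str(c.left_junction),
            "right_junction_reads": str(c.right_junction),
            "left_supporting_reads": str(c.left_support),
            "right_supporting_reads": str(c.right_support),
            "status": "confident" if c.confidence == CONFIDENT else "raw_only",
        })


def run_pipeline(pairs: Iterable[ReadPair], library: TELibrary,
                 ref: ReferenceGenome, cfg: Optional[RunConfig] = None,
                 lib_index: Optional[LibraryIndex] = None,
                 genome_index: Optional[GenomeIndex] = None,
                 chunk_size: int = 100_000) -> PipelineResult:
    """Full caller: classify reads, map evidence, cluster, call, filter."""
    cfg = cfg or RunConfig()
    t0 = time.time()
    lib_index = lib_index or LibraryIndex(library, cfg)
    genome_index = genome_index or GenomeIndex(ref)

    pairs = list(pairs)
    n_cat = Counter()
    tasks: List[MapTask] = []
    # junction control: untrimmed read sequences, same order as junction tasks
    control_seqs: List[str] = []
    control_span: List[Tuple[int, int]] = []  # (first task idx, n fragments)

    for lo in range(0, len(pairs), chunk_size):
        chunk = pairs[lo:lo + chunk_size]
        seqs: List[str] = []
        for p in chunk:
            seqs.append(p.seq1)
            seqs.append(p.seq2)
        hits = lib_index.match_batch(seqs)
        for j, p in enumerate(chunk):
            h1, h2 = hits[2 * j], hits[2 * j + 1]
            if not h1 and not h2:
                n_cat["UNINFORMATIVE"] += 2
                continue
            c1, c2 = classify_pair(p, h1, h2, library, cfg)
            for c, seq in ((c1, p.seq1), (c2, p.seq2)):
                n_cat[c.category] += 1
                if c.category == JUNCTION:
                    first = len(tasks)
                    for fr in c.fragments:
                        tasks.append(MapTask(
                            read_id=c.read_id, mate=c.mate, category=JUNCTION,
                            seq=fr.flank_seq, te_family=c.te_family,
                            te_side=fr.te_side,
                            flank_left_of_te=fr.flank_left_of_te))
                    control_seqs.append(seq)
                    control_span.append((first, len(c.fragments)))
                elif c.category == FULL_TE:
                    tasks.append(MapTask(c.read_id, c.mate, FULL_TE, seq,
                                         te_family=c.te_family))
                elif c.category == SUPPORTING:
                    tasks.append(MapTask(c.read_id, c.mate, SUPPORTING, seq,
                                         te_family=c.te_family))
    logger.info("classification: %s in %.1fs", dict(n_cat), time.time() - t0)

    # false-junction control: a junction read whose *untrimmed* sequence maps
    # end-to-end is an ordinary genomic read with a coincidental TE match
    t1 = time.time()
    control_hits = map_sequences(control_seqs, genome_index, cfg.mismatch)
    drop_task_idx = set()
    n_false_junction = 0
    for (first, nfrag), hit in zip(control_span, control_hits):
        if hit is not None:
            n_false_junction += 1
            drop_task_idx.update(range(first, first + nfrag))
    kept_tasks = [t for i, t in enumerate(tasks) if i not in drop_task_idx]

    alignments = align_to_reference(kept_tasks, ref, cfg.mismatch,
                                    index=genome_index)
    alignments = sort_alignments(alignments, chrom_order=ref.chroms)
    logger.info("mapping: %d/%d fragments placed (%d false junctions) in %.1fs",
                len(alignments), len(kept_tasks), n_false_junction,
                time.time() - t1)

    clusters = build_clusters(alignments, cfg)
    cand_groups: List[List[CandidateInsertion]] = []
    for cl in clusters:
        subs = refine_subclusters(cl, cfg)
        cand_groups.append([call_insertion(s, ref, cfg) for s in subs])
    confident, raw = apply_filters(cand_groups, ref.annotation, cfg)

    per_family = Counter(c.te_family for c in confident)
    summary = {
        "n_pairs": len(pairs),
        "read_categories": dict(n_cat),
        "n_false_junctions_filtered": n_false_junction,
        "n_fragments_mapped": len(alignments),
        "n_clusters": len(clusters),
        "n_raw_calls": len(raw),
        "n_confident_calls": len(confident),
        "confident_calls_per_family": dict(sorted(per_family.items())),
    }
    logger.info("calls: %d confident / %d raw", len(confident), len(raw))
    return PipelineResult(confident, raw, summary)
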