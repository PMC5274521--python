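"""TE-library matching and read classification.

A read is *informative* when it carries a qualifying ungapped match to a
TE consensus.  The hit predicate mirrors a BLAT search at ``-minScore 10
-tileSize 7``: a maximal ungapped window on one diagonal with

* length >= ``len_cut_match``,
* mismatches <= ``mismatch``,
* matches - mismatches >= ``min_score``,
* at least ``min_seed_count`` disjoint exact ``seed_len``-mers
  (the tile-hit requirement; without it a random 100 bp read carries
  hundreds of coincidental >=10 bp windows against a 40 kb library and
  every read would look informative).

Classification then sorts each mate into JUNCTION (TE boundary inside the
read, genomic flank retained), FULL_TE (read entirely TE), SUPPORTING
(mate of a FULL_TE read) or UNINFORMATIVE.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._kernels import LIB_PAD, SENTINEL, build_kmer_index, match_reads_batch
from .io_formats import ReadPair, RunConfig, TELibrary, encode_seq

JUNCTION = "JUNCTION"
FULL_TE = "FULL_TE"
SUPPORTING = "SUPPORTING"
UNINFORMATIVE = "UNINFORMATIVE"

TE_5PRIME = "TE_5PRIME"
TE_3PRIME = "TE_3PRIME"

__all__ = [
    "RepeatHit", "JunctionFragment", "ClassifiedRead", "LibraryIndex",
    "find_repeat_hits", "classify_pair", "assign_family",
    "JUNCTION", "FULL_TE", "SUPPORTING", "UNINFORMATIVE",
    "TE_5PRIME", "TE_3PRIME",
]


@dataclass(frozen=True)
class RepeatHit:
    """One ungapped read/consensus alignment (0-based half-open intervals)."""

    te_family: str
    read_start: int
    read_end: int
    te_start: int
    te_end: int
    strand: str          # '+' read matches consensus, '-' matches its revcomp
    mismatches: int
    score: int           # matches - mismatches
    read_id: str = ""
    mate: int = 0

    @property
    def read_interval(self) -> Tuple[int, int]:
        return (self.read_start, self.read_end)

    @property
    def te_interval(self) -> Tuple[int, int]:
        return (self.te_start, self.te_end)


@dataclass(frozen=True)
class JunctionFragment:
    """A trimmed genomic flank from a junction read."""

    flank_seq: str
    te_side: str             # which consensus end the flank abuts
    flank_left_of_te: bool   # True: read layout is [flank][TE...]


@dataclass(frozen=True)
class ClassifiedRead:
    read_id: str
    mate: int                # 1 or 2
    category: str
    te_family: Optional[str] = None
    fragments: Tuple[JunctionFragment, ...] = ()
    blocks_supporting: bool = False  # internal TE hit: mate may not be SUPPORTING

    @property
    def flank_seq(self) -> Optional[str]:
        return self.fragments[0].flank_seq if len(self.fragments) == 1 else None

    @property
    def te_side(self) -> Optional[str]:
        return self.fragments[0].te_side if len(self.fragments) == 1 else None


class LibraryIndex:
    """Seed index over a TE library; reusable across reads and batches."""

    def __init__(self, library: TELibrary, cfg: RunConfig):
        if len(library) == 0:
            raise ValueError("empty TE library")
        self.library = library
        self.cfg = cfg
        self.names = [f.name for f in library]
        self.lengths = np.array([len(f.consensus) for f in library], dtype=np.int64)
        parts = []
        offsets = []
        pos = 0
        pad = np.full(LIB_PAD, SENTINEL, dtype=np.uint8)
        for fam in library:
            offsets.append(pos)
            parts.append(encode_seq(fam.consensus))
            pos += len(fam.consensus)
            parts.append(pad)
            pos += LIB_PAD
        self.codes = np.concatenate(parts)
        self.offsets = np.array(offsets, dtype=np.int64)
        self.bucket_start, self.bucket_pos = build_kmer_index(
            self.codes, cfg.seed_len)

    def family_of(self, lib_pos: int) -> int:
        i = int(np.searchsorted(self.offsets, lib_pos, side="right")) - 1
        return i

    def match_batch(self, seqs: Sequence[str]) -> List[List[RepeatHit]]:
        """Hits per sequence (order preserved), in original read coordinates."""
        cfg = self.cfg
        flat = np.concatenate([encode_seq(s) for s in seqs]) if seqs else \
            np.empty(0, dtype=np.uint8)
        lens = np.array([len(s) for s in seqs], dtype=np.int64)
        starts = np.concatenate(([0], np.cumsum(lens)[:-1])) if len(seqs) else \
            np.empty(0, dtype=np.int64)
        cap = max(4 * len(seqs) + 1024, 1 << 16)
        while True:
            out = np.empty((cap, 8), dtype=np.int64)
            n = match_reads_batch(
                flat, starts, lens, self.codes,
                self.bucket_start, self.bucket_pos, cfg.seed_len,
                cfg.mismatch, cfg.len_cut_match, cfg.min_score,
                cfg.min_seed_count, out)
            if n >= 0:
                break
            cap *= 4
        hits: List[List[RepeatHit]] = [[] for _ in seqs]
        for row in range(n):
            ridx, orient, rs, re_, ls, le, mm, score = out[row]
            rl = lens[ridx]
            if orient == 1:  # map back to original read orientation
                rs, re_ = rl - re_, rl - rs
            fam_i = self.family_of(ls)
            off = self.offsets[fam_i]
            hits[int(ridx)].append(RepeatHit(
                te_family=self.names[fam_i],
                read_start=int(rs), read_end=int(re_),
                te_start=int(ls - off), te_end=int(le - off),
                strand="+" if orient == 0 else "-",
                mismatches=int(mm), score=int(score)))
        return [_merge_family_overlaps(h) for h in hits]


def _hit_rank(h: RepeatHit):
    # best hit first: high score, few mismatches, then stable positional order
    return (-h.score, h.mismatches, h.read_start, h.te_start, h.strand)


def _merge_family_overlaps(hits: List[RepeatHit]) -> List[RepeatHit]:
    """Merge read-interval-overlapping hits of one family to the best one."""
    out: List[RepeatHit] = []
    byfam: Dict[str, List[RepeatHit]] = {}
    for h in hits:
        byfam.setdefault(h.te_family, []).append(h)
    for fam in sorted(byfam):
        fam_hits = sorted(byfam[fam], key=lambda h: (h.read_start, h.read_end))
        group: List[RepeatHit] = []
        extent = -1
        for h in fam_hits:
            if group and h.read_start >= extent:
                out.append(min(group, key=_hit_rank))
                group = []
            group.append(h)
            extent = max(extent, h.read_end)
        if group:
            out.append(min(group, key=_hit_rank))
    out.sort(key=lambda h: (h.read_start, h.read_end, h.te_family, h.strand))
    return out


def find_repeat_hits(read: str, library: TELibrary, cfg: RunConfig,
                     index: Optional[LibraryIndex] = None) -> List[RepeatHit]:
    """All qualifying hits of one read against the library (both strands)."""
    if len(library) == 0:
        raise ValueError("empty TE library")
    if index is None:
        index = LibraryIndex(library, cfg)
    return index.match_batch([read])[0]


def assign_family(hits: Sequence[RepeatHit]) -> str:
    """Winning family: highest score, then fewest mismatches, then name."""
    if not hits:
        raise ValueError("assign_family: empty hit list")
    best = min(hits, key=lambda h: (-h.score, h.mismatches, h.te_family))
    return best.te_family


def _classify_mate(read_id: str, mate: int, seq: str,
                   hits: Sequence[RepeatHit], library: TELibrary,
                   cfg: RunConfig) -> ClassifiedRead:
    if not hits:
        return ClassifiedRead(read_id, mate, UNINFORMATIVE)
    fam = assign_family(hits)
    fam_hits = [h for h in hits if h.te_family == fam]
    h = min(fam_hits, key=_hit_rank)
    te_len = len(library[fam].consensus)
    R = len(seq)
    tol = cfg.terminus_tolerance_bp
    trim = cfg.len_cut_trim

    left_flank = h.read_start
    right_flank = R - h.read_end
    # which consensus terminus each read-side boundary of the hit touches
    reach5 = h.te_start <= tol
    reach3 = te_len - h.te_end <= tol
    # boundary at read_start corresponds to te 5' end on '+', 3' end on '-'
    left_bound_ok = reach5 if h.strand == "+" else reach3
    right_bound_ok = reach3 if h.strand == "+" else reach5
    side_at_left = TE_5PRIME if h.strand == "+" else TE_3PRIME
    side_at_right = TE_3PRIME if h.strand == "+" else TE_5PRIME

    if left_flank < trim and right_flank < trim:
        return ClassifiedRead(read_id, mate, FULL_TE, te_family=fam)

    frags: List[JunctionFragment] = []
    internal = False
    if left_flank >= trim and right_flank >= trim:
        # hit spans a short consensus entirely: a junction on each side
        if left_bound_ok and right_bound_ok:
            frags.append(JunctionFragment(seq[:h.read_start], side_at_left, True))
            frags.append(JunctionFragment(seq[h.read_end:], side_at_right, False))
        else:
            internal = True
    elif left_flank >= trim:
        if left_bound_ok:
            frags.append(JunctionFragment(seq[:h.read_start], side_at_left, True))
        else:
            internal = True
    else:  # right_flank >= trim
        if right_bound_ok:
            frags.append(JunctionFragment(seq[h.read_end:], side_at_right, False))
        else:
            internal = True

    if frags:
        return ClassifiedRead(read_id, mate, JUNCTION, te_family=fam,
                              fragments=tuple(frags))
    return ClassifiedRead(read_id, mate, UNINFORMATIVE,
                          blocks_supporting=internal)


def classify_pair(pair: ReadPair,
                  hits1: Sequence[RepeatHit], hits2: Sequence[RepeatHit],
                  library: TELibrary, cfg: RunConfig
                  ) -> Tuple[ClassifiedRead, ClassifiedRead]:
    """Assign one category to each mate of a pair.

    A mate with no hit at all is promoted to SUPPORTING when its partner
    is FULL_TE (the partner sits inside the element; this read anchors
    the pair on the genome).  A mate whose best hit is internal to a
    consensus keeps UNINFORMATIVE and is never promoted.
    """
    c1 = _classify_mate(pair.read_id, 1, pair.seq1, hits1, library, cfg)
    c2 = _classify_mate(pair.read_id, 2, pair.seq2, hits2, library, cfg)

    def promote(me: ClassifiedRead, partner: ClassifiedRead,
                my_hits: Sequence[RepeatHit]) -> ClassifiedRead:
        if (me.category == UNINFORMATIVE and not my_hits
                and partner.category == FULL_TE):
            return ClassifiedRead(me.read_id, me.mate, SUPPORTING,
                                  te_family=partner.te_family)
        return me

    return promote(c1, c2, hits1), promote(c2, c1, hits2)
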