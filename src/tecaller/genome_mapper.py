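"""Placement of trimmed flanks, full reads and supporting reads on the
reference genome.

The internal mapper reports end-to-end (global) placements with at most
``max_mismatch`` substitutions — flanks have already been trimmed to pure
genomic sequence, so local re-alignment would only re-introduce TE bases.
Its mapping quality contract is two-valued: 60 when the best placement is
unique at the minimal mismatch count, 0 when two or more co-optimal
placements exist.  Downstream code only ever compares mapq against
``cfg.mapq_min``, so an external aligner emitting the full 0-60 range can
be substituted through the SAM adapter at the bottom of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from ._kernels import GENOME_PAD, SENTINEL, build_kmer_index, map_fragments_batch
from .io_formats import ReferenceGenome, encode_seq
from .repeat_matcher import FULL_TE, JUNCTION, SUPPORTING

PROBE_LEN = 10  # genome index k-mer length

__all__ = ["GenomeAlignment", "MapTask", "GenomeIndex", "align_to_reference",
           "map_sequences", "sort_alignments", "encode_qname", "decode_qname",
           "read_sam_alignments"]


@dataclass(frozen=True)
class MapTask:
    """One fragment to place on the reference."""

    read_id: str
    mate: int
    category: str            # JUNCTION | FULL_TE | SUPPORTING
    seq: str
    te_family: Optional[str] = None
    te_side: Optional[str] = None          # JUNCTION only
    flank_left_of_te: Optional[bool] = None  # JUNCTION only


@dataclass(frozen=True)
class GenomeAlignment:
    read_id: str
    mate: int
    category: str
    chrom: str
    start: int               # 0-based half-open span
    end: int
    strand: str              # '+'/'-'
    mapq: int
    mismatches: int
    te_family: Optional[str] = None
    te_side: Optional[str] = None
    flank_left_of_te: Optional[bool] = None

    def __post_init__(self):
        if not (0 <= self.mapq <= 60):
            raise ValueError(f"mapq {self.mapq} outside [0, 60]")


class GenomeIndex:
    """Probe index over a reference genome; build once, map many batches."""

    def __init__(self, ref: ReferenceGenome):
        self.ref = ref
        self.chrom_names = list(ref.sequences)
        parts = []
        starts = []
        ends = []
        pos = 0
        pad = np.full(GENOME_PAD, SENTINEL, dtype=np.uint8)
        for name in self.chrom_names:
            starts.append(pos)
            seq = ref.sequences[name]
            parts.append(encode_seq(seq))
            pos += len(seq)
            ends.append(pos)
            parts.append(pad)
            pos += GENOME_PAD
        self.codes = np.concatenate(parts)
        self.chrom_starts = np.array(starts, dtype=np.int64)
        self.chrom_ends = np.array(ends, dtype=np.int64)
        self.bucket_start, self.bucket_pos = build_kmer_index(
            self.codes, PROBE_LEN)

    def locate(self, global_pos: int) -> Tuple[str, int]:
        i = int(np.searchsorted(self.chrom_starts, global_pos, side="right")) - 1
        return self.chrom_names[i], int(global_pos - self.chrom_starts[i])


def map_sequences(seqs: Sequence[str], index: GenomeIndex, max_mismatch: int
                  ) -> List[Optional[Tuple[str, int, str, int, int]]]:
    """Best placement per sequence: (chrom, start, strand, mismatches, mapq)
    or None when no end-to-end placement with <= max_mismatch exists.

    Sequences shorter than the probe length or containing N are reported
    unplaced (the simulator never produces them; real input rarely does).
    """
    if max_mismatch > 2:
        raise ValueError("internal mapper supports max_mismatch <= 2")
    mappable = [i for i, s in enumerate(seqs)
                if len(s) >= PROBE_LEN and "N" not in s]
    out: List[Optional[Tuple[str, int, str, int, int]]] = [None] * len(seqs)
    if not mappable:
        return out
    flat = np.concatenate([encode_seq(seqs[i]) for i in mappable])
    lens = np.array([len(seqs[i]) for i in mappable], dtype=np.int64)
    starts = np.concatenate(([0], np.cumsum(lens)[:-1]))
    results = np.zeros((len(mappable), 5), dtype=np.int64)
    map_fragments_batch(flat, starts, lens, index.codes,
                        index.chrom_starts, index.chrom_ends,
                        index.bucket_start, index.bucket_pos,
                        PROBE_LEN, max_mismatch, results)
    for row, i in enumerate(mappable):
        if results[row, 0]:
            chrom, local = index.locate(int(results[row, 1]))
            strand = "+" if results[row, 2] == 0 else "-"
            mapq = 60 if results[row, 4] == 1 else 0
            out[i] = (chrom, local, strand, int(results[row, 3]), mapq)
    return out


def align_to_reference(tasks: Sequence[MapTask], ref: ReferenceGenome,
                       max_mismatch: int = 2,
                       index: Optional[GenomeIndex] = None
                       ) -> List[GenomeAlignment]:
    """Place fragments; fragments with no qualifying placement are dropped."""
    if not ref.sequences:
        raise ValueError("empty reference")
    if index is None:
        index = GenomeIndex(ref)
    placements = map_sequences([t.seq for t in tasks], index, max_mismatch)
    out: List[GenomeAlignment] = []
    for task, p in zip(tasks, placements):
        if p is None:
            continue
        chrom, start, strand, mm, mapq = p
        out.append(GenomeAlignment(
            read_id=task.read_id, mate=task.mate, category=task.category,
            chrom=chrom, start=start, end=start + len(task.seq),
            strand=strand, mapq=mapq, mismatches=mm,
            te_family=task.te_family, te_side=task.te_side,
            flank_left_of_te=task.flank_left_of_te))
    return out


def sort_alignments(alignments: Sequence[GenomeAlignment],
                    chrom_order: Optional[Sequence[str]] = None
                    ) -> List[GenomeAlignment]:
    """Stable sort by (chromosome, start); ties keep input order."""
    if chrom_order:
        rank: Dict[str, int] = {c: i for i, c in enumerate(chrom_order)}
        return sorted(alignments, key=lambda a: (rank.get(a.chrom, len(rank)),
                                                 a.chrom, a.start))
    return sorted(alignments, key=lambda a: (a.chrom, a.start))


# ---------------------------------------------------------------------------
# external-aligner seam
#
# Fragments can be written as FASTA/FASTQ with a structured QNAME, aligned
# by any SAM-emitting mapper, and read back.  The QNAME carries everything
# the caller needs beyond the alignment itself.

_CAT_CODE = {JUNCTION: "J", FULL_TE: "F", SUPPORTING: "S"}
_CODE_CAT = {v: k for k, v in _CAT_CODE.items()}
_SIDE_CODE = {"TE_5PRIME": "5P", "TE_3PRIME": "3P", None: "NA"}
_CODE_SIDE = {v: k for k, v in _SIDE_CODE.items()}


def encode_qname(task: MapTask) -> str:
    left = "NA" if task.flank_left_of_te is None else (
        "L" if task.flank_left_of_te else "R")
    return ":".join([task.read_id, str(task.mate), _CAT_CODE[task.category],
                     _SIDE_CODE[task.te_side], left, task.te_family or "NA"])


def decode_qname(qname: str) -> MapTask:
    read_id, mate, cat, side, left, family = qname.rsplit(":", 5)
    return MapTask(
        read_id=read_id, mate=int(mate), category=_CODE_CAT[cat], seq="",
        te_family=None if family == "NA" else family,
        te_side=_CODE_SIDE[side],
        flank_left_of_te=None if left == "NA" else left == "L")


def read_sam_alignments(path) -> List[GenomeAlignment]:
    """Ingest coordinate- or name-sorted SAM produced by an external aligner
    on fragments named by :func:`encode_qname`.  Only ungapped (single-M
    CIGAR) primary alignments are accepted; MAPQ is taken verbatim.
    """
    import pysam

    out: List[GenomeAlignment] = []
    with pysam.AlignmentFile(str(path), "r", check_sq=False) as sam:
        for rec in sam:
            if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
                continue
            if len(rec.cigartuples or []) != 1 or rec.cigartuples[0][0] != 0:
                continue
            task = decode_qname(rec.query_name)
            out.append(GenomeAlignment(
                read_id=task.read_id, mate=task.mate, category=task.category,
                chrom=rec.reference_name, start=rec.reference_start,
                end=rec.reference_end, strand="-" if rec.is_reverse else "+",
                mapq=min(rec.mapping_quality, 60),
                mismatches=int(rec.get_tag("NM")) if rec.has_tag("NM") else 0,
                te_family=task.te_family, te_side=task.te_side,
                flank_left_of_te=task.flank_left_of_te))
    return out
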