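"""Readers, writers and shared domain types.

Coordinate conventions
----------------------
Everything held in memory is 0-based, half-open.  External files (GFF3)
are 1-based, inclusive.  The conversion happens here and only here: a
record gains/loses its +1 at the moment it crosses an I/O boundary.

Sequences are stored as upper-case strings over the ACGTN alphabet; any
other character (IUPAC ambiguity codes, soft-masking already uppercased)
is mapped to N on input.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, Iterator, List, Optional, Tuple

import numpy as np
from Bio import SeqIO
from Bio.SeqIO.QualityIO import FastqGeneralIterator

__all__ = [
    "FormatError",
    "DuplicateRecordError",
    "EmptyFileError",
    "PairSyncError",
    "TruncatedRecordError",
    "TEFamily",
    "TELibrary",
    "AnnotatedRepeat",
    "ReferenceGenome",
    "ReadPair",
    "RunConfig",
    "GffRecord",
    "read_fasta",
    "write_fasta",
    "read_fastq_pair",
    "write_fastq_pair",
    "read_gff3",
    "write_gff3",
    "encode_seq",
    "decode_seq",
    "revcomp",
]


class FormatError(ValueError):
    """Malformed or inconsistent input file."""


class DuplicateRecordError(FormatError):
    """Two records in one FASTA file share a name."""


class EmptyFileError(FormatError):
    """A sequence file contained no records."""


class PairSyncError(FormatError):
    """Mate FASTQ files are desynchronised (ids or lengths differ)."""


class TruncatedRecordError(FormatError):
    """A FASTQ record is incomplete."""


# ---------------------------------------------------------------------------
# sequence alphabet helpers

_VALID = set("ACGTN")

# A=0 C=1 G=2 T=3 N=4; table also uppercases and maps unknowns to N.
_ENC_TABLE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _ENC_TABLE[ord(_b)] = _i
    _ENC_TABLE[ord(_b.lower())] = _i
_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)

_COMP = str.maketrans("ACGTN", "TGCAN")


def clean_seq(seq: str) -> str:
    """Uppercase and collapse non-ACGTN characters to N."""
    s = seq.upper()
    if set(s) <= _VALID:
        return s
    return "".join(c if c in _VALID else "N" for c in s)


def encode_seq(seq: str) -> np.ndarray:
    """DNA string -> uint8 codes (A0 C1 G2 T3 N4)."""
    return _ENC_TABLE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_seq(codes: np.ndarray) -> str:
    return _DEC[codes].tobytes().decode("ascii")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class TEFamily:
    """A named TE consensus plus the TSD length its integration produces."""

    name: str
    consensus: str
    tsd_len: int

    def __post_init__(self):
        if not self.name:
            raise ValueError("family name must be non-empty")
        if len(self.consensus) < 1:
            raise ValueError(f"family {self.name}: empty consensus")
        if self.tsd_len < 0:
            raise ValueError(f"family {self.name}: tsd_len < 0")


class TELibrary:
    """An ordered collection of TE families with unique names."""

    def __init__(self, families: Iterable[TEFamily]):
        self.families: List[TEFamily] = list(families)
        if not self.families:
            raise ValueError("TE library is empty")
        names = [f.name for f in self.families]
        if len(set(names)) != len(names):
            raise DuplicateRecordError("duplicate family names in TE library")
        self._by_name = {f.name: f for f in self.families}

    def __len__(self):
        return len(self.families)

    def __iter__(self) -> Iterator[TEFamily]:
        return iter(self.families)

    def __getitem__(self, name: str) -> TEFamily:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @classmethod
    def from_fasta(cls, path, tsd_lens: Optional[Dict[str, int]] = None,
                   default_tsd_len: int = 0) -> "TELibrary":
        seqs = read_fasta(path)
        tsd_lens = tsd_lens or {}
        return cls(
            TEFamily(name, seq, tsd_lens.get(name, default_tsd_len))
            for name, seq in seqs.items()
        )


@dataclass(frozen=True)
class AnnotatedRepeat:
    """A TE already present in the reference assembly (0-based half-open)."""

    chrom: str
    start: int
    end: int
    family: str

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"bad repeat interval {self.start}..{self.end}")


class ReferenceGenome:
    """Chromosome name -> sequence, plus an optional reference TE annotation."""

    def __init__(self, sequences: Dict[str, str],
                 annotation: Optional[List[AnnotatedRepeat]] = None):
        if not sequences:
            raise ValueError("reference genome has no sequences")
        for name, seq in sequences.items():
            if not seq:
                raise ValueError(f"chromosome {name} is empty")
        self.sequences = dict(sequences)
        self.annotation = list(annotation) if annotation else []
        for rep in self.annotation:
            if rep.chrom not in self.sequences:
                raise ValueError(f"annotated repeat on unknown chromosome {rep.chrom}")
            if rep.end > len(self.sequences[rep.chrom]):
                raise ValueError(f"annotated repeat {rep} exceeds chromosome length")

    @property
    def chroms(self) -> List[str]:
        return list(self.sequences)

    def __len__(self):
        return sum(len(s) for s in self.sequences.values())

    @classmethod
    def from_fasta(cls, path, annotation=None) -> "ReferenceGenome":
        return cls(read_fasta(path), annotation)


@dataclass(frozen=True)
class ReadPair:
    """One sequenced fragment: two mates sharing an id (no /1,/2 suffix)."""

    read_id: str
    seq1: str
    qual1: str
    seq2: str
    qual2: str

    def __post_init__(self):
        if not self.seq1 or not self.seq2:
            raise ValueError(f"read {self.read_id}: empty mate sequence")


@dataclass(frozen=True)
class RunConfig:
    """All tunables of the caller.

    The first three mirror the matcher's command-line heritage: a TE/read
    match must span at least ``len_cut_match`` bases with at most
    ``mismatch`` substitutions and score (matches - mismatches) at least
    ``min_score``; a trimmed genomic flank shorter than ``len_cut_trim``
    is discarded.
    """

    len_cut_match: int = 10
    len_cut_trim: int = 10
    mismatch: int = 2
    min_score: int = 10           # BLAT-style -minScore on matches-mismatches
    seed_len: int = 7             # exact-match tile length; hits need 2 disjoint tiles
    min_seed_count: int = 2
    terminus_tolerance_bp: int = 3  # how close to a consensus end counts as "at the end"
    window_bp: int = 2000
    mapq_min: int = 29
    min_cluster_junctions: int = 3
    annot_proximity_bp: int = 10
    tsd_slack_bp: int = 25        # junction breakpoints closer than this co-cluster
    match_tolerance_bp: int = 100  # evaluation only
    rule2_per_flank: bool = False  # False: rule (ii) counts left+right summed

    def __post_init__(self):
        for f in ("len_cut_match", "len_cut_trim", "mismatch", "min_score",
                  "seed_len", "min_seed_count", "terminus_tolerance_bp",
                  "window_bp", "mapq_min", "min_cluster_junctions",
                  "annot_proximity_bp", "tsd_slack_bp", "match_tolerance_bp"):
            if getattr(self, f) < 0:
                raise ValueError(f"config field {f} must be >= 0")

    def with_(self, **kw) -> "RunConfig":
        return replace(self, **kw)


@dataclass
class GffRecord:
    """One GFF3 feature line; start/end are 0-based half-open in memory."""

    chrom: str
    start: int
    end: int
    type: str = "transposable_element_insertion_site"
    source: str = "tecaller"
    score: str = "."
    strand: str = "."
    phase: str = "."
    attributes: Dict[str, str] = field(default_factory=dict)


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path) -> Dict[str, str]:
    """Read a FASTA file into an ordered name -> sequence map.

    Sequences are uppercased; non-ACGTN characters become N.  Raises
    ``EmptyFileError`` / ``DuplicateRecordError`` / ``FileNotFoundError``.
    """
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    out: Dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in out:
            raise DuplicateRecordError(f"duplicate FASTA record name: {rec.id}")
        out[rec.id] = clean_seq(str(rec.seq))
    if not out:
        raise EmptyFileError(f"no FASTA records in {path}")
    return out


def write_fasta(seqs: Dict[str, str], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in seqs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


# ---------------------------------------------------------------------------
# FASTQ pairs

_MATE_SUFFIXES = (("/1", "/2"), (".1", ".2"))


def _strip_mate(raw_id: str, mate: int) -> str:
    """Remove a /1 /2 or Casava-style ' 1:...' suffix; error if neither fits."""
    # Casava 1.8: "instrument:...:pos 1:N:0:index" -> id is the first token
    if " " in raw_id:
        head, tail = raw_id.split(" ", 1)
        if tail[:1] == str(mate):
            return head
        raise PairSyncError(f"read id '{raw_id}' does not look like mate {mate}")
    for suf in _MATE_SUFFIXES:
        if raw_id.endswith(suf[mate - 1]):
            return raw_id[: -len(suf[mate - 1])]
    return raw_id  # bare shared id


def read_fastq_pair(path1, path2) -> Iterator[ReadPair]:
    """Stream synchronised mate FASTQ files as ReadPair objects."""
    with open(path1) as f1, open(path2) as f2:
        it1 = FastqGeneralIterator(f1)
        it2 = FastqGeneralIterator(f2)
        n = 0
        while True:
            r1 = next(it1, None)
            r2 = next(it2, None)
            if r1 is None and r2 is None:
                break
            if r1 is None or r2 is None:
                longer = path2 if r1 is None else path1
                raise PairSyncError(
                    f"mate files desynchronised after {n} pairs: {longer} is longer")
            id1 = _strip_mate(r1[0], 1)
            id2 = _strip_mate(r2[0], 2)
            if id1 != id2:
                raise PairSyncError(f"mate ids disagree at pair {n}: '{r1[0]}' vs '{r2[0]}'")
            yield ReadPair(id1, clean_seq(r1[1]), r1[2], clean_seq(r2[1]), r2[2])
            n += 1


def write_fastq_pair(pairs: Iterable[ReadPair], path1, path2) -> int:
    n = 0
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for p in pairs:
            f1.write(f"@{p.read_id}/1\n{p.seq1}\n+\n{p.qual1}\n")
            f2.write(f"@{p.read_id}/2\n{p.seq2}\n+\n{p.qual2}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# GFF3


def _esc(v: str) -> str:
    return str(v).replace(";", "%3B").replace("=", "%3D").replace(",", "%2C")


def _unesc(v: str) -> str:
    return v.replace("%3B", ";").replace("%3D", "=").replace("%2C", ",")


def write_gff3(records: Iterable[GffRecord], path) -> None:
    """Write records as GFF3 (1-based inclusive on disk)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for r in records:
            attrs = ";".join(f"{k}={_esc(v)}" for k, v in r.attributes.items()) or "."
            fh.write("\t".join([
                r.chrom, r.source, r.type,
                str(r.start + 1), str(r.end),
                r.score, r.strand, r.phase, attrs,
            ]) + "\n")


def read_gff3(path) -> List[GffRecord]:
    """Read a GFF3 file back into records (0-based half-open in memory)."""
    out: List[GffRecord] = []
    with open(path) as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            cols = line.split("\t")
            if len(cols) != 9:
                raise FormatError(f"{path}:{ln}: expected 9 columns, got {len(cols)}")
            attrs: Dict[str, str] = {}
            if cols[8] != ".":
                for item in cols[8].split(";"):
                    if not item:
                        continue
                    k, _, v = item.partition("=")
                    attrs[k] = _unesc(v)
            out.append(GffRecord(
                chrom=cols[0], source=cols[1], type=cols[2],
                start=int(cols[3]) - 1, end=int(cols[4]),
                score=cols[5], strand=cols[6], phase=cols[7],
                attributes=attrs,
            ))
    return out
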