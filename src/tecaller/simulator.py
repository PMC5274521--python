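"""Benchmark data generator: TE-insertion genome mutator and paired-end
read simulator.

``plant_insertions`` picks random sites, duplicates the target-site motif
(the ``tsd_len`` reference bases following the site) and inserts the TE
consensus, on a random strand, between the two motif copies — the
signature a real integration leaves.  ``simulate_reads`` shears the
mutated genome into paired 100 bp reads with a Gaussian insert size and a
uniform per-base substitution error, i.e. the standard short-read
simulation recipe (read length 100, insert 500 +/- 100) with the empirical
quality model replaced by a flat error rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Tuple

import numpy as np

from .io_formats import (GffRecord, ReadPair, ReferenceGenome, TELibrary,
                         decode_seq, encode_seq, revcomp)

__all__ = ["SimulatedTruth", "ReadSimParams", "plant_insertions",
           "simulate_reads", "truth_to_gff", "truth_from_gff"]

EDGE_MARGIN = 1000  # keep planted sites away from chromosome ends


@dataclass(frozen=True)
class SimulatedTruth:
    """One planted insertion.  ``pos`` is 0-based: the number of original
    bases before the insertion point, i.e. the element goes in after base
    ``pos`` in 1-based terms and the duplicated motif is
    ``chrom[pos:pos+tsd_len]``."""

    chrom: str
    pos: int
    te_family: str
    tsd_seq: str
    strand: str


@dataclass(frozen=True)
class ReadSimParams:
    coverage: float
    seed: int
    read_len: int = 100
    insert_mean: int = 500
    insert_sd: int = 100
    error_rate: float = 0.01

    def __post_init__(self):
        if self.coverage <= 0:
            raise ValueError("coverage must be > 0")
        if self.read_len > self.insert_mean:
            raise ValueError("read_len must be <= insert_mean")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")


def plant_insertions(genome: ReferenceGenome, library: TELibrary,
                     n: int = 200, seed: int = 0,
                     min_spacing: int = 4000
                     ) -> Tuple[ReferenceGenome, List[SimulatedTruth]]:
    """Plant ``n`` random TE insertions with TSDs; returns (mutated genome,
    sorted truth records).

    Sites are drawn uniformly, at least ``min_spacing`` apart (twice the
    clustering window by default, so each truth site maps to one call
    cluster unambiguously) and ``EDGE_MARGIN`` away from chromosome ends.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    chroms = list(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in chroms], dtype=np.int64)
    usable = np.maximum(lens - 2 * EDGE_MARGIN, 0)
    if usable.sum() < n * min_spacing:
        raise ValueError(
            f"genome too short for {n} sites with spacing {min_spacing}")
    probs = usable / usable.sum()

    chosen: Dict[str, List[int]] = {c: [] for c in chroms}
    tries = 0
    placed = 0
    max_tries = 10000 * n
    while placed < n:
        tries += 1
        if tries > max_tries:
            raise ValueError("could not place sites with required spacing")
        ci = int(rng.choice(len(chroms), p=probs))
        pos = int(rng.integers(EDGE_MARGIN, lens[ci] - EDGE_MARGIN))
        if any(abs(pos - q) < min_spacing for q in chosen[chroms[ci]]):
            continue
        chosen[chroms[ci]].append(pos)
        placed += 1

    fam_idx = rng.integers(0, len(library), size=n)
    strands = np.where(rng.integers(0, 2, size=n) == 0, "+", "-")

    truths: List[SimulatedTruth] = []
    i = 0
    mutated: Dict[str, str] = {}
    for c in chroms:
        sites = sorted(chosen[c])
        fams = []
        for pos in sites:
            fam = library.families[int(fam_idx[i])]
            strand = str(strands[i])
            motif = genome.sequences[c][pos:pos + fam.tsd_len]
            truths.append(SimulatedTruth(c, pos, fam.name, motif, strand))
            fams.append((pos, fam, strand, motif))
            i += 1
        seq = genome.sequences[c]
        parts = []
        prev = 0
        for pos, fam, strand, motif in fams:
            te = fam.consensus if strand == "+" else revcomp(fam.consensus)
            # orig[:pos+tsd] + TE + orig[pos:]  == flank, motif, TE, motif, rest
            parts.append(seq[prev:pos + fam.tsd_len])
            parts.append(te)
            prev = pos
        parts.append(seq[prev:])
        mutated[c] = "".join(parts)

    truths.sort(key=lambda t: (t.chrom, t.pos))
    return ReferenceGenome(mutated), truths


def simulate_reads(genome: ReferenceGenome, params: ReadSimParams
                   ) -> List[ReadPair]:
    """Simulate paired-end reads over the whole genome.

    N pairs = ceil(coverage * genome_len / (2 * read_len)); fragment
    lengths ~ Normal(insert_mean, insert_sd) truncated to
    [read_len, 2*insert_mean]; mate1 is the fragment's 5' read_len bases,
    mate2 the reverse complement of its 3' read_len bases; substitution
    errors are applied per base at ``error_rate``; qualities are constant
    Q30.
    """
    rng = np.random.default_rng(params.seed)
    rl = params.read_len
    chroms = list(genome.sequences)
    lens = np.array([len(genome.sequences[c]) for c in chroms], dtype=np.int64)
    total = int(lens.sum())
    n_pairs = math.ceil(params.coverage * total / (2 * rl))
    counts = rng.multinomial(n_pairs, lens / total)

    qual = chr(33 + 30) * rl
    pairs: List[ReadPair] = []
    serial = 0
    for ci, c in enumerate(chroms):
        nc = int(counts[ci])
        if nc == 0:
            continue
        clen = int(lens[ci])
        lo, hi = rl, 2 * params.insert_mean
        frag = np.rint(rng.normal(params.insert_mean, params.insert_sd,
                                  size=nc)).astype(np.int64)
        for _ in range(1000):
            bad = (frag < lo) | (frag > hi)
            if not bad.any():
                break
            frag[bad] = np.rint(rng.normal(params.insert_mean, params.insert_sd,
                                           size=int(bad.sum()))).astype(np.int64)
        frag = np.clip(frag, lo, min(hi, clen))
        starts = (rng.random(nc) * (clen - frag + 1)).astype(np.int64)

        codes = encode_seq(genome.sequences[c])
        idx1 = starts[:, None] + np.arange(rl)
        m1 = codes[idx1]
        idx2 = (starts + frag - rl)[:, None] + np.arange(rl)
        m2 = codes[idx2][:, ::-1]
        m2 = np.where(m2 < 4, 3 - m2, m2).astype(np.uint8)

        if params.error_rate > 0:
            for m in (m1, m2):
                mask = rng.random(m.shape) < params.error_rate
                nerr = int(mask.sum())
                if nerr:
                    shift = rng.integers(1, 4, size=nerr).astype(np.uint8)
                    m[mask] = np.where(m[mask] < 4,
                                       (m[mask] + shift) % 4, m[mask])
        s1 = decode_seq(m1.reshape(-1))
        s2 = decode_seq(m2.reshape(-1))
        for j in range(nc):
            pairs.append(ReadPair(f"sim{serial:08d}",
                                  s1[j * rl:(j + 1) * rl], qual,
                                  s2[j * rl:(j + 1) * rl], qual))
            serial += 1
    return pairs


# ---------------------------------------------------------------------------
# truth <-> GFF3


def truth_to_gff(truths: List[SimulatedTruth]) -> List[GffRecord]:
    out = []
    for t in truths:
        out.append(GffRecord(
            chrom=t.chrom, start=t.pos - 1, end=t.pos,
            type="transposable_element_insertion_site",
            source="tecaller-sim", strand=t.strand,
            attributes={"TE": t.te_family, "TSD": t.tsd_seq or "NA"}))
    return out


def truth_from_gff(records: List[GffRecord]) -> List[SimulatedTruth]:
    out = []
    for r in records:
        tsd = r.attributes.get("TSD", "NA")
        out.append(SimulatedTruth(
            chrom=r.chrom, pos=r.end, te_family=r.attributes.get("TE", "NA"),
            tsd_seq="" if tsd == "NA" else tsd, strand=r.strand))
    return out
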