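"""Synthetic stand-ins for the rice benchmark inputs.

The benchmark this package ships is download-free: the TE library and the
reference chromosome are generated deterministically in code rather than
fetched.  The library carries the fourteen rice family *names* (seven DNA
transposons, seven LTR retroelements) but synthetic random consensus
sequences — family identity, length class and TSD length are what the
caller exercises, not the actual rice base composition.  Lengths are
field-realistic: MITEs / small DNA transposons a few hundred bp,
retroelements several kb.  TSD lengths follow the family type: Tourist-like
MITEs 3 bp, hAT-like elements ~8-9 bp, CACTA 3 bp, LTR retroelements 5 bp.
"""

from __future__ import annotations

from typing import Dict

import numpy as np

from .io_formats import ReferenceGenome, TEFamily, TELibrary, decode_seq

# (name, length, tsd_len); DNA transposons first, then retroelements.
_FAMILY_SPECS = [
    ("mPing", 430, 3),
    ("nDart", 620, 9),
    ("Gaijin", 450, 3),
    ("spmlike", 1100, 3),
    ("Truncator", 750, 2),
    ("mGing", 380, 3),
    ("nDarz", 560, 9),
    ("Bajie", 4800, 5),
    ("Dasheng", 7500, 5),
    ("Retro1", 5200, 5),
    ("RIRE2", 8000, 5),
    ("RIRE3", 6800, 5),
    ("Copia2", 5100, 5),
    ("karma", 5900, 5),
]

_LIBRARY_SEED = 20170126  # fixed: the fixture library is one object, not a dial


def rice_like_library() -> TELibrary:
    """The 14-family synthetic benchmark TE library (deterministic)."""
    rng = np.random.default_rng(_LIBRARY_SEED)
    fams = []
    for name, length, tsd in _FAMILY_SPECS:
        seq = decode_seq(rng.integers(0, 4, size=length).astype(np.uint8))
        fams.append(TEFamily(name, seq, tsd))
    return TELibrary(fams)


def random_genome(length: int = 2_000_000, seed: int = 0,
                  chrom: str = "chr1", n_chroms: int = 1) -> ReferenceGenome:
    """A euchromatin-like (low-repeat) random reference genome."""
    rng = np.random.default_rng(seed)
    seqs: Dict[str, str] = {}
    per = length // n_chroms
    for i in range(n_chroms):
        name = chrom if n_chroms == 1 else f"{chrom}{i + 1}"
        seqs[name] = decode_seq(rng.integers(0, 4, size=per).astype(np.uint8))
    return ReferenceGenome(seqs)
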