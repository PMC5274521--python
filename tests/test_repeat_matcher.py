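"""Matcher tests, anchored by an exhaustive diagonal-enumeration oracle.

The oracle enumerates every (strand, diagonal) alignment between a read
and every consensus by brute force, lists all windows that start and end
on a match and carry at most the allowed mismatches, keeps only windows
not properly contained in another such window (maximality), and then
applies the reporting thresholds.  It shares no code with the seeded
kernel it checks.
"""

import numpy as np
import pytest

from tecaller import (ReadPair, RunConfig, TEFamily, TELibrary,
                      assign_family, classify_pair, find_repeat_hits)
from tecaller.io_formats import decode_seq, revcomp
from tecaller.repeat_matcher import (FULL_TE, JUNCTION, SUPPORTING,
                                     TE_3PRIME, TE_5PRIME, UNINFORMATIVE,
                                     LibraryIndex, RepeatHit)

from conftest import rand_seq


# ---------------------------------------------------------------------------
# oracle


def _diagonal_windows(read, cons, off, max_mm):
    """All maximal valid windows on one diagonal, as (rs, re, mm)."""
    n = len(read)
    m = len(cons)
    lo = max(0, -off)
    hi = min(n, m - off)
    if hi - lo < 1:
        return []
    is_match = [read[i] == cons[i + off] and read[i] != "N"
                for i in range(lo, hi)]
    matches = [i + lo for i, ok in enumerate(is_match) if ok]
    valid = []
    for a in range(len(matches)):
        mm = 0
        for b in range(a, len(matches)):
            mm = (matches[b] - matches[a] + 1) - (b - a + 1)
            if mm > max_mm:
                break
            valid.append((matches[a], matches[b] + 1, mm))
    maximal = [w for w in valid
               if not any(v[0] <= w[0] and w[1] <= v[1] and v != w
                          for v in valid)]
    return maximal


def oracle_hits(read, library, cfg):
    hits = []
    for fam in library:
        for strand, r in (("+", read), ("-", revcomp(read))):
            L = len(read)
            for off in range(-L + 1, len(fam.consensus)):
                for rs, re, mm in _diagonal_windows(r, fam.consensus, off,
                                                    cfg.mismatch):
                    length = re - rs
                    score = length - 2 * mm
                    if length < cfg.len_cut_match or score < cfg.min_score:
                        continue
                    # disjoint exact seed_len runs
                    runs, run = [], 0
                    for i in range(rs, re):
                        if r[i] == fam.consensus[i + off] and r[i] != "N":
                            run += 1
                        else:
                            runs.append(run)
                            run = 0
                    runs.append(run)
                    if sum(x // cfg.seed_len for x in runs) < cfg.min_seed_count:
                        continue
                    if strand == "-":
                        rs, re = L - re, L - rs
                    hits.append(RepeatHit(fam.name, rs, re,
                                          rs if strand == "+" else 0, 0,
                                          strand, mm, score))
                    # te interval recomputed below from read interval
    return hits


def oracle_merged_keys(read, library, cfg):
    """Oracle hits reduced by the same-family overlap-merge contract,
    as comparable (family, read interval, strand, mm, score) keys."""
    hits = oracle_hits(read, library, cfg)
    byfam = {}
    for h in hits:
        byfam.setdefault(h.te_family, []).append(h)
    keys = set()
    for fam, fh in byfam.items():
        fh = sorted(fh, key=lambda h: (h.read_start, h.read_end))
        groups = []
        extent = -1
        for h in fh:
            if groups and h.read_start >= extent:
                extent = -1
            if extent < 0:
                groups.append([])
            groups[-1].append(h)
            extent = max(extent, h.read_end)
        for g in groups:
            best = min(g, key=lambda h: (-h.score, h.mismatches,
                                         h.read_start))
            keys.add((fam, best.read_start, best.read_end, best.strand,
                      best.mismatches, best.score))
    return keys


# ---------------------------------------------------------------------------


class TestFindRepeatHits:
    def test_exact_terminal_substring(self, small_library, cfg):
        rng = np.random.default_rng(0)
        fam = small_library["alpha"]
        L = len(fam.consensus)
        read = fam.consensus[-40:] + rand_seq(rng, 60)
        hits = find_repeat_hits(read, small_library, cfg)
        hits = [h for h in hits if h.te_family == "alpha"]
        assert len(hits) == 1
        h = hits[0]
        assert (h.read_interval, h.te_interval) == ((0, 40), (L - 40, L))
        assert h.strand == "+" and h.mismatches == 0 and h.score == 40

    def test_reverse_strand_hit(self, small_library, cfg):
        rng = np.random.default_rng(1)
        fam = small_library["beta"]
        read = rand_seq(rng, 50) + revcomp(fam.consensus[:30])
        hits = [h for h in find_repeat_hits(read, small_library, cfg)
                if h.te_family == "beta"]
        assert len(hits) == 1
        h = hits[0]
        assert h.strand == "-"
        # the maximal window covers the planted 30 bp (it may extend a
        # little into the random prefix through coincidental matches)
        assert h.read_start <= 50 and h.read_end == 80
        assert h.te_start == 0 and h.te_end >= 30
        assert h.mismatches <= cfg.mismatch

    def test_unrelated_read_has_no_hits(self, small_library, cfg):
        # poly-A shares no qualifying stretch with the random consensi
        assert find_repeat_hits("A" * 100, small_library, cfg) == []

    def test_empty_library_error(self, cfg):
        with pytest.raises(ValueError):
            TELibrary([])

    def test_oracle_equivalence_random_and_planted_reads(self, small_library,
                                                         cfg):
        """Seeded kernel == exhaustive enumeration, on random 100 bp reads
        and on reads with planted TE fragments (both strands, with errors)."""
        rng = np.random.default_rng(99)
        reads = [rand_seq(rng, 100) for _ in range(120)]
        for _ in range(60):
            fam = small_library.families[rng.integers(0, 3)]
            L = len(fam.consensus)
            flen = int(rng.integers(8, 60))
            ts = int(rng.integers(0, L - flen + 1))
            piece = fam.consensus[ts:ts + flen]
            if rng.integers(0, 2):
                piece = revcomp(piece)
            pl = list(piece)
            for _ in range(int(rng.integers(0, 3))):  # up to 2 errors
                i = int(rng.integers(0, flen))
                pl[i] = "ACGT"[(("ACGT".index(pl[i])) + 1) % 4]
            piece = "".join(pl)
            pos = int(rng.integers(0, 101 - flen))
            bg = rand_seq(rng, 100)
            reads.append(bg[:pos] + piece + bg[pos + flen:])
        index = LibraryIndex(small_library, cfg)
        got_all = index.match_batch(reads)
        for read, got in zip(reads, got_all):
            got_keys = {(h.te_family, h.read_start, h.read_end, h.strand,
                         h.mismatches, h.score) for h in got}
            assert got_keys == oracle_merged_keys(read, small_library, cfg)

    def test_te_interval_consistent_with_read_interval(self, small_library,
                                                       cfg):
        rng = np.random.default_rng(5)
        fam = small_library["gamma"]
        read = rand_seq(rng, 30) + fam.consensus[100:160] + rand_seq(rng, 10)
        for h in find_repeat_hits(read, small_library, cfg):
            if h.te_family != "gamma":
                continue
            assert h.te_end - h.te_start == h.read_end - h.read_start
            seg = read[h.read_start:h.read_end]
            ref = fam.consensus[h.te_start:h.te_end]
            if h.strand == "-":
                seg = revcomp(seg)
            assert sum(a != b for a, b in zip(seg, ref)) == h.mismatches

    def test_determinism(self, small_library, cfg):
        rng = np.random.default_rng(8)
        fam = small_library["alpha"]
        read = fam.consensus[:50] + rand_seq(rng, 50)
        assert (find_repeat_hits(read, small_library, cfg)
                == find_repeat_hits(read, small_library, cfg))


class TestAssignFamily:
    def _hit(self, fam, score, mm):
        return RepeatHit(fam, 0, score, 0, score, "+", mm, score)

    def test_highest_score_wins(self):
        assert assign_family([self._hit("F1", 38, 0),
                              self._hit("F2", 20, 0)]) == "F1"

    def test_tie_breaks_on_mismatches_then_name(self):
        assert assign_family([RepeatHit("beta", 0, 20, 0, 20, "+", 1, 18),
                              RepeatHit("alpha", 0, 22, 0, 22, "+", 2, 18)
                              ]) == "beta"
        assert assign_family([self._hit("beta", 20, 1),
                              self._hit("alpha", 20, 1)]) == "alpha"

    def test_single_hit(self):
        assert assign_family([self._hit("x", 15, 0)]) == "x"

    def test_empty_error(self):
        with pytest.raises(ValueError):
            assign_family([])


class TestClassifyPair:
    def _pair(self, s1, s2):
        return ReadPair("p", s1, "I" * len(s1), s2, "I" * len(s2))

    def _classify(self, library, cfg, s1, s2):
        idx = LibraryIndex(library, cfg)
        h1, h2 = idx.match_batch([s1, s2])
        return classify_pair(self._pair(s1, s2), h1, h2, library, cfg)

    def test_full_te_mate_promotes_supporting(self, small_library, cfg,
                                              small_genome):
        fam = small_library["beta"]
        s1 = fam.consensus[200:300]
        s2 = small_genome.sequences["chrA"][1000:1100]
        c1, c2 = self._classify(small_library, cfg, s1, s2)
        assert c1.category == FULL_TE and c1.te_family == "beta"
        assert c2.category == SUPPORTING and c2.te_family == "beta"

    def test_junction_read_trimmed_to_flank(self, small_library, cfg,
                                            small_genome):
        fam = small_library["alpha"]
        flank = small_genome.sequences["chrA"][5000:5065]
        s1 = fam.consensus[-35:] + flank   # TE 3' end then genome
        s2 = small_genome.sequences["chrA"][3000:3100]
        c1, c2 = self._classify(small_library, cfg, s1, s2)
        assert c1.category == JUNCTION
        assert c1.flank_seq == flank
        assert c1.te_side == TE_3PRIME
        assert not c1.fragments[0].flank_left_of_te
        # junction partners do not promote supporting reads
        assert c2.category == UNINFORMATIVE

    def test_flank_shorter_than_len_cut_trim_is_dropped(self, small_library,
                                                        cfg, small_genome):
        fam = small_library["alpha"]
        s1 = fam.consensus[-92:] + small_genome.sequences["chrA"][5000:5008]
        s2 = small_genome.sequences["chrA"][3000:3100]
        c1, _ = self._classify(small_library, cfg, s1, s2)
        assert c1.category != JUNCTION      # 8 bp flank < 10
        assert c1.category == FULL_TE       # overhang < len_cut_trim each side

    def test_internal_hit_blocks_supporting_promotion(self, small_library,
                                                      cfg, small_genome):
        fam = small_library["beta"]
        g = small_genome.sequences["chrA"]
        s1 = fam.consensus[200:300]                      # FULL_TE
        s2 = g[1000:1040] + fam.consensus[400:420] + g[1040:1080]
        c1, c2 = self._classify(small_library, cfg, s1, s2)
        assert c1.category == FULL_TE
        assert c2.category == UNINFORMATIVE and c2.blocks_supporting

    def test_short_consensus_spanned_gives_two_junctions(self, cfg,
                                                         small_genome):
        rng = np.random.default_rng(17)
        tiny = TELibrary([TEFamily("tiny", rand_seq(rng, 60), 4)])
        g = small_genome.sequences["chrA"]
        s1 = g[100:120] + tiny["tiny"].consensus + g[120:140]
        s2 = g[9000:9100]
        c1, _ = self._classify(tiny, cfg, s1, s2)
        assert c1.category == JUNCTION and len(c1.fragments) == 2
        sides = {(f.te_side, f.flank_left_of_te) for f in c1.fragments}
        assert sides == {(TE_5PRIME, True), (TE_3PRIME, False)}
        assert c1.fragments[0].flank_seq == g[100:120]
        assert c1.fragments[1].flank_seq == g[120:140]

    def test_flank_is_verbatim_substring(self, small_library, cfg):
        rng = np.random.default_rng(23)
        for _ in range(30):
            fam = small_library.families[int(rng.integers(0, 3))]
            cut = int(rng.integers(12, 80))
            s1 = fam.consensus[:cut] + rand_seq(rng, 100 - cut)
            s2 = rand_seq(rng, 100)
            c1, _ = self._classify(small_library, cfg, s1, s2)
            for fr in c1.fragments:
                assert fr.flank_seq in s1

    def test_category_partition(self, small_library, cfg, small_genome):
        # no mate may be SUPPORTING while carrying a hit itself
        fam = small_library["gamma"]
        g = small_genome.sequences["chrA"]
        cases = [
            (fam.consensus[:100], fam.consensus[100:200]),
            (fam.consensus[:50] + g[100:150], g[200:300]),
            (g[400:500], g[600:700]),
        ]
        allowed = {FULL_TE, JUNCTION, SUPPORTING, UNINFORMATIVE}
        idx = LibraryIndex(small_library, cfg)
        for s1, s2 in cases:
            h1, h2 = idx.match_batch([s1, s2])
            c1, c2 = classify_pair(self._pair(s1, s2), h1, h2,
                                   small_library, cfg)
            assert {c1.category, c2.category} <= allowed
            if c1.category == SUPPORTING:
                assert not h1
            if c2.category == SUPPORTING:
                assert not h2
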