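"""Numba kernels for the repeat matcher and the reference mapper.

Sequences arrive as uint8 code arrays (A0 C1 G2 T3 N4).  Concatenated
multi-sequence arrays (TE library, multi-chromosome genome) are padded
between segments with sentinel code 4, which never matches anything, so
no alignment window or k-mer can bridge two segments.

All loops are written for numba's nopython mode; the Python wrappers
around them live in repeat_matcher.py and genome_mapper.py.
"""

from __future__ import annotations

import numpy as np
from numba import njit

SENTINEL = 4
LIB_PAD = 15     # > any supported mismatch budget
GENOME_PAD = 512  # > any supported fragment length


@njit(cache=False)
def build_kmer_index(codes, k):
    """Counting-sort k-mer index: returns (bucket_start, positions).

    bucket_start has 4**k + 1 entries; positions of k-mers containing a
    sentinel/N code are not indexed.
    """
    n = codes.shape[0]
    nk = 1 << (2 * k)
    mask = nk - 1
    counts = np.zeros(nk + 1, dtype=np.int64)
    key = 0
    last_bad = -1
    for i in range(n):
        c = codes[i]
        if c >= 4:
            last_bad = i
        key = ((key << 2) | (c & 3)) & mask
        if i >= k - 1 and last_bad <= i - k:
            counts[key + 1] += 1
    bucket_start = np.cumsum(counts)
    positions = np.empty(bucket_start[-1], dtype=np.int64)
    fill = bucket_start[:-1].copy()
    key = 0
    last_bad = -1
    for i in range(n):
        c = codes[i]
        if c >= 4:
            last_bad = i
        key = ((key << 2) | (c & 3)) & mask
        if i >= k - 1 and last_bad <= i - k:
            positions[fill[key]] = i - k + 1
            fill[key] += 1
    return bucket_start, positions


# ---------------------------------------------------------------------------
# repeat matcher
#
# A reportable hit is a maximal ungapped window on one (read, library)
# diagonal with:
#   mismatches <= max_mm, length >= min_len, matches - mismatches >= min_score,
#   and >= min_seeds disjoint exact runs of seed length k (BLAT-tile analogue).
# Any such window necessarily has two same-diagonal seed k-mers whose read
# offsets differ by >= k, so scanning only diagonals satisfying that
# condition loses nothing.

_DIAG_BIAS = 1 << 12  # diagonals are >= -read_len; bias keeps sort keys positive
_OFF_BITS = 20
_OFF_MASK = (1 << _OFF_BITS) - 1


@njit(cache=False)
def match_reads_batch(reads_flat, read_starts, read_lens, lib,
                      bucket_start, bucket_pos, k,
                      max_mm, min_len, min_score, min_seeds, out):
    """Find qualifying hits for a batch of reads against the library.

    out: int64 (cap, 8) rows [read_idx, orient, r_start, r_end, l_start,
    l_end, mismatches, score]; read coords are in the *scanned* orientation
    (orient 1 = reverse complement).  Returns number of rows, or -1 if out
    overflowed.
    """
    nk_mask = (1 << (2 * k)) - 1
    lib_len = lib.shape[0]
    cap = out.shape[0]
    nout = 0
    seedbuf = np.empty(1 << 16, dtype=np.int64)
    rcbuf = np.empty(1 << 12, dtype=np.uint8)
    bounds = np.empty((1 << 12) + 2, dtype=np.int64)

    for ridx in range(read_starts.shape[0]):
        r0 = read_starts[ridx]
        rl = read_lens[ridx]
        if rl < k:
            continue
        for orient in range(2):
            if orient == 0:
                read = reads_flat[r0:r0 + rl]
            else:
                for j in range(rl):
                    c = reads_flat[r0 + rl - 1 - j]
                    rcbuf[j] = 3 - c if c < 4 else 4
                read = rcbuf[:rl]

            # --- seed collection
            ns = 0
            key = 0
            last_bad = -1
            overflow = False
            for i in range(rl):
                c = read[i]
                if c >= 4:
                    last_bad = i
                key = ((key << 2) | (c & 3)) & nk_mask
                if i >= k - 1 and last_bad <= i - k:
                    off = i - k + 1
                    b0 = bucket_start[key]
                    b1 = bucket_start[key + 1]
                    for bi in range(b0, b1):
                        d = bucket_pos[bi] - off
                        if ns >= seedbuf.shape[0]:
                            overflow = True
                            break
                        seedbuf[ns] = ((d + _DIAG_BIAS) << _OFF_BITS) | off
                        ns += 1
                    if overflow:
                        break
            if overflow:
                return -1
            if ns == 0:
                continue
            sb = seedbuf[:ns]
            sb.sort()

            # --- per-diagonal scan (two-disjoint-seed diagonals only)
            p = 0
            while p < ns:
                dkey = sb[p] >> _OFF_BITS
                q = p
                while q < ns and (sb[q] >> _OFF_BITS) == dkey:
                    q += 1
                min_off = sb[p] & _OFF_MASK
                max_off = sb[q - 1] & _OFF_MASK
                p_next = q
                if max_off - min_off < k:
                    p = p_next
                    continue
                d = dkey - _DIAG_BIAS
                i0 = 0 if d >= 0 else -d
                i1 = rl if lib_len - d > rl else lib_len - d
                # mismatch positions along the diagonal
                nb = 1
                bounds[0] = i0 - 1
                for i in range(i0, i1):
                    a = read[i]
                    b = lib[i + d]
                    if a != b or a >= 4:
                        bounds[nb] = i
                        nb += 1
                bounds[nb] = i1
                nmm = nb - 1
                # enumerate maximal windows: a window spans bounds[ii] ..
                # bounds[jj] exclusive, carries kk = jj-ii-1 mismatches, and
                # must start and end on a match (non-empty first/last run);
                # it is maximal when no valid window properly contains it,
                # i.e. it cannot be extended through an adjacent mismatch
                # run to another match while staying within the budget.
                for ii in range(nmm + 1):
                    if bounds[ii + 1] - bounds[ii] - 1 <= 0:
                        continue  # window would start on a mismatch
                    for kk in range(max_mm + 1):
                        jj = ii + kk + 1
                        if jj > nmm + 1:
                            break
                        if bounds[jj] - bounds[jj - 1] - 1 <= 0:
                            continue  # window would end on a mismatch
                        s = bounds[ii] + 1
                        e = bounds[jj] - 1
                        extendable = False
                        ii2 = ii - 1
                        lo2 = jj - 1 - max_mm
                        while ii2 >= 0 and ii2 >= lo2:
                            if bounds[ii2 + 1] - bounds[ii2] - 1 > 0:
                                extendable = True
                                break
                            ii2 -= 1
                        if not extendable:
                            jj2 = jj + 1
                            hi2 = ii + 1 + max_mm
                            while jj2 <= nmm + 1 and jj2 <= hi2:
                                if bounds[jj2] - bounds[jj2 - 1] - 1 > 0:
                                    extendable = True
                                    break
                                jj2 += 1
                        if extendable:
                            continue
                        length = e - s + 1
                        if length < min_len:
                            continue
                        score = length - 2 * kk
                        if score < min_score:
                            continue
                        # disjoint exact seed runs inside the window
                        nseed = 0
                        prev = s - 1
                        for t in range(ii + 1, jj):
                            nseed += (bounds[t] - prev - 1) // k
                            prev = bounds[t]
                        nseed += (e - prev) // k
                        if nseed < min_seeds:
                            continue
                        if nout >= cap:
                            return -1
                        out[nout, 0] = ridx
                        out[nout, 1] = orient
                        out[nout, 2] = s
                        out[nout, 3] = e + 1
                        out[nout, 4] = s + d
                        out[nout, 5] = e + 1 + d
                        out[nout, 6] = kk
                        out[nout, 7] = score
                        nout += 1
                p = p_next
    return nout


# ---------------------------------------------------------------------------
# reference mapper
#
# End-to-end placement of a fragment with <= max_mm substitutions, both
# strands.  Completeness: fragments of length >= 3k use three disjoint
# exact k-mer probes (pigeonhole over max_mm <= 2); shorter fragments
# enumerate all <= max_mm substitution neighbours of their k-prefix.


@njit(cache=False)
def _verify(frag, genome, pos, max_mm):
    mm = 0
    for j in range(frag.shape[0]):
        a = frag[j]
        b = genome[pos + j]
        if a != b or a >= 4:
            mm += 1
            if mm > max_mm:
                return -1
    return mm


@njit(cache=False)
def _chrom_of(chrom_starts, pos):
    # chrom_starts: start offset of each chromosome in the padded array
    lo = 0
    hi = chrom_starts.shape[0]
    while hi - lo > 1:
        mid = (lo + hi) // 2
        if chrom_starts[mid] <= pos:
            lo = mid
        else:
            hi = mid
    return lo


@njit(cache=False)
def map_fragments_batch(frags_flat, frag_starts, frag_lens, genome,
                        chrom_starts, chrom_ends,
                        bucket_start, bucket_pos, k, max_mm, results):
    """Best end-to-end placement per fragment.

    results: int64 (n, 5) rows [found, best_pos, strand(0=+,1=-), mismatches,
    n_co_optimal].  best placement = lexicographically smallest
    (mismatches, position, strand).
    """
    glen = genome.shape[0]
    candbuf = np.empty(1 << 16, dtype=np.int64)
    rcbuf = np.empty(1 << 12, dtype=np.uint8)

    for fi in range(frag_starts.shape[0]):
        f0 = frag_starts[fi]
        fl = frag_lens[fi]
        best_mm = max_mm + 1
        best_pos = -1
        best_strand = 0
        n_opt = 0
        for orient in range(2):
            if orient == 0:
                frag = frags_flat[f0:f0 + fl]
            else:
                for j in range(fl):
                    c = frags_flat[f0 + fl - 1 - j]
                    rcbuf[j] = 3 - c if c < 4 else 4
                frag = rcbuf[:fl]
            nc = 0
            if fl >= 3 * k:
                # three disjoint exact probes
                mid = ((fl - k) // 2 // 1)
                for pidx in range(3):
                    off = 0 if pidx == 0 else (mid if pidx == 1 else fl - k)
                    key = 0
                    bad = False
                    for t in range(k):
                        c = frag[off + t]
                        if c >= 4:
                            bad = True
                            break
                        key = (key << 2) | c
                    if bad:
                        continue
                    for bi in range(bucket_start[key], bucket_start[key + 1]):
                        cand = bucket_pos[bi] - off
                        if 0 <= cand and cand + fl <= glen:
                            if nc < candbuf.shape[0]:
                                candbuf[nc] = cand
                                nc += 1
                # dedupe (same placement via several probes)
                if nc > 1:
                    cb = candbuf[:nc]
                    cb.sort()
                    w = 1
                    for t in range(1, nc):
                        if candbuf[t] != candbuf[t - 1]:
                            candbuf[w] = candbuf[t]
                            w += 1
                    nc = w
            else:
                # prefix-neighbour enumeration (complete for max_mm <= 2)
                key0 = 0
                bad = False
                for t in range(k):
                    c = frag[t]
                    if c >= 4:
                        bad = True
                        break
                    key0 = (key0 << 2) | c
                if not bad:
                    nkeys = 0
                    # depth 0
                    keys = np.empty(1 + 3 * k + 9 * k * (k - 1) // 2,
                                    dtype=np.int64)
                    keys[nkeys] = key0
                    nkeys += 1
                    if max_mm >= 1:
                        for i in range(k):
                            sh = 2 * (k - 1 - i)
                            ci = (key0 >> sh) & 3
                            for b in range(4):
                                if b != ci:
                                    keys[nkeys] = key0 + ((b - ci) << sh)
                                    nkeys += 1
                    if max_mm >= 2:
                        for i in range(k):
                            shi = 2 * (k - 1 - i)
                            ci = (key0 >> shi) & 3
                            for j2 in range(i + 1, k):
                                shj = 2 * (k - 1 - j2)
                                cj = (key0 >> shj) & 3
                                for b1 in range(4):
                                    if b1 == ci:
                                        continue
                                    for b2 in range(4):
                                        if b2 == cj:
                                            continue
                                        keys[nkeys] = (key0
                                                       + ((b1 - ci) << shi)
                                                       + ((b2 - cj) << shj))
                                        nkeys += 1
                    for kidx in range(nkeys):
                        key = keys[kidx]
                        for bi in range(bucket_start[key], bucket_start[key + 1]):
                            cand = bucket_pos[bi]
                            if cand + fl <= glen:
                                if nc < candbuf.shape[0]:
                                    candbuf[nc] = cand
                                    nc += 1
            # verify candidates
            for t in range(nc):
                cand = candbuf[t]
                ci = _chrom_of(chrom_starts, cand)
                if cand + fl > chrom_ends[ci]:
                    continue
                mm = _verify(frag, genome, cand, max_mm)
                if mm < 0:
                    continue
                if mm < best_mm:
                    best_mm = mm
                    best_pos = cand
                    best_strand = orient
                    n_opt = 1
                elif mm == best_mm:
                    n_opt += 1
                    if cand < best_pos or (cand == best_pos
                                           and orient < best_strand):
                        best_pos = cand
                        best_strand = orient
        if best_pos >= 0:
            results[fi, 0] = 1
            results[fi, 1] = best_pos
            results[fi, 2] = best_strand
            results[fi, 3] = best_mm
            results[fi, 4] = n_opt
        else:
            results[fi, 0] = 0
    return 0
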