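"""Numba-compiled dynamic-programming kernels.

Everything in this module operates on uint8-encoded DNA (A=0, C=1, G=2,
T=3, N=4; the numeric order *is* the lexicographic order used by the code
generator).  An N never matches anything, including another N.

The kernels implement the sequence-Levenshtein distance (minimum over the
last row and last column of the unit-cost edit-distance matrix), its
short-circuited bounded variant, the greedy lexicographic code closure,
the clamp-anchored embedded distance used for decoding, and a sliding
approximate clamp search.  Short-circuiting relies on the fact that the
row minima of the Levenshtein matrix are non-decreasing from row to row,
so once the current row minimum and the running last-column minimum both
reach the bound no smaller value can appear.
"""

from __future__ import annotations

import numpy as np
from numba import njit

_ENC = np.full(256, 255, dtype=np.uint8)
for _i, _c in enumerate("ACGT"):
    _ENC[ord(_c)] = _i
    _ENC[ord(_c.lower())] = _i
_ENC[ord("N")] = 4
_ENC[ord("n")] = 4

_DEC = np.frombuffer(b"ACGTN", dtype=np.uint8)


def encode(seq: str) -> np.ndarray:
    """Encode a DNA string to uint8 codes; raises on non-ACGTN characters."""
    arr = _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr == 255).any():
        bad = seq[int(np.argmax(arr == 255))]
        raise ValueError(f"invalid DNA character {bad!r} in sequence")
    return arr


def decode(arr: np.ndarray) -> str:
    return _DEC[arr].tobytes().decode("ascii")


@njit(cache=False)
def sl_bounded(a, b, bound):  # pragma: no cover - exercised via wrappers
    """Sequence-Levenshtein distance, saturated at ``bound``.

    Returns min(d, bound) where d = min over the last row and last column
    of the edit-distance DP matrix between ``a`` and ``b``.
    """
    m = a.shape[0]
    n = b.shape[0]
    prev = np.empty(n + 1, np.int64)
    cur = np.empty(n + 1, np.int64)
    for j in range(n + 1):
        prev[j] = j
    colmin = n  # D[0][n]
    for i in range(1, m + 1):
        cur[0] = i
        rowmin = i
        for j in range(1, n + 1):
            ai = a[i - 1]
            if ai == b[j - 1] and ai < 4:
                v = prev[j - 1]
            else:
                v = prev[j - 1] + 1
            w = prev[j] + 1
            if w < v:
                v = w
            w = cur[j - 1] + 1
            if w < v:
                v = w
            cur[j] = v
            if v < rowmin:
                rowmin = v
        if cur[n] < colmin:
            colmin = cur[n]
        if rowmin >= bound and colmin >= bound:
            return bound
        tmp = prev
        prev = cur
        cur = tmp
    best = colmin
    for j in range(n + 1):
        if prev[j] < best:
            best = prev[j]
    if best > bound:
        best = bound
    return best


@njit(cache=False)
def sl_distance_arr(a, b):  # pragma: no cover
    return sl_bounded(a, b, a.shape[0] + b.shape[0] + 1)


@njit(cache=False)
def pairwise_min_distance(mat):  # pragma: no cover
    """Minimum sequence-Levenshtein distance over all unordered pairs."""
    n = mat.shape[0]
    best = mat.shape[1] * 2 + 1
    for i in range(n):
        for j in range(i + 1, n):
            d = sl_bounded(mat[i], mat[j], best)
            if d < best:
                best = d
                if best == 0:
                    return 0
    return best


@njit(cache=False)
def pairwise_mean_distance(mat):  # pragma: no cover
    """Per-row mean sequence-Levenshtein distance to all other rows."""
    n = mat.shape[0]
    big = mat.shape[1] * 2 + 1
    sums = np.zeros(n, np.int64)
    for i in range(n):
        for j in range(i + 1, n):
            d = sl_bounded(mat[i], mat[j], big)
            sums[i] += d
            sums[j] += d
    return sums / (n - 1)


@njit(cache=False)
def conway_closure(length, dmin, use_triplet, use_gc, use_selfcomp,
                   stop_after, cap):  # pragma: no cover
    """Greedy lexicographic closure over all 4**length words.

    Words are enumerated in A<C<G<T order; a word failing a composition
    filter is skipped, otherwise it is accepted iff its bounded distance
    to every previously accepted word is >= dmin.  Subtrees rooted at a
    homopolymer triplet are pruned wholesale.  Returns (accepted, n,
    exhausted) where exhausted is False iff the preallocated capacity was
    hit before enumeration finished.
    """
    accepted = np.zeros((cap, length), np.uint8)
    n_acc = 0
    word = np.zeros(length, np.uint8)
    while True:
        ok = True
        trip_end = -1
        if use_triplet:
            run = 1
            for i in range(1, length):
                if word[i] == word[i - 1]:
                    run += 1
                    if run >= 3:
                        ok = False
                        trip_end = i
                        break
                else:
                    run = 1
        if ok and use_gc:
            gc = 0
            for i in range(length):
                if word[i] == 1 or word[i] == 2:
                    gc += 1
            if 10 * gc < 4 * length or 10 * gc > 6 * length:
                ok = False
        if ok and use_selfcomp:
            sc = True
            for i in range(length):
                if word[i] != 3 - word[length - 1 - i]:
                    sc = False
                    break
            if sc:
                ok = False
        if ok:
            good = True
            for k in range(n_acc):
                if sl_bounded(accepted[k], word, dmin) < dmin:
                    good = False
                    break
            if good:
                if n_acc >= cap:
                    return accepted, n_acc, False
                for i in range(length):
                    accepted[n_acc, i] = word[i]
                n_acc += 1
                if stop_after > 0 and n_acc >= stop_after:
                    return accepted, n_acc, True
        if trip_end >= 0:
            # every word sharing this prefix contains the triplet
            for j in range(trip_end + 1, length):
                word[j] = 3
        i = length - 1
        while i >= 0 and word[i] == 3:
            word[i] = 0
            i -= 1
        if i < 0:
            return accepted, n_acc, True
        word[i] += 1


@njit(cache=False)
def embedded_bounded(b, w, bound):  # pragma: no cover
    """Distance of barcode ``b`` embedded at the start of window ``w``.

    DP rows index prefixes of b, columns prefixes of w; b must be fully
    consumed while w may terminate at any position (minimum over the
    final row).  Callers anchor at the clamp by passing both sequences
    reversed.  Saturated at ``bound``.
    """
    m = b.shape[0]
    n = w.shape[0]
    prev = np.empty(n + 1, np.int64)
    cur = np.empty(n + 1, np.int64)
    for j in range(n + 1):
        prev[j] = j
    for i in range(1, m + 1):
        cur[0] = i
        rowmin = i
        for j in range(1, n + 1):
            bi = b[i - 1]
            if bi == w[j - 1] and bi < 4:
                v = prev[j - 1]
            else:
                v = prev[j - 1] + 1
            x = prev[j] + 1
            if x < v:
                v = x
            x = cur[j - 1] + 1
            if x < v:
                v = x
            cur[j] = v
            if v < rowmin:
                rowmin = v
        if rowmin >= bound:
            return bound
        tmp = prev
        prev = cur
        cur = tmp
    best = bound
    for j in range(n + 1):
        if prev[j] < best:
            best = prev[j]
    return best


@njit(cache=False)
def embedded_context_bounded(a, w, bound):  # pragma: no cover
    """Distance of candidate-plus-context ``a`` against window ``w``.

    ``a`` is the reversed barcode followed by the reversed upstream
    context; the window must be fully consumed (minimum over the final
    DP column) while ``a`` may terminate at any position.  Scoring the
    junk bases 5' of the barcode against the known context separates
    shifted alignments of impostor barcodes that would otherwise tie.
    Saturated at ``bound``.
    """
    m = a.shape[0]
    n = w.shape[0]
    prev = np.empty(n + 1, np.int64)
    cur = np.empty(n + 1, np.int64)
    for j in range(n + 1):
        prev[j] = j
    colmin = n  # D[0][n]
    for i in range(1, m + 1):
        cur[0] = i
        rowmin = i
        for j in range(1, n + 1):
            ai = a[i - 1]
            if ai == w[j - 1] and ai < 4:
                v = prev[j - 1]
            else:
                v = prev[j - 1] + 1
            x = prev[j] + 1
            if x < v:
                v = x
            x = cur[j - 1] + 1
            if x < v:
                v = x
            cur[j] = v
            if v < rowmin:
                rowmin = v
        if cur[n] < colmin:
            colmin = cur[n]
        if rowmin >= bound and colmin >= bound:
            return bound
        tmp = prev
        prev = cur
        cur = tmp
    if colmin > bound:
        colmin = bound
    return colmin


@njit(cache=False)
def decode_window(pool_rev, w_rev, radius, ctx_rev, use_ctx):  # pragma: no cover
    """Assign a (reversed) window to a pool of (reversed) barcodes.

    With ``use_ctx`` the candidate is extended by the reversed upstream
    context and the window must be fully explained; otherwise the
    barcode-only free-end distance is used.  Returns (best_index,
    best_distance, n_tied); best_distance saturates at radius+1 when no
    candidate lies within the radius.
    """
    best = radius + 1
    besti = -1
    nbest = 0
    m = pool_rev.shape[1]
    n = w_rev.shape[0]
    ext = 0
    if use_ctx:
        ext = ctx_rev.shape[0]
        if ext > n:
            ext = n
    a = np.empty(m + ext, np.uint8)
    for k in range(pool_rev.shape[0]):
        if use_ctx:
            for i in range(m):
                a[i] = pool_rev[k, i]
            for i in range(ext):
                a[m + i] = ctx_rev[i]
            d = embedded_context_bounded(a, w_rev, best + 1)
        else:
            d = embedded_bounded(pool_rev[k], w_rev, best + 1)
        if d < best:
            best = d
            besti = k
            nbest = 1
        elif d == best and best <= radius:
            nbest += 1
    return besti, best, nbest


@njit(cache=False)
def decode_windows(pool_rev, wins, wlens, radius, ctx_rev, use_ctx,
                   out_idx, out_d, out_n):  # pragma: no cover
    for r in range(wins.shape[0]):
        w = wins[r, : wlens[r]]
        besti, best, nbest = decode_window(pool_rev, w, radius, ctx_rev,
                                           use_ctx)
        out_idx[r] = besti
        out_d[r] = best
        out_n[r] = nbest


@njit(cache=False)
def find_clamp(read, clamp, max_edits):  # pragma: no cover
    """Best clamp alignment: minimum edit count, ties by leftmost start.

    Returns (start, end, edits); (-1, -1, -1) when no start position
    aligns the clamp within ``max_edits``.  ``end`` is the read position
    just past the clamp alignment; among ends tying on edit count the
    one closest to start+len(clamp) wins (smaller end on a further tie).
    A strictly leftmost-qualifying rule would shift the anchor one base
    5' whenever max_edits >= 1 (deleting the first clamp base always
    costs one edit), so edit count takes priority over position.
    """
    n = read.shape[0]
    m = clamp.shape[0]
    wmax = m + max_edits
    prev = np.empty(wmax + 1, np.int64)
    cur = np.empty(wmax + 1, np.int64)
    g_ed = max_edits + 1
    g_start = -1
    g_end = -1
    for p in range(n - (m - max_edits) + 1):
        lim = n - p
        if lim > wmax:
            lim = wmax
        for j in range(lim + 1):
            prev[j] = j
        abandoned = False
        for i in range(1, m + 1):
            cur[0] = i
            rowmin = i
            for j in range(1, lim + 1):
                ci = clamp[i - 1]
                if ci == read[p + j - 1] and ci < 4:
                    v = prev[j - 1]
                else:
                    v = prev[j - 1] + 1
                x = prev[j] + 1
                if x < v:
                    v = x
                x = cur[j - 1] + 1
                if x < v:
                    v = x
                cur[j] = v
                if v < rowmin:
                    rowmin = v
            if rowmin >= g_ed:
                abandoned = True
                break
            tmp = prev
            prev = cur
            cur = tmp
        if abandoned:
            continue
        best = g_ed
        bestj = -1
        for j in range(lim + 1):
            if prev[j] < best:
                best = prev[j]
                bestj = j
            elif (
                prev[j] == best
                and bestj >= 0
                and (abs(j - m) < abs(bestj - m)
                     or (abs(j - m) == abs(bestj - m) and j < bestj))
            ):
                bestj = j
        if best < g_ed:
            g_ed = best
            g_start = p
            g_end = p + bestj
            if g_ed == 0:
                return g_start, g_end, 0
    if g_ed <= max_edits:
        return g_start, g_end, g_ed
    return -1, -1, -1
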