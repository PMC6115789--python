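"""Integer dynamic-programming kernels (numba-compiled).

Both kernels work in centi-kcal/mol integers on base-encoded sequences and
must reproduce, cell for cell, the sums computed by the pure-Python
re-scoring functions in :mod:`mirtarp.energy`; tracebacks re-derive
decisions from the filled matrices using the same arithmetic.
"""

from __future__ import annotations

import numpy as np
from numba import njit

from .energy import INF_CENTS

INF = INF_CENTS


@njit(cache=True)
def _two_loop(stack, bulge, internal, au_end, ninio_per_nt, ninio_max,
              p_outer, p_inner, l1, l2):
    if l1 == 0 and l2 == 0:
        return stack[p_outer, p_inner]
    if l1 == 0 or l2 == 0:
        size = l1 + l2
        e = bulge[size]
        if size == 1:
            e += stack[p_outer, p_inner]
        else:
            e += au_end[p_outer] + au_end[p_inner]
        return e
    asym = abs(l1 - l2) * ninio_per_nt
    if asym > ninio_max:
        asym = ninio_max
    return internal[l1 + l2] + asym + au_end[p_outer] + au_end[p_inner]


@njit(cache=True)
def duplex_fill(x, w, ptab, stack, bulge, internal, au_end,
                duplex_init, ninio_per_nt, ninio_max, max_loop):
    """Fill V[i, j] = min energy of a duplex whose 3'-most miRNA pair is (i, j).

    V includes the initiation term and the AU penalty of the 5'-most pair
    but not of pair (i, j) itself; the overall optimum is
    min(V[i, j] + au_end[pair(i, j)]).  Returns (V, Bi, Bj, best, bi, bj).
    """
    n = len(x)
    m = len(w)
    V = np.full((n, m), INF, dtype=np.int64)
    Bi = np.full((n, m), -1, dtype=np.int32)
    Bj = np.full((n, m), -1, dtype=np.int32)
    for i in range(n):
        for j in range(m):
            p = ptab[x[i], w[j]]
            if p < 0:
                continue
            best = duplex_init + au_end[p]
            bi = -1
            bj = -1
            i0 = i - max_loop - 1
            if i0 < 0:
                i0 = 0
            for i2 in range(i0, i):
                l1 = i - i2 - 1
                jmax = j + (max_loop - l1) + 1
                if jmax > m - 1:
                    jmax = m - 1
                for j2 in range(j + 1, jmax + 1):
                    if V[i2, j2] >= INF:
                        continue
                    p2 = ptab[x[i2], w[j2]]
                    e = V[i2, j2] + _two_loop(stack, bulge, internal, au_end,
                                              ninio_per_nt, ninio_max,
                                              p2, p, l1, j2 - j - 1)
                    if e < best:
                        best = e
                        bi = i2
                        bj = j2
            V[i, j] = best
            Bi[i, j] = bi
            Bj[i, j] = bj
    best = INF
    ei = -1
    ej = -1
    for i in range(n):
        for j in range(m):
            if V[i, j] >= INF:
                continue
            p = ptab[x[i], w[j]]
            e = V[i, j] + au_end[p]
            if e < best:
                best = e
                ei = i
                ej = j
    return V, Bi, Bj, best, ei, ej


@njit(cache=True)
def fold_fill(s, ptab, stack, bulge, internal, hairpin_ext, au_end,
              ninio_per_nt, ninio_max, max_loop, min_hairpin,
              ml_offset, ml_branch, ml_unpaired):
    """Zuker-style fill for intramolecular folding.

    V[i, j]: min energy of [i..j] with (i, j) paired (loop AU penalties for
    loops *inside*, not the outside face of (i, j)).
    WM[i, j]: min energy of a multiloop segment with >= 1 branch, where a
    branch (k, l) contributes V[k, l] + ml_branch + au_end, and each
    unpaired base ml_unpaired.
    W[j + 1]: min energy of the exterior prefix [0..j] (W[0] = 0).
    """
    n = len(s)
    V = np.full((n, n), INF, dtype=np.int64)
    WM = np.full((n, n), INF, dtype=np.int64)
    W = np.zeros(n + 1, dtype=np.int64)
    for span in range(1, n):
        for i in range(n - span):
            j = i + span
            p = ptab[s[i], s[j]]
            if p >= 0 and span > min_hairpin:
                best = hairpin_ext[span - 1] + au_end[p]
                lmax1 = max_loop
                if lmax1 > span - 2:
                    lmax1 = span - 2
                for l1 in range(lmax1 + 1):
                    k = i + 1 + l1
                    lmax2 = max_loop - l1
                    if lmax2 > j - k - 1:
                        lmax2 = j - k - 1
                    for l2 in range(lmax2 + 1):
                        l = j - 1 - l2
                        if V[k, l] >= INF:
                            continue
                        p2 = ptab[s[k], s[l]]
                        e = V[k, l] + _two_loop(stack, bulge, internal, au_end,
                                                ninio_per_nt, ninio_max, p, p2, l1, l2)
                        if e < best:
                            best = e
                for k in range(i + 2, j - 1):
                    if WM[i + 1, k - 1] >= INF or WM[k, j - 1] >= INF:
                        continue
                    e = ml_offset + au_end[p] + WM[i + 1, k - 1] + WM[k, j - 1]
                    if e < best:
                        best = e
                V[i, j] = best
            # WM over [i..j]
            best = INF
            if p >= 0 and V[i, j] < INF:
                best = V[i, j] + ml_branch + au_end[p]
            if WM[i + 1, j] < INF:
                e = WM[i + 1, j] + ml_unpaired
                if e < best:
                    best = e
            if WM[i, j - 1] < INF:
                e = WM[i, j - 1] + ml_unpaired
                if e < best:
                    best = e
            for k in range(i + 1, j + 1):
                if WM[i, k - 1] >= INF or WM[k, j] >= INF:
                    continue
                e = WM[i, k - 1] + WM[k, j]
                if e < best:
                    best = e
            WM[i, j] = best
    for j in range(n):
        best = W[j]
        for k in range(j + 1):
            if V[k, j] >= INF:
                continue
            p = ptab[s[k], s[j]]
            e = W[k] + V[k, j] + au_end[p]
            if e < best:
                best = e
        W[j + 1] = best
    return V, WM, W
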