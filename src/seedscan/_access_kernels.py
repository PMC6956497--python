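"""Numba kernels for the intra-molecular partition function and exact
region-wise unpaired probabilities.

Model (see docs/methods.md): non-crossing intra-molecular structures over
canonical pairs with a minimum hairpin loop of 3 nt; hairpin and interior
loops cost ``a + b*size`` (interior loops capped at 30 unpaired nt total);
stacked dyads use the inter-molecular stacking table; multiloops cost a
closing constant plus a per-branch constant, with free unpaired bases.
External (exterior-loop) bases are free.

All partition-function arrays are rescaled by ``s**(-len)`` per covered
nucleotide (Vienna-style) so that 300-nt sequences stay inside float64
range; the scale cancels in every probability.

Index convention: 1-based positions in arrays of shape (n+2, ...); entry 0
and n+1 are padding.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MIN_HAIRPIN = 3      # unpaired nt enclosed by a hairpin pair
MAX_INTLOOP = 30     # max total unpaired nt in an intra-molecular interior loop

# PAIR16[x*4+y] usage: weight tables are indexed by code(p,q) = S[p]*4 + S[q]


@njit(cache=True)
def _code(seq, p, q):
    return seq[p] * 4 + seq[q]


@njit(cache=True)
def intra_mfe(seq, n, canon16, stack16, la, lb, mlc, mlb):
    """Minimum free energy over the intra-molecular ensemble (kcal/mol).

    Same recursion structure as the partition function, min-sum semiring.
    Used only to choose the rescaling base.
    """
    INF = 1e30
    Eb = np.full((n + 2, n + 2), INF)
    Em = np.full((n + 2, n + 2), INF)   # >=1 multiloop branch in i..j
    Em2 = np.full((n + 2, n + 2), INF)  # >=2 branches
    for L in range(1, n + 1):
        for i in range(1, n - L + 2):
            j = i + L - 1
            # Eb
            if L >= MIN_HAIRPIN + 2 and canon16[_code(seq, i, j)]:
                best = la + lb * (j - i - 1)  # hairpin
                pmax = min(i + 1 + MAX_INTLOOP, j - MIN_HAIRPIN - 1)
                for pp in range(i + 1, pmax + 1):
                    u1 = pp - i - 1
                    for qq in range(j - 1, pp + MIN_HAIRPIN, -1):
                        u2 = j - qq - 1
                        if u1 + u2 > MAX_INTLOOP:
                            break
                        z = Eb[pp, qq]
                        if z < INF:
                            if u1 == 0 and u2 == 0:
                                cand = stack16[_code(seq, i, j), _code(seq, pp, qq)] + z
                            else:
                                cand = la + lb * (u1 + u2) + z
                            if cand < best:
                                best = cand
                v = mlc + Em2[i + 1, j - 1]
                if v < best:
                    best = v
                Eb[i, j] = best
            # Em / Em2
            bm = Em[i + 1, j] if L > 1 else INF
            bm2 = Em2[i + 1, j] if L > 1 else INF
            for e in range(i + MIN_HAIRPIN + 1, j + 1):
                be = Eb[i, e]
                if be < INF:
                    one = be + mlb
                    if one < bm:
                        bm = one
                    rest = Em[e + 1, j] if e + 1 <= j else INF
                    if rest < INF:
                        if one + rest < bm:
                            bm = one + rest
                        if one + rest < bm2:
                            bm2 = one + rest
            Em[i, j] = bm
            Em2[i, j] = bm2
    F = np.zeros(n + 1)
    for j in range(1, n + 1):
        best = F[j - 1]
        for k in range(1, j - MIN_HAIRPIN):
            if Eb[k, j] < INF:
                cand = F[k - 1] + Eb[k, j]
                if cand < best:
                    best = cand
        F[j] = best
    return F[n]


@njit(cache=True)
def inside(seq, n, canon16, wstack, la, lb, wml_close, wml_branch, beta, spow,
           forbid_lo, forbid_hi):
    """Scaled inside partition functions.

    Returns (Zb, Qm, Qm2, Qpre, Qsuf).  Positions in [forbid_lo, forbid_hi]
    (1-based, inclusive; pass 0,0 for none) are forced unpaired, which gives
    the restricted partition function used by the cross-check backend.
    Every array entry covering bases i..j carries a factor s**-(j-i+1).
    """
    Zb = np.zeros((n + 2, n + 2))
    Qm = np.zeros((n + 2, n + 2))
    Qm2 = np.zeros((n + 2, n + 2))
    for L in range(1, n + 1):
        for i in range(1, n - L + 2):
            j = i + L - 1
            # --- Zb[i,j]
            if (L >= MIN_HAIRPIN + 2
                    and canon16[_code(seq, i, j)]
                    and not (forbid_lo <= i <= forbid_hi)
                    and not (forbid_lo <= j <= forbid_hi)):
                acc = np.exp(-beta * (la + lb * (j - i - 1))) * spow[L]
                pmax = min(i + 1 + MAX_INTLOOP, j - MIN_HAIRPIN - 1)
                for pp in range(i + 1, pmax + 1):
                    u1 = pp - i - 1
                    for qq in range(j - 1, pp + MIN_HAIRPIN, -1):
                        u2 = j - qq - 1
                        if u1 + u2 > MAX_INTLOOP:
                            break
                        z = Zb[pp, qq]
                        if z > 0.0:
                            if u1 == 0 and u2 == 0:
                                acc += (wstack[_code(seq, i, j), _code(seq, pp, qq)]
                                        * spow[2] * z)
                            else:
                                acc += (np.exp(-beta * (la + lb * (u1 + u2)))
                                        * spow[u1 + u2 + 2] * z)
                acc += wml_close * spow[2] * Qm2[i + 1, j - 1]
                Zb[i, j] = acc
            # --- Qm / Qm2
            qm = Qm[i + 1, j] * spow[1] if L > 1 else 0.0
            qm2 = Qm2[i + 1, j] * spow[1] if L > 1 else 0.0
            for e in range(i + MIN_HAIRPIN + 1, j + 1):
                z = Zb[i, e]
                if z > 0.0:
                    rest = Qm[e + 1, j] if e + 1 <= j else 0.0
                    qm += z * wml_branch * (spow[j - e] + rest)
                    qm2 += z * wml_branch * rest
            Qm[i, j] = qm
            Qm2[i, j] = qm2
    Qpre = np.zeros(n + 2)
    Qpre[0] = 1.0
    for j in range(1, n + 1):
        acc = Qpre[j - 1] * spow[1]
        for k in range(1, j - MIN_HAIRPIN):
            if Zb[k, j] > 0.0:
                acc += Qpre[k - 1] * Zb[k, j]
        Qpre[j] = acc
    Qsuf = np.zeros(n + 2)
    Qsuf[n + 1] = 1.0
    for i in range(n, 0, -1):
        acc = Qsuf[i + 1] * spow[1]
        for e in range(i + MIN_HAIRPIN + 1, n + 1):
            if Zb[i, e] > 0.0:
                acc += Zb[i, e] * Qsuf[e + 1]
        Qsuf[i] = acc
    return Zb, Qm, Qm2, Qpre, Qsuf


@njit(cache=True)
def outside(seq, n, wstack, la, lb, wml_close, wml_branch, beta, spow,
            Zb, Qm, Qpre, Qsuf):
    """Scaled outside weights Zhat[p,q]: the partition function over
    everything *outside* pair (p,q), so that the pair probability is
    Pb(p,q) = Zhat[p,q] * Zb[p,q] / Z.  Zhat covers n - (q-p+1) bases."""
    Zhat = np.zeros((n + 2, n + 2))
    M1 = np.zeros(n + 2)
    M2 = np.zeros(n + 2)
    wml = wml_close * wml_branch
    for p in range(1, n + 1):
        # helpers over enclosing left ends P < p, for all right ends Q
        for Q in range(p + 1, n + 1):
            m1 = 0.0
            m2 = 0.0
            for P in range(1, p):
                zh = Zhat[P, Q]
                if zh > 0.0:
                    m1 += zh * Qm[P + 1, p - 1]
                    m2 += zh * spow[p - P - 1]
            M1[Q] = m1
            M2[Q] = m2
        for q in range(p + MIN_HAIRPIN + 1, n + 1):
            if Zb[p, q] <= 0.0:
                continue
            acc = Qpre[p - 1] * Qsuf[q + 1]
            # (p,q) inner helix of an interior loop / stack closed by (P,Q)
            for P in range(max(1, p - 1 - MAX_INTLOOP), p):
                u1 = p - P - 1
                qmax = min(n, q + 1 + (MAX_INTLOOP - u1))
                for Q in range(q + 1, qmax + 1):
                    u2 = Q - q - 1
                    zh = Zhat[P, Q]
                    if zh > 0.0:
                        if u1 == 0 and u2 == 0:
                            acc += (wstack[_code(seq, P, Q), _code(seq, p, q)]
                                    * spow[2] * zh)
                        else:
                            acc += (np.exp(-beta * (la + lb * (u1 + u2)))
                                    * spow[u1 + u2 + 2] * zh)
            # (p,q) a branch of a multiloop closed by (P,Q)
            ml = 0.0
            for Q in range(q + 1, n + 1):
                m1 = M1[Q]
                m2 = M2[Q]
                if m1 > 0.0 or m2 > 0.0:
                    qmr = Qm[q + 1, Q - 1] if q + 1 <= Q - 1 else 0.0
                    ml += m1 * (spow[Q - q - 1] + qmr) + m2 * qmr
            acc += ml * wml * spow[2]
            Zhat[p, q] = acc
    return Zhat


@njit(cache=True)
def pu_regions(seq, n, la, lb, wml_close, beta, spow, maxlen,
               Zb, Qm, Qm2, Qpre, Qsuf, Zhat):
    """Exact unpaired probabilities Pu(i..j) for all regions with
    j-i+1 <= maxlen, via decomposition over the innermost pair (p,q)
    enclosing the region (or none: exterior loop)."""
    Ztot = Qpre[n]
    # hairpin case: 2-D cumulative of Zhat * hairpin weight
    SG = np.zeros((n + 2, n + 2))
    tmp = np.zeros((n + 2, n + 2))
    for p in range(1, n + 1):
        for j in range(n - 1, 0, -1):
            v = tmp[p, j + 1]
            q = j + 1
            if Zhat[p, q] > 0.0:
                v += (Zhat[p, q]
                      * np.exp(-beta * (la + lb * (q - p - 1))) * spow[q - p + 1])
            tmp[p, j] = v
    for j in range(1, n + 1):
        for i in range(2, n + 1):
            SG[i, j] = SG[i - 1, j] + tmp[i - 1, j]
    # multiloop helpers
    A1 = np.zeros((n + 2, n + 2))  # sum_{q>j} Zhat[p,q] * s^-(q-j-1)
    for p in range(1, n + 1):
        for j in range(n - 1, p - 1, -1):
            A1[p, j] = A1[p, j + 1] * spow[1] + Zhat[p, j + 1]
    B1 = np.zeros((n + 2, n + 2))  # sum_{p<i} Zhat[p,q] * s^-(i-p-1)
    for q in range(1, n + 1):
        for i in range(2, q + 1):
            B1[i, q] = B1[i - 1, q] * spow[1] + Zhat[i - 1, q]
    U = np.zeros((n + 2, n + 2))   # sum_{p<i} Zhat[p,q] * Qm[p+1, i-1]
    for i in range(2, n + 1):
        for q in range(i, n + 1):
            acc = 0.0
            for p in range(1, i - 1):
                zh = Zhat[p, q]
                if zh > 0.0:
                    acc += zh * Qm[p + 1, i - 1]
            U[i, q] = acc
    # interior-loop cases: region inside the left / right gap of the loop
    Er = np.zeros((n + 2, n + 2))  # Er[p, pp], inner helix right of region
    for p in range(1, n + 1):
        for pp in range(p + 2, min(p + 1 + MAX_INTLOOP, n) + 1):
            u1 = pp - p - 1
            acc = 0.0
            for qq in range(pp + MIN_HAIRPIN + 1, n + 1):
                z = Zb[pp, qq]
                if z > 0.0:
                    inner = 0.0
                    for u2 in range(0, MAX_INTLOOP - u1 + 1):
                        q = qq + 1 + u2
                        if q > n:
                            break
                        zh = Zhat[p, q]
                        if zh > 0.0:
                            inner += (zh * np.exp(-beta * (la + lb * (u1 + u2)))
                                      * spow[u1 + u2 + 2])
                    acc += z * inner
            Er[p, pp] = acc
    Cr = np.zeros((n + 2, n + 2))  # Cr[p, j] = sum_{pp > j} Er[p, pp]
    for p in range(1, n + 1):
        for j in range(n - 1, p, -1):
            Cr[p, j] = Cr[p, j + 1] + Er[p, j + 1]
    Dr = np.zeros((n + 2, n + 2))  # Dr[i, j] = sum_{p < i} Cr[p, j]
    for j in range(1, n + 1):
        for i in range(2, j + 1):
            Dr[i, j] = Dr[i - 1, j] + Cr[i - 1, j]
    El = np.zeros((n + 2, n + 2))  # El[q, qq], inner helix left of region
    for q in range(1, n + 1):
        for qq in range(max(1, q - 1 - MAX_INTLOOP), q - 1):
            u2 = q - qq - 1
            acc = 0.0
            for pp in range(1, qq - MIN_HAIRPIN):
                z = Zb[pp, qq]
                if z > 0.0:
                    inner = 0.0
                    for u1 in range(0, MAX_INTLOOP - u2 + 1):
                        p = pp - 1 - u1
                        if p < 1:
                            break
                        zh = Zhat[p, q]
                        if zh > 0.0:
                            inner += (zh * np.exp(-beta * (la + lb * (u1 + u2)))
                                      * spow[u1 + u2 + 2])
                    acc += z * inner
            El[q, qq] = acc
    Cl = np.zeros((n + 2, n + 2))  # Cl[q, i] = sum_{qq < i} El[q, qq]
    for q in range(1, n + 1):
        for i in range(2, q + 1):
            Cl[q, i] = Cl[q, i - 1] + El[q, i - 1]
    Dl = np.zeros((n + 2, n + 2))  # Dl[i, j] = sum_{q > j} Cl[q, i]
    for i in range(1, n + 1):
        for j in range(n - 1, i - 1, -1):
            Dl[i, j] = Dl[i, j + 1] + Cl[j + 1, i]
    # assemble per region
    pu = np.full((n + 1, maxlen + 1), np.nan)
    for i in range(1, n + 1):
        for w in range(1, min(maxlen, n - i + 1) + 1):
            j = i + w - 1
            num = Qpre[i - 1] * spow[w] * Qsuf[j + 1]
            num += SG[i, j] + Dr[i, j] + Dl[i, j]
            t1 = 0.0
            for p in range(1, i - 1):
                qm2l = Qm2[p + 1, i - 1]
                if qm2l > 0.0:
                    t1 += qm2l * A1[p, j]
            t2 = 0.0
            t3 = 0.0
            for q in range(j + 2, n + 1):
                qmr = Qm[j + 1, q - 1]
                qm2r = Qm2[j + 1, q - 1]
                if qmr > 0.0:
                    t2 += qmr * U[i, q]
                if qm2r > 0.0:
                    t3 += qm2r * B1[i, q]
            num += wml_close * spow[2] * spow[w] * (t1 + t2 + t3)
            v = num / Ztot
            if v < 0.0:
                v = 0.0
            elif v > 1.0:
                v = 1.0
            pu[i, w] = v
    return pu


@njit(cache=True)
def pair_probabilities(n, Zb, Zhat, Ztot):
    Pb = np.zeros((n + 2, n + 2))
    for p in range(1, n + 1):
        for q in range(p + 1, n + 1):
            if Zb[p, q] > 0.0 and Zhat[p, q] > 0.0:
                Pb[p, q] = Zb[p, q] * Zhat[p, q] / Ztot
    return Pb
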