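"""Numba kernels for constrained minimum-free-energy interaction prediction.

Conventions: sequences are 1-based int8 code arrays with padding; an
interaction's pairs ascend on RNA1 and descend on RNA2 (antiparallel).  A
pair is addressed by its two positions (i, k); ``code = s1[i]*4 + s2[k]``
indexes the canonical-pair/stacking/terminal tables.

The seeded predictor anchors on every enumerated seed (left pair (a,b),
right pair (c,d)), computes windowed left/right extension DPs for the
hybrid core (stacks + linear-cost loops), and minimizes the total energy

    E = init + core + terminal(left) + terminal(right) + ED1(i1..j) + ED2(l..k1)

over all boundary quadruples via min-plus products against the banded ED
lookup tables (which already encode the interaction-length and minimum-
accessibility constraints as +inf entries).
"""

from __future__ import annotations

import numpy as np
from numba import njit

INF = 1e30
_EPS = 1e-9


@njit(cache=True, inline="always")
def _pc(s1c, s2c, i, k):
    return s1c[i] * 4 + s2c[k]


@njit(cache=True)
def find_seeds(s1c, n1, s2c, n2, canon16, gu16, stackE, termE, init,
               bp, allow_gu, max_e_hybrid, max_e, min_pu,
               ed1_seed, ed2_seed, pu1_seed, pu2_seed):
    """Enumerate canonical seeds: (a, b) anchors every seed with pairs
    (a+t, b-t), t = 0..bp-1, passing all configured seed filters.

    Returns (a, b, core, eh, etot) arrays ordered by ascending a, then
    ascending region-2 start (b-bp+1).  ``core`` is the plain stacking sum
    used by the extension DP; ``eh`` the standalone seed hybridization
    energy (init + stacks + terminal penalties); ``etot`` adds both seed-
    region ED penalties.
    """
    cap = (n1 - bp + 1) * (n2 - bp + 1)
    if cap <= 0:
        return (np.empty(0, np.int64), np.empty(0, np.int64),
                np.empty(0, np.float64), np.empty(0, np.float64),
                np.empty(0, np.float64))
    aa = np.empty(cap, np.int64)
    bb = np.empty(cap, np.int64)
    cc = np.empty(cap, np.float64)
    eh_arr = np.empty(cap, np.float64)
    et_arr = np.empty(cap, np.float64)
    m = 0
    for a in range(1, n1 - bp + 2):
        for b in range(bp, n2 + 1):
            ok = True
            core = 0.0
            for t in range(bp):
                c12 = _pc(s1c, s2c, a + t, b - t)
                if not canon16[c12]:
                    ok = False
                    break
                if not allow_gu and gu16[c12]:
                    ok = False
                    break
                if t > 0:
                    core += stackE[_pc(s1c, s2c, a + t - 1, b - t + 1), c12]
            if not ok:
                continue
            k2s = b - bp + 1  # region-2 start
            if min_pu >= 0.0 and (pu1_seed[a] < min_pu or pu2_seed[k2s] < min_pu):
                continue
            eh = (init + core + termE[_pc(s1c, s2c, a, b)]
                  + termE[_pc(s1c, s2c, a + bp - 1, k2s)])
            if eh > max_e_hybrid + _EPS:
                continue
            etot = eh + ed1_seed[a] + ed2_seed[k2s]
            if etot > max_e + _EPS:
                continue
            aa[m] = a
            bb[m] = b
            cc[m] = core
            eh_arr[m] = eh
            et_arr[m] = etot
            m += 1
    return aa[:m], bb[:m], cc[:m], eh_arr[:m], et_arr[:m]


@njit(cache=True)
def _window_left(s1c, s2c, canon16, stackE, la, lb, ML, a, b, ilo, khi, M, G):
    """Left-extension DP: M[i,k] = min core energy of a duplex path from
    pair (i,k) rightward to the anchor pair (a,b)."""
    for i in range(ilo, a + 1):
        for k in range(b, khi + 1):
            M[i, k] = INF
    M[a, b] = 0.0
    for i in range(a - 1, ilo - 1, -1):
        umax1 = min(ML, a - (i + 1))
        for k in range(b, khi + 1):
            g = INF
            for u1 in range(umax1 + 1):
                v = M[i + 1 + u1, k]
                if v < INF:
                    v += lb * u1
                    if v < g:
                        g = v
            G[k] = g
        for k in range(b + 1, khi + 1):
            c12 = _pc(s1c, s2c, i, k)
            if not canon16[c12]:
                M[i, k] = INF
                continue
            best = INF
            v = M[i + 1, k - 1]
            if v < INF:
                v += stackE[c12, _pc(s1c, s2c, i + 1, k - 1)]
                if v < best:
                    best = v
            lbest = INF
            umax2 = min(ML, k - 1 - b)
            for u2 in range(umax2 + 1):
                g = G[k - 1 - u2]
                if g < INF:
                    g += lb * u2
                    if g < lbest:
                        lbest = g
            if la + lbest < best:
                best = la + lbest
            M[i, k] = best


@njit(cache=True)
def _window_right(s1c, s2c, canon16, stackE, la, lb, ML, c, d, jhi, llo, M, G):
    """Right-extension DP: M[j,l] = min core energy of a duplex path from
    the anchor pair (c,d) rightward to pair (j,l)."""
    for j in range(c, jhi + 1):
        for l in range(llo, d + 1):
            M[j, l] = INF
    M[c, d] = 0.0
    for j in range(c + 1, jhi + 1):
        umax1 = min(ML, j - 1 - c)
        for l in range(llo, d + 1):
            g = INF
            for u1 in range(umax1 + 1):
                v = M[j - 1 - u1, l]
                if v < INF:
                    v += lb * u1
                    if v < g:
                        g = v
            G[l] = g
        for l in range(d - 1, llo - 1, -1):
            c12 = _pc(s1c, s2c, j, l)
            if not canon16[c12]:
                M[j, l] = INF
                continue
            best = INF
            v = M[j - 1, l + 1]
            if v < INF:
                v += stackE[_pc(s1c, s2c, j - 1, l + 1), c12]
                if v < best:
                    best = v
            lbest = INF
            umax2 = min(ML, d - (l + 1))
            for u2 in range(umax2 + 1):
                g = G[l + 1 + u2]
                if g < INF:
                    g += lb * u2
                    if g < lbest:
                        lbest = g
            if la + lbest < best:
                best = la + lbest
            M[j, l] = best


@njit(cache=True)
def _seed_bounds(a, b, bp, n1, n2, W1, W2):
    c = a + bp - 1
    d = b - bp + 1
    ilo = max(1, a + bp - W1)
    khi = min(n2, b - bp + W2)
    jhi = min(n1, a + W1 - 1)
    llo = max(1, b + 1 - W2)
    return c, d, ilo, khi, jhi, llo


@njit(cache=True)
def predict_seeded(s1c, n1, s2c, n2, canon16, stackE, termE, la, lb, init,
                   ED1, ED2, W1, W2, ML,
                   seeds_a, seeds_b, seeds_core, bp):
    """Per-seed optimal interaction energy.

    Returns an array bestE[s] = minimal E over all constraint-satisfying
    interactions whose pairs contain seed s as a sub-helix.
    """
    ns = seeds_a.shape[0]
    out = np.full(ns, INF)
    ML_ = np.full((n1 + 2, n2 + 2), INF)
    MR_ = np.full((n1 + 2, n2 + 2), INF)
    G1 = np.full(n2 + 2, INF)
    G2 = np.full(n2 + 2, INF)
    P = np.full((n2 + 2, n1 + 2), INF)
    for s in range(ns):
        a = seeds_a[s]
        b = seeds_b[s]
        c, d, ilo, khi, jhi, llo = _seed_bounds(a, b, bp, n1, n2, W1, W2)
        _window_left(s1c, s2c, canon16, stackE, la, lb, ML, a, b, ilo, khi,
                     ML_, G1)
        _window_right(s1c, s2c, canon16, stackE, la, lb, ML, c, d, jhi, llo,
                      MR_, G2)
        # P[k1, j] = min_{i1} (A[i1,k1] + ED1[i1,j])
        for k1 in range(b, khi + 1):
            for j in range(c, jhi + 1):
                P[k1, j] = INF
            for i1 in range(ilo, a + 1):
                av = ML_[i1, k1]
                if av >= INF:
                    continue
                av += termE[_pc(s1c, s2c, i1, k1)]
                for j in range(c, jhi + 1):
                    e1 = ED1[i1, j]
                    if e1 < INF:
                        v = av + e1
                        if v < P[k1, j]:
                            P[k1, j] = v
        best = INF
        for j in range(c, jhi + 1):
            for l in range(llo, d + 1):
                bv = MR_[j, l]
                if bv >= INF:
                    continue
                bv += termE[_pc(s1c, s2c, j, l)]
                q = INF
                for k1 in range(b, khi + 1):
                    p = P[k1, j]
                    if p < INF:
                        e2 = ED2[l, k1]
                        if e2 < INF:
                            v = p + e2
                            if v < q:
                                q = v
                if q + bv < best:
                    best = q + bv
        if best < INF:
            out[s] = best + init + seeds_core[s]
    return out


@njit(cache=True)
def recover_seeded(s1c, n1, s2c, n2, canon16, stackE, termE, la, lb, init,
                   ED1, ED2, W1, W2, ML, a, b, core, bp, target):
    """Boundary quadruple (i1, l, j, k1) of the minimal interaction through
    seed (a,b), chosen by the deterministic tie-break: smallest region-1
    start, then region-2 start, then region-1 length, then region-2
    length.  ``target`` is the known optimal E for this seed."""
    c, d, ilo, khi, jhi, llo = _seed_bounds(a, b, bp, n1, n2, W1, W2)
    ML_ = np.full((n1 + 2, n2 + 2), INF)
    MR_ = np.full((n1 + 2, n2 + 2), INF)
    G = np.full(n2 + 2, INF)
    _window_left(s1c, s2c, canon16, stackE, la, lb, ML, a, b, ilo, khi, ML_, G)
    _window_right(s1c, s2c, canon16, stackE, la, lb, ML, c, d, jhi, llo, MR_, G)
    base = init + core
    for i1 in range(ilo, a + 1):
        # cheap row lower bound
        arow = INF
        for k1 in range(b, khi + 1):
            v = ML_[i1, k1]
            if v < arow:
                arow = v
        if arow >= INF:
            continue
        for l in range(llo, d + 1):
            for j in range(c, jhi + 1):
                e1 = ED1[i1, j]
                if e1 >= INF:
                    continue
                bv = MR_[j, l]
                if bv >= INF:
                    continue
                bv += termE[_pc(s1c, s2c, j, l)]
                for k1 in range(b, khi + 1):
                    av = ML_[i1, k1]
                    if av >= INF:
                        continue
                    e2 = ED2[l, k1]
                    if e2 >= INF:
                        continue
                    tot = (base + av + termE[_pc(s1c, s2c, i1, k1)]
                           + e1 + e2 + bv)
                    if tot <= target + _EPS:
                        return i1, l, j, k1
    return -1, -1, -1, -1


@njit(cache=True)
def traceback_seeded(s1c, n1, s2c, n2, canon16, stackE, la, lb, ML,
                     a, b, bp, W1, W2, i1, k1, j, l):
    """Pair list of the optimal interaction with boundaries
    (i1..j, l..k1) through seed (a,b); re-derives the extension paths from
    the window DPs (stack step preferred, then smallest loop)."""
    c, d, ilo, khi, jhi, llo = _seed_bounds(a, b, bp, n1, n2, W1, W2)
    ML_ = np.full((n1 + 2, n2 + 2), INF)
    MR_ = np.full((n1 + 2, n2 + 2), INF)
    G = np.full(n2 + 2, INF)
    _window_left(s1c, s2c, canon16, stackE, la, lb, ML, a, b, ilo, khi, ML_, G)
    _window_right(s1c, s2c, canon16, stackE, la, lb, ML, c, d, jhi, llo, MR_, G)
    pi = np.empty(n1 + n2 + 2, np.int64)
    pk = np.empty(n1 + n2 + 2, np.int64)
    m = 0
    # left path: (i1,k1) -> (a,b)
    ci, ck = i1, k1
    while True:
        pi[m] = ci
        pk[m] = ck
        m += 1
        if ci == a and ck == b:
            break
        cur = ML_[ci, ck]
        nxt_i, nxt_k = -1, -1
        v = ML_[ci + 1, ck - 1]
        if v < INF and abs(cur - (v + stackE[_pc(s1c, s2c, ci, ck),
                                            _pc(s1c, s2c, ci + 1, ck - 1)])) <= _EPS:
            nxt_i, nxt_k = ci + 1, ck - 1
        else:
            done = False
            for u1 in range(0, min(ML, a - ci - 1) + 1):
                if done:
                    break
                for u2 in range(0, min(ML, ck - 1 - b) + 1):
                    if u1 == 0 and u2 == 0:
                        continue
                    v = ML_[ci + 1 + u1, ck - 1 - u2]
                    if v < INF and abs(cur - (v + la + lb * (u1 + u2))) <= _EPS:
                        nxt_i, nxt_k = ci + 1 + u1, ck - 1 - u2
                        done = True
                        break
            if not done:
                # (0,0)-loop fallback (degenerate ties)
                v = ML_[ci + 1, ck - 1]
                if v < INF and abs(cur - (v + la)) <= _EPS:
                    nxt_i, nxt_k = ci + 1, ck - 1
        if nxt_i < 0:
            return pi[:0], pk[:0]
        ci, ck = nxt_i, nxt_k
    # seed interior pairs
    for t in range(1, bp):
        pi[m] = a + t
        pk[m] = b - t
        m += 1
    # right path: (c,d) -> (j,l), walked backwards from (j,l)
    ri = np.empty(n1 + n2 + 2, np.int64)
    rk = np.empty(n1 + n2 + 2, np.int64)
    rm = 0
    cj, cl = j, l
    while not (cj == c and cl == d):
        ri[rm] = cj
        rk[rm] = cl
        rm += 1
        cur = MR_[cj, cl]
        nxt_j, nxt_l = -1, -1
        v = MR_[cj - 1, cl + 1]
        if v < INF and abs(cur - (v + stackE[_pc(s1c, s2c, cj - 1, cl + 1),
                                            _pc(s1c, s2c, cj, cl)])) <= _EPS:
            nxt_j, nxt_l = cj - 1, cl + 1
        else:
            done = False
            for u1 in range(0, min(ML, cj - 1 - c) + 1):
                if done:
                    break
                for u2 in range(0, min(ML, d - cl - 1) + 1):
                    if u1 == 0 and u2 == 0:
                        continue
                    v = MR_[cj - 1 - u1, cl + 1 + u2]
                    if v < INF and abs(cur - (v + la + lb * (u1 + u2))) <= _EPS:
                        nxt_j, nxt_l = cj - 1 - u1, cl + 1 + u2
                        done = True
                        break
            if not done:
                v = MR_[cj - 1, cl + 1]
                if v < INF and abs(cur - (v + la)) <= _EPS:
                    nxt_j, nxt_l = cj - 1, cl + 1
        if nxt_j < 0:
            return pi[:0], pk[:0]
        cj, cl = nxt_j, nxt_l
    for t in range(rm - 1, -1, -1):
        pi[m] = ri[t]
        pk[m] = rk[t]
        m += 1
    return pi[:m], pk[:m]


@njit(cache=True)
def predict_unseeded(s1c, n1, s2c, n2, canon16, stackE, termE, la, lb, init,
                     ED1, ED2, W1, W2, ML):
    """Exact minimum over all interactions without a seed requirement.

    Anchors on every canonical left-end pair and runs the windowed forward
    DP; intended for oracle-scale inputs (cost grows with n1*n2 window
    DPs).  Returns (E, i1, l, j, k1); E >= INF when nothing qualifies."""
    M = np.full((n1 + 2, n2 + 2), INF)
    G = np.full(n2 + 2, INF)
    bE = INF
    bi1 = bl = bj = bk1 = -1
    for i1 in range(1, n1 + 1):
        for k1 in range(1, n2 + 1):
            if not canon16[_pc(s1c, s2c, i1, k1)]:
                continue
            jhi = min(n1, i1 + W1 - 1)
            llo = max(1, k1 - W2 + 1)
            _window_right(s1c, s2c, canon16, stackE, la, lb, ML,
                          i1, k1, jhi, llo, M, G)
            t_l = termE[_pc(s1c, s2c, i1, k1)]
            for j in range(i1, jhi + 1):
                e1 = ED1[i1, j]
                if e1 >= INF:
                    continue
                for l in range(llo, k1 + 1):
                    m = M[j, l]
                    if m >= INF:
                        continue
                    e2 = ED2[l, k1]
                    if e2 >= INF:
                        continue
                    E = init + t_l + m + termE[_pc(s1c, s2c, j, l)] + e1 + e2
                    if E < bE - _EPS:
                        bE, bi1, bl, bj, bk1 = E, i1, l, j, k1
                    elif E <= bE + _EPS:
                        # deterministic tie-break
                        t_new = (i1, l, j - i1 + 1, k1 - l + 1)
                        t_old = (bi1, bl, bj - bi1 + 1, bk1 - bl + 1)
                        if t_new < t_old:
                            bE, bi1, bl, bj, bk1 = min(E, bE), i1, l, j, k1
    return bE, bi1, bl, bj, bk1


@njit(cache=True)
def traceback_unseeded(s1c, n1, s2c, n2, canon16, stackE, la, lb, ML,
                       W1, W2, i1, k1, j, l):
    M = np.full((n1 + 2, n2 + 2), INF)
    G = np.full(n2 + 2, INF)
    jhi = min(n1, i1 + W1 - 1)
    llo = max(1, k1 - W2 + 1)
    _window_right(s1c, s2c, canon16, stackE, la, lb, ML, i1, k1, jhi, llo, M, G)
    ri = np.empty(n1 + n2 + 2, np.int64)
    rk = np.empty(n1 + n2 + 2, np.int64)
    rm = 0
    cj, cl = j, l
    while not (cj == i1 and cl == k1):
        ri[rm] = cj
        rk[rm] = cl
        rm += 1
        cur = M[cj, cl]
        nxt_j, nxt_l = -1, -1
        v = M[cj - 1, cl + 1]
        if v < INF and abs(cur - (v + stackE[_pc(s1c, s2c, cj - 1, cl + 1),
                                            _pc(s1c, s2c, cj, cl)])) <= _EPS:
            nxt_j, nxt_l = cj - 1, cl + 1
        else:
            done = False
            for u1 in range(0, min(ML, cj - 1 - i1) + 1):
                if done:
                    break
                for u2 in range(0, min(ML, k1 - cl - 1) + 1):
                    if u1 == 0 and u2 == 0:
                        continue
                    v = M[cj - 1 - u1, cl + 1 + u2]
                    if v < INF and abs(cur - (v + la + lb * (u1 + u2))) <= _EPS:
                        nxt_j, nxt_l = cj - 1 - u1, cl + 1 + u2
                        done = True
                        break
            if not done:
                v = M[cj - 1, cl + 1]
                if v < INF and abs(cur - (v + la)) <= _EPS:
                    nxt_j, nxt_l = cj - 1, cl + 1
        if nxt_j < 0:
            return ri[:0], rk[:0]
        cj, cl = nxt_j, nxt_l
    out_i = np.empty(rm + 1, np.int64)
    out_k = np.empty(rm + 1, np.int64)
    out_i[0] = i1
    out_k[0] = k1
    for t in range(rm):
        out_i[t + 1] = ri[rm - 1 - t]
        out_k[t + 1] = rk[rm - 1 - t]
    return out_i, out_k
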