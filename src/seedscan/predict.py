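"""Constrained minimum-free-energy RNA-RNA interaction prediction.

An interaction between two RNAs is a non-crossing set of inter-molecular
base pairs (ascending on RNA1, descending on RNA2) scored by

    E = Eh + ED1(i..j) + ED2(k..l)

where Eh is the nearest-neighbor hybridization energy of the duplex and
ED1/ED2 are the accessibility penalties of the two interaction sites.
:func:`predict` returns the interaction minimizing E subject to the
configured constraints: a contained canonical seed helix (length seedBP,
optionally GU-free, energy- and accessibility-filtered), maximal
interaction length per RNA, maximal interior-loop/bulge size, a ceiling on
the overall energy, and minimal site accessibility.

The search anchors a two-step dynamic program on every enumerated seed
(windowed left/right extension DPs joined by min-plus products against the
accessibility tables); :func:`predict_bruteforce` re-solves the same
minimization by exhaustive enumeration and is the correctness oracle at
small sequence lengths.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from . import _hybrid_kernels as HK
from .accessibility import (
    PU_FLOOR,
    AccessibilityProfile,
    compute_unpaired_probabilities,
    ed_penalty,
)
from .energy import (
    BasePair,
    ENCODE,
    EnergyParameterSet,
    GU_PAIRS,
    NucleotideSequence,
    PAIR_CODE,
    PAIR_ORDER,
    load_parameters,
    pairs_from_positions,
)

_EPS = 1e-9

#: per-sequence length bound for the exhaustive oracle
BRUTEFORCE_BOUND = 15


@dataclass(frozen=True)
class SeedConstraintSet:
    """Constraints on the canonical seed helix an interaction must contain."""

    seed_required: bool = True
    seedBP: int = 7
    allowGU: bool = True
    seedMaxE: Optional[float] = None         # bound on Eh_seed + ED1 + ED2
    seedMaxEhybrid: Optional[float] = None   # bound on Eh_seed alone
    seedMinPu: Optional[float] = None        # both seed regions

    def __post_init__(self) -> None:
        if self.seed_required and self.seedBP < 2:
            raise ValueError("seedBP must be >= 2 when a seed is required")
        if self.seedMinPu is not None and not (0.0 <= self.seedMinPu <= 1.0):
            raise ValueError("seedMinPu must be in [0, 1]")


@dataclass(frozen=True)
class InteractionConstraintSet:
    """Constraints on the overall interaction."""

    intLenMax: int = 150
    intMaxE: float = 0.0
    intMinPu: Optional[float] = None
    maxLoop: int = 16

    def __post_init__(self) -> None:
        if self.maxLoop < 0:
            raise ValueError("maxLoop must be >= 0")
        if self.intMinPu is not None and not (0.0 <= self.intMinPu <= 1.0):
            raise ValueError("intMinPu must be in [0, 1]")


@dataclass(frozen=True)
class PredictionConfig:
    seed: SeedConstraintSet = field(default_factory=SeedConstraintSet)
    interaction: InteractionConstraintSet = field(
        default_factory=InteractionConstraintSet
    )
    params: EnergyParameterSet = field(
        default_factory=lambda: load_parameters("default")
    )
    accessibility_source: str = "computed"   # "computed" | "file"

    def __post_init__(self) -> None:
        if self.seed.seed_required and self.interaction.intLenMax < self.seed.seedBP:
            raise ValueError("intLenMax must be >= seedBP")


def preset(name: str) -> PredictionConfig:
    """Named parameter presets.

    ``default``: 7-bp canonical seeds, GU allowed, no energy/accessibility
    seed filters, interaction length <= 150, loops <= 16, overall energy
    <= 0 kcal/mol.  ``recommended``: 7-bp GU-free seeds with minimal seed
    unpaired probability 0.001, interaction length <= 60, loops <= 8, and
    minimal site unpaired probability 0.001.
    """
    if name == "default":
        return PredictionConfig(
            seed=SeedConstraintSet(),
            interaction=InteractionConstraintSet(),
        )
    if name == "recommended":
        return PredictionConfig(
            seed=SeedConstraintSet(allowGU=False, seedMinPu=0.001),
            interaction=InteractionConstraintSet(
                intLenMax=60, maxLoop=8, intMinPu=0.001
            ),
        )
    raise ValueError(f"unknown preset {name!r} (use 'default' or 'recommended')")


@dataclass(frozen=True)
class Seed:
    """A canonical seed helix: seedBP consecutively stacked pairs."""

    region1: tuple[int, int]
    region2: tuple[int, int]
    pairs: tuple[BasePair, ...]
    Eh_seed: float
    ED1_seed: float
    ED2_seed: float

    @property
    def E_seed(self) -> float:
        return self.Eh_seed + self.ED1_seed + self.ED2_seed


@dataclass(frozen=True)
class Interaction:
    """A predicted hybrid with its energy decomposition (1-based regions)."""

    id1: str
    id2: str
    region1: tuple[int, int]
    region2: tuple[int, int]
    pairs: tuple[BasePair, ...]
    Eh: float
    ED1: float
    ED2: float
    E: float
    seed: Optional[Seed] = None

    def hybrid_dp(self) -> str:
        """Dot-bracket encoding 'region1&region2', both written 5'->3';
        the t-th '(' pairs with the t-th ')' counted from the right."""
        i0, i1 = self.region1
        k0, k1 = self.region2
        left = ["."] * (i1 - i0 + 1)
        right = ["."] * (k1 - k0 + 1)
        for p in self.pairs:
            left[p.pos1 - i0] = "("
            right[p.pos2 - k0] = ")"
        return "".join(left) + "&" + "".join(right)


class PredictionError(ValueError):
    pass


# ---------------------------------------------------------------------------
# numeric tables

_TABLE_CACHE: dict[int, tuple] = {}


def _tables(params: EnergyParameterSet):
    key = id(params)
    if key not in _TABLE_CACHE:
        canon = np.zeros(16, dtype=np.uint8)
        gu = np.zeros(16, dtype=np.uint8)
        for x in range(4):
            for y in range(4):
                if PAIR_CODE[x, y] >= 0:
                    canon[x * 4 + y] = 1
        for lbl in GU_PAIRS:
            gu[ENCODE[lbl[0]] * 4 + ENCODE[lbl[1]]] = 1
        stackE = params.stack16()
        stackE = np.where(np.isfinite(stackE), stackE, HK.INF)
        termE = np.zeros(16)
        for t, lbl in enumerate(PAIR_ORDER):
            termE[ENCODE[lbl[0]] * 4 + ENCODE[lbl[1]]] = params.terminal(lbl)
        _TABLE_CACHE[key] = (canon, gu, stackE, termE)
    return _TABLE_CACHE[key]


def _codes1(seq: NucleotideSequence) -> np.ndarray:
    c = np.zeros(len(seq) + 2, dtype=np.int8)
    c[1:-1] = seq.codes
    return c


def _need_profile(
    seq: NucleotideSequence,
    prof: Optional[AccessibilityProfile],
    params: EnergyParameterSet,
    maxlen: int,
) -> AccessibilityProfile:
    if prof is None:
        return compute_unpaired_probabilities(seq, params, min(maxlen, len(seq)))
    if prof.length != len(seq):
        raise PredictionError(
            f"profile {prof.sequence_id!r} covers {prof.length} nt but "
            f"sequence {seq.id!r} has {len(seq)}"
        )
    if prof.max_region_len < min(maxlen, len(seq)):
        raise PredictionError(
            f"profile {prof.sequence_id!r} only covers regions up to "
            f"{prof.max_region_len} nt; {min(maxlen, len(seq))} required"
        )
    return prof


def _ed_table(
    prof: AccessibilityProfile, W: int, int_min_pu: Optional[float], rt: float
) -> np.ndarray:
    """Banded ED lookup, +inf where the region is too long or fails the
    minimum-accessibility bound."""
    n = prof.length
    ed = np.full((n + 2, n + 2), HK.INF)
    wmax = min(W, n)
    for L in range(1, wmax + 1):
        i = np.arange(1, n - L + 2)
        pu = prof.band[i - 1, L - 1]
        vals = -rt * np.log(np.clip(pu, PU_FLOOR, 1.0))
        if int_min_pu is not None:
            vals = np.where(pu >= int_min_pu, vals, HK.INF)
        ed[i, i + L - 1] = vals
    return ed


def _seed_vectors(
    prof: AccessibilityProfile, bp: int, rt: float
) -> tuple[np.ndarray, np.ndarray]:
    n = prof.length
    pu = np.zeros(n + 2)
    edv = np.full(n + 2, HK.INF)
    if bp <= n:
        i = np.arange(1, n - bp + 2)
        vals = prof.band[i - 1, bp - 1]
        pu[i] = vals
        edv[i] = -rt * np.log(np.clip(vals, PU_FLOOR, 1.0))
    return pu, edv


# ---------------------------------------------------------------------------
# seed enumeration

def _raw_seeds(
    s1: NucleotideSequence,
    s2: NucleotideSequence,
    prof1: AccessibilityProfile,
    prof2: AccessibilityProfile,
    sc: SeedConstraintSet,
    params: EnergyParameterSet,
):
    canon, gu, stackE, termE = _tables(params)
    bp = sc.seedBP
    pu1, ed1 = _seed_vectors(prof1, bp, params.rt)
    pu2, ed2 = _seed_vectors(prof2, bp, params.rt)
    return HK.find_seeds(
        _codes1(s1), len(s1), _codes1(s2), len(s2), canon, gu, stackE, termE,
        params.init, bp, sc.allowGU,
        HK.INF if sc.seedMaxEhybrid is None else sc.seedMaxEhybrid,
        HK.INF if sc.seedMaxE is None else sc.seedMaxE,
        -1.0 if sc.seedMinPu is None else sc.seedMinPu,
        ed1, ed2, pu1, pu2,
    )


def enumerate_seeds(
    s1: NucleotideSequence,
    s2: NucleotideSequence,
    prof1: AccessibilityProfile,
    prof2: AccessibilityProfile,
    sc: SeedConstraintSet,
    params: EnergyParameterSet,
) -> list[Seed]:
    """All seedBP-long perfectly stacked complementary helices passing the
    configured seed filters, ordered by ascending RNA1 start, then RNA2
    start."""
    aa, bb, core, eh, etot = _raw_seeds(s1, s2, prof1, prof2, sc, params)
    bp = sc.seedBP
    out = []
    order = np.lexsort((bb - bp + 1, aa))
    for t in order:
        a, b = int(aa[t]), int(bb[t])
        k2s = b - bp + 1
        pairs = tuple(
            pairs_from_positions(s1, s2, [(a + u, b - u) for u in range(bp)])
        )
        p1 = prof1.pu(a, a + bp - 1)
        p2 = prof2.pu(k2s, b)
        out.append(Seed(
            region1=(a, a + bp - 1),
            region2=(k2s, b),
            pairs=pairs,
            Eh_seed=float(eh[t]),
            ED1_seed=ed_penalty(p1, params.temperature),
            ED2_seed=ed_penalty(p2, params.temperature),
        ))
    return out


# ---------------------------------------------------------------------------
# prediction

def _build_interaction(
    s1, s2, cfg, prof1, prof2, pos_i, pos_k, seeds_ab=None
) -> Interaction:
    params = cfg.params
    positions = [(int(i), int(k)) for i, k in zip(pos_i, pos_k)]
    pairs = pairs_from_positions(s1, s2, positions)
    i1, j = positions[0][0], positions[-1][0]
    k1, l = positions[0][1], positions[-1][1]
    from .energy import hybridization_energy

    eh = hybridization_energy(params, pairs)
    ed1 = ed_penalty(prof1.pu(i1, j), params.temperature)
    ed2 = ed_penalty(prof2.pu(l, k1), params.temperature)
    seed_obj = None
    if cfg.seed.seed_required and seeds_ab is not None:
        bp = cfg.seed.seedBP
        pos_set = set(positions)
        best_key = None
        for (a, b) in seeds_ab:
            if all((a + u, b - u) in pos_set for u in range(bp)):
                key = (a, b - bp + 1)
                if best_key is None or key < best_key:
                    best_key = key
        if best_key is not None:
            a, k2s = best_key
            b = k2s + bp - 1
            spairs = tuple(pairs_from_positions(
                s1, s2, [(a + u, b - u) for u in range(bp)]
            ))
            seed_obj = Seed(
                region1=(a, a + bp - 1),
                region2=(k2s, b),
                pairs=spairs,
                Eh_seed=hybridization_energy(params, list(spairs)),
                ED1_seed=ed_penalty(prof1.pu(a, a + bp - 1), params.temperature),
                ED2_seed=ed_penalty(prof2.pu(k2s, b), params.temperature),
            )
    return Interaction(
        id1=s1.id, id2=s2.id,
        region1=(i1, j), region2=(l, k1),
        pairs=tuple(pairs),
        Eh=eh, ED1=ed1, ED2=ed2, E=eh + ed1 + ed2,
        seed=seed_obj,
    )


def predict(
    s1: NucleotideSequence,
    s2: NucleotideSequence,
    cfg: PredictionConfig,
    prof1: Optional[AccessibilityProfile] = None,
    prof2: Optional[AccessibilityProfile] = None,
) -> Optional[Interaction]:
    """The constraint-satisfying interaction of minimal overall energy E,
    or None when no interaction with E <= intMaxE satisfies every
    constraint.  Deterministic: ties resolve to the smallest RNA1 start,
    then RNA2 start, then shortest region 1, then region 2."""
    params = cfg.params
    ic = cfg.interaction
    n1, n2 = len(s1), len(s2)
    prof1 = _need_profile(s1, prof1, params, ic.intLenMax)
    prof2 = _need_profile(s2, prof2, params, ic.intLenMax)
    canon, gu, stackE, termE = _tables(params)
    W1 = min(ic.intLenMax, n1)
    W2 = min(ic.intLenMax, n2)
    ED1 = _ed_table(prof1, W1, ic.intMinPu, params.rt)
    ED2 = _ed_table(prof2, W2, ic.intMinPu, params.rt)
    s1c, s2c = _codes1(s1), _codes1(s2)

    if cfg.seed.seed_required:
        aa, bb, core, _eh, _et = _raw_seeds(s1, s2, prof1, prof2, cfg.seed, params)
        if aa.shape[0] == 0:
            return None
        bp = cfg.seed.seedBP
        bestE = HK.predict_seeded(
            s1c, n1, s2c, n2, canon, stackE, termE,
            params.loop_a, params.loop_b, params.init,
            ED1, ED2, W1, W2, ic.maxLoop, aa, bb, core, bp,
        )
        e_star = float(bestE.min())
        if e_star > ic.intMaxE + _EPS or e_star >= HK.INF / 2:
            return None
        best = None
        for t in np.flatnonzero(bestE <= e_star + _EPS):
            i1, l, j, k1 = HK.recover_seeded(
                s1c, n1, s2c, n2, canon, stackE, termE,
                params.loop_a, params.loop_b, params.init,
                ED1, ED2, W1, W2, ic.maxLoop,
                int(aa[t]), int(bb[t]), float(core[t]), bp, float(bestE[t]),
            )
            if i1 < 0:
                continue
            key = (i1, l, j - i1 + 1, k1 - l + 1)
            if best is None or key < best[0]:
                best = (key, t, (i1, l, j, k1))
        if best is None:
            return None
        _, t, (i1, l, j, k1) = best
        pos_i, pos_k = HK.traceback_seeded(
            s1c, n1, s2c, n2, canon, stackE,
            params.loop_a, params.loop_b, ic.maxLoop,
            int(aa[t]), int(bb[t]), bp, W1, W2, i1, k1, j, l,
        )
        if pos_i.shape[0] == 0:
            raise PredictionError("traceback failed to reproduce the optimum")
        return _build_interaction(
            s1, s2, cfg, prof1, prof2, pos_i, pos_k,
            seeds_ab=[(int(x), int(y)) for x, y in zip(aa, bb)],
        )

    e_star, i1, l, j, k1 = HK.predict_unseeded(
        s1c, n1, s2c, n2, canon, stackE, termE,
        params.loop_a, params.loop_b, params.init,
        ED1, ED2, W1, W2, ic.maxLoop,
    )
    if e_star > ic.intMaxE + _EPS or e_star >= HK.INF / 2:
        return None
    pos_i, pos_k = HK.traceback_unseeded(
        s1c, n1, s2c, n2, canon, stackE,
        params.loop_a, params.loop_b, ic.maxLoop, W1, W2, i1, k1, j, l,
    )
    if pos_i.shape[0] == 0:
        raise PredictionError("traceback failed to reproduce the optimum")
    return _build_interaction(s1, s2, cfg, prof1, prof2, pos_i, pos_k)


# ---------------------------------------------------------------------------
# exhaustive oracle

def predict_bruteforce(
    s1: NucleotideSequence,
    s2: NucleotideSequence,
    cfg: PredictionConfig,
    prof1: Optional[AccessibilityProfile] = None,
    prof2: Optional[AccessibilityProfile] = None,
) -> Optional[Interaction]:
    """Same contract as :func:`predict`, solved by exhaustive enumeration of
    every non-crossing inter-molecular pair set.  Only valid for sequences
    up to :data:`BRUTEFORCE_BOUND` nt each."""
    n1, n2 = len(s1), len(s2)
    if n1 > BRUTEFORCE_BOUND or n2 > BRUTEFORCE_BOUND:
        raise ValueError(
            f"inputs exceed the enumeration bound ({BRUTEFORCE_BOUND} nt)"
        )
    params = cfg.params
    sc, ic = cfg.seed, cfg.interaction
    prof1 = _need_profile(s1, prof1, params, n1)
    prof2 = _need_profile(s2, prof2, params, n2)
    c1 = s1.codes
    c2 = s2.codes
    pidx = [[int(PAIR_CODE[c1[i - 1], c2[k - 1]]) for k in range(n2 + 1)]
            if i else None for i in range(n1 + 1)]
    stack6 = params.stack
    term6 = params.terminal6()
    gu6 = [p in GU_PAIRS for p in PAIR_ORDER]
    rt = params.rt
    la, lb, init = params.loop_a, params.loop_b, params.init
    ML = ic.maxLoop
    W1 = min(ic.intLenMax, n1)
    W2 = min(ic.intLenMax, n2)

    def ed(p: float) -> float:
        return -rt * math.log(max(p, PU_FLOOR))

    def has_passing_seed(pairs: list[tuple[int, int]]) -> bool:
        if not sc.seed_required:
            return True
        bp = sc.seedBP
        for t in range(len(pairs) - bp + 1):
            ok = True
            for u in range(bp - 1):
                if (pairs[t + u + 1][0] != pairs[t + u][0] + 1
                        or pairs[t + u + 1][1] != pairs[t + u][1] - 1):
                    ok = False
                    break
            if not ok:
                continue
            win = pairs[t: t + bp]
            if not sc.allowGU and any(gu6[pidx[i][k]] for i, k in win):
                continue
            ehs = init + term6[pidx[win[0][0]][win[0][1]]] \
                + term6[pidx[win[-1][0]][win[-1][1]]]
            for u in range(bp - 1):
                ehs += stack6[pidx[win[u][0]][win[u][1]],
                              pidx[win[u + 1][0]][win[u + 1][1]]]
            if sc.seedMaxEhybrid is not None and ehs > sc.seedMaxEhybrid + _EPS:
                continue
            p1 = prof1.pu(win[0][0], win[0][0] + bp - 1)
            p2 = prof2.pu(win[-1][1], win[0][1])
            if sc.seedMinPu is not None and (p1 < sc.seedMinPu or p2 < sc.seedMinPu):
                continue
            if sc.seedMaxE is not None and ehs + ed(p1) + ed(p2) > sc.seedMaxE + _EPS:
                continue
            return True
        return False

    best: list = [None]  # (E, key, pairs)

    def evaluate(pairs: list[tuple[int, int]]) -> None:
        (i1, k1), (j, l) = pairs[0], pairs[-1]
        eh = init + term6[pidx[i1][k1]] + term6[pidx[j][l]]
        for (pa, ka), (pb, kb) in zip(pairs, pairs[1:]):
            u1, u2 = pb - pa - 1, ka - kb - 1
            if u1 == 0 and u2 == 0:
                eh += stack6[pidx[pa][ka], pidx[pb][kb]]
            else:
                eh += la + lb * (u1 + u2)
        p1 = prof1.pu(i1, j)
        p2 = prof2.pu(l, k1)
        if ic.intMinPu is not None and (p1 < ic.intMinPu or p2 < ic.intMinPu):
            return
        E = eh + ed(p1) + ed(p2)
        if E > ic.intMaxE + _EPS:
            return
        if not has_passing_seed(pairs):
            return
        key = (i1, l, j - i1 + 1, k1 - l + 1)
        cur = best[0]
        if cur is None or E < cur[0] - _EPS or (E <= cur[0] + _EPS and key < cur[1]):
            best[0] = (min(E, cur[0]) if cur else E, key, list(pairs))

    def extend(pairs: list[tuple[int, int]]) -> None:
        evaluate(pairs)
        i, k = pairs[-1]
        i1, k1 = pairs[0]
        for i2 in range(i + 1, min(n1, i + 1 + ML, i1 + W1 - 1) + 1):
            for k2 in range(max(1, k - 1 - ML, k1 - W2 + 1), k):
                if pidx[i2][k2] >= 0:
                    pairs.append((i2, k2))
                    extend(pairs)
                    pairs.pop()

    for i in range(1, n1 + 1):
        for k in range(1, n2 + 1):
            if pidx[i][k] >= 0:
                extend([(i, k)])

    if best[0] is None:
        return None
    _, _, pairs = best[0]
    seeds_ab = None
    if sc.seed_required:
        aa, bb, *_ = _raw_seeds(s1, s2, prof1, prof2, sc, params)
        seeds_ab = [(int(x), int(y)) for x, y in zip(aa, bb)]
    return _build_interaction(
        s1, s2, cfg, prof1, prof2,
        np.array([p[0] for p in pairs]), np.array([p[1] for p in pairs]),
        seeds_ab=seeds_ab,
    )
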