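"""Nearest-neighbor thermodynamic model for inter-molecular RNA duplexes.

The hybridization energy Eh of a duplex is scored with a compact
nearest-neighbor parameter set: a 36-entry stacking table over ordered dyads
of the six canonical base pairs (AU, UA, CG, GC, GU, UG), a linear
interior-loop/bulge cost ``a + b*(u1+u2)`` for ``u1+u2 >= 1`` unpaired bases
between consecutive pairs, a duplex initiation term, and a terminal penalty
per AU/GU helix end:

    Eh = init + sum(stacks) + sum(loop costs) + terminal(left) + terminal(right)

All energies are Gibbs free energies in kcal/mol at the parameter set's
temperature (default 310.15 K).  The shipped presets carry Turner-like
magnitudes (GC-rich stacks around -3 kcal/mol, AU around -1, wobble GU
around -0.5); the TSV parameter-file format accepts any complete table, so
published sets can be dropped in without code changes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np

# residue encoding used throughout the package
ALPHABET = "ACGU"
ENCODE = {c: i for i, c in enumerate(ALPHABET)}

#: the six canonical pairs in fixed order; index into stacking tables
PAIR_ORDER = ("AU", "UA", "CG", "GC", "GU", "UG")
_PAIR_INDEX = {p: i for i, p in enumerate(PAIR_ORDER)}

#: PAIR_CODE[x, y] = canonical-pair index of residues (x, y), or -1
PAIR_CODE = -np.ones((4, 4), dtype=np.int8)
for _p, _i in _PAIR_INDEX.items():
    PAIR_CODE[ENCODE[_p[0]], ENCODE[_p[1]]] = _i

GU_PAIRS = frozenset({"GU", "UG"})
# pairs that draw the terminal helix-end penalty (weak closing pairs)
WEAK_END_PAIRS = frozenset({"AU", "UA", "GU", "UG"})

#: gas constant in kcal/(mol*K)
R_GAS = 0.0019872


class EnergyParameterError(ValueError):
    """Malformed, incomplete, or inconsistent energy parameter input."""


@dataclass(frozen=True)
class BasePair:
    """One inter-molecular base pair: residue ``nt1`` on RNA1, ``nt2`` on RNA2.

    Positions are 1-based in their respective sequences.  RNA1 positions
    ascend 5'->3' along a duplex; the paired RNA2 positions descend
    (antiparallel orientation).
    """

    pos1: int
    pos2: int
    nt1: str
    nt2: str

    def __post_init__(self) -> None:
        if self.label not in _PAIR_INDEX:
            raise EnergyParameterError(
                f"non-canonical base pair {self.nt1}-{self.nt2} "
                f"at ({self.pos1},{self.pos2})"
            )

    @property
    def label(self) -> str:
        return self.nt1 + self.nt2

    @property
    def is_gu(self) -> bool:
        return self.label in GU_PAIRS


@dataclass(frozen=True)
class NucleotideSequence:
    """An RNA sequence over {A,C,G,U}; T on input is normalized to U."""

    id: str
    residues: str
    description: str = ""

    def __post_init__(self) -> None:
        norm = self.residues.upper().replace("T", "U")
        object.__setattr__(self, "residues", norm)
        if not norm:
            raise ValueError(f"sequence {self.id!r} is empty")
        bad = set(norm) - set(ALPHABET)
        if bad:
            raise ValueError(
                f"sequence {self.id!r} contains non-RNA residues: "
                f"{', '.join(sorted(bad))}"
            )

    def __len__(self) -> int:
        return len(self.residues)

    @property
    def codes(self) -> np.ndarray:
        """0-based integer encoding (A=0, C=1, G=2, U=3)."""
        return np.frombuffer(
            self.residues.encode().translate(_CODE_TABLE), dtype=np.uint8
        ).astype(np.int8)


_CODE_TABLE = bytes.maketrans(b"ACGU", bytes([0, 1, 2, 3]))


@dataclass(frozen=True)
class EnergyParameterSet:
    """A complete compact nearest-neighbor parameter set (kcal/mol).

    ``stack`` is a 6x6 matrix indexed by :data:`PAIR_ORDER` for the left and
    right pair of a stacked dyad read 5'->3' on strand 1.  ``loop_a`` and
    ``loop_b`` are the linear loop coefficients; ``init`` the duplex
    initiation; ``terminal_penalty`` is added once per AU/GU helix end.
    """

    name: str
    stack: np.ndarray  # (6, 6) float64
    loop_a: float
    loop_b: float
    init: float
    terminal_penalty: float
    temperature: float = 310.15
    # intra-molecular ensemble terms (accessibility); part of the same
    # self-consistent model, see docs/methods.md
    multiloop_close: float = 3.0
    multiloop_branch: float = 0.4

    def __post_init__(self) -> None:
        st = np.asarray(self.stack, dtype=float)
        if st.shape != (6, 6) or not np.all(np.isfinite(st)):
            raise EnergyParameterError(
                f"parameter set {self.name!r}: incomplete stacking table "
                "(all 36 dyad entries must be present and finite)"
            )
        object.__setattr__(self, "stack", st)
        if self.loop_b < 0:
            raise EnergyParameterError(
                "loop cost must be non-decreasing in loop size (b >= 0)"
            )
        if self.temperature <= 0:
            raise EnergyParameterError("temperature must be > 0 K")

    @property
    def rt(self) -> float:
        """R*T in kcal/mol."""
        return R_GAS * self.temperature

    def loop_cost(self, u1: int, u2: int) -> float:
        """Free-energy cost of an interior loop/bulge with ``u1``/``u2``
        unpaired bases on either strand (``u1 + u2 >= 1``)."""
        total = u1 + u2
        if u1 < 0 or u2 < 0 or total < 1:
            raise ValueError("loop requires u1, u2 >= 0 and u1 + u2 >= 1")
        return self.loop_a + self.loop_b * total

    def terminal(self, pair: BasePair | str) -> float:
        label = pair if isinstance(pair, str) else pair.label
        return self.terminal_penalty if label in WEAK_END_PAIRS else 0.0

    # numeric tables used by the DP kernels -------------------------------
    def stack16(self) -> np.ndarray:
        """Stacking table on the 16-state (x*4+y) residue-pair encoding,
        +inf for non-canonical dyad members."""
        out = np.full((16, 16), np.inf)
        for lp, li in _PAIR_INDEX.items():
            for rp, ri in _PAIR_INDEX.items():
                lcode = ENCODE[lp[0]] * 4 + ENCODE[lp[1]]
                rcode = ENCODE[rp[0]] * 4 + ENCODE[rp[1]]
                out[lcode, rcode] = self.stack[li, ri]
        return out

    def terminal6(self) -> np.ndarray:
        return np.array(
            [self.terminal(p) for p in PAIR_ORDER], dtype=float
        )


# ---------------------------------------------------------------------------
# parameter file I/O

_SECTIONS = ("meta", "init", "terminal", "loop", "stack")


def _preset_path(name: str) -> Path:
    return Path(str(resources.files("seedscan").joinpath(f"data/{name}.tsv")))


def available_presets() -> list[str]:
    data = resources.files("seedscan").joinpath("data")
    return sorted(p.name[:-4] for p in data.iterdir() if p.name.endswith(".tsv"))


def load_parameters(source: str | Path) -> EnergyParameterSet:
    """Load an :class:`EnergyParameterSet` from a shipped preset name or a
    parameter file in the documented TSV format.

    Missing stacking entries, unknown sections/keys, or out-of-range values
    are errors; nothing is silently defaulted.
    """
    path = Path(source)
    if not path.exists():
        candidate = _preset_path(str(source))
        if candidate.exists():
            path = candidate
        else:
            raise EnergyParameterError(
                f"unknown energy preset or missing file: {source!r} "
                f"(shipped presets: {', '.join(available_presets())})"
            )

    section = None
    meta: dict[str, str] = {}
    scalars: dict[str, float] = {}
    stack = np.full((6, 6), np.nan)
    seen_dyads: set[tuple[str, str]] = set()
    for lineno, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("[") and line.endswith("]"):
            section = line[1:-1]
            if section not in _SECTIONS:
                raise EnergyParameterError(
                    f"{path}:{lineno}: unknown section [{section}]"
                )
            continue
        fields = line.split("\t")
        if section is None:
            raise EnergyParameterError(f"{path}:{lineno}: data before any section")
        if section == "stack":
            if len(fields) != 3:
                raise EnergyParameterError(
                    f"{path}:{lineno}: [stack] rows are 'left<TAB>right<TAB>dG'"
                )
            left, right, val = fields
            if left not in _PAIR_INDEX or right not in _PAIR_INDEX:
                raise EnergyParameterError(
                    f"{path}:{lineno}: unknown pair in dyad {left}/{right}"
                )
            if (left, right) in seen_dyads:
                raise EnergyParameterError(
                    f"{path}:{lineno}: duplicate stack entry {left}/{right}"
                )
            seen_dyads.add((left, right))
            stack[_PAIR_INDEX[left], _PAIR_INDEX[right]] = float(val)
        elif section == "meta":
            if len(fields) != 2:
                raise EnergyParameterError(f"{path}:{lineno}: bad [meta] row")
            meta[fields[0]] = fields[1]
        else:
            if len(fields) != 2:
                raise EnergyParameterError(
                    f"{path}:{lineno}: [{section}] rows are 'key<TAB>value'"
                )
            scalars[f"{section}.{fields[0]}"] = float(fields[1])

    if len(seen_dyads) < 36:
        missing = 36 - len(seen_dyads)
        raise EnergyParameterError(
            f"{path}: incomplete stacking table ({missing} of 36 dyads missing)"
        )
    required = ("init.init", "terminal.end_penalty", "loop.a", "loop.b")
    for key in required:
        if key not in scalars:
            raise EnergyParameterError(f"{path}: missing required entry {key}")
    return EnergyParameterSet(
        name=meta.get("name", path.stem),
        stack=stack,
        loop_a=scalars["loop.a"],
        loop_b=scalars["loop.b"],
        init=scalars["init.init"],
        terminal_penalty=scalars["terminal.end_penalty"],
        temperature=float(meta.get("temperature", 310.15)),
        multiloop_close=scalars.get("loop.ml_close", 3.0),
        multiloop_branch=scalars.get("loop.ml_branch", 0.4),
    )


# ---------------------------------------------------------------------------
# scoring

def stacking_energy(
    params: EnergyParameterSet, left: BasePair | str, right: BasePair | str
) -> float:
    """Stacking free energy of the dyad (left pair, right pair), read 5'->3'
    along strand 1."""
    llabel = left if isinstance(left, str) else left.label
    rlabel = right if isinstance(right, str) else right.label
    for label in (llabel, rlabel):
        if label not in _PAIR_INDEX:
            raise EnergyParameterError(f"non-canonical pair {label!r}")
    return float(params.stack[_PAIR_INDEX[llabel], _PAIR_INDEX[rlabel]])


def hybridization_energy(
    params: EnergyParameterSet, pairs: list[BasePair]
) -> float:
    """Hybridization energy Eh of an ordered duplex pair list.

    Pairs must be strictly increasing in RNA1 position and strictly
    decreasing in RNA2 position (antiparallel, non-crossing).  Eh sums duplex
    initiation, stacking over directly adjacent dyads, loop costs over dyads
    separated by unpaired bases, and terminal penalties at both helix ends.
    """
    if not pairs:
        raise ValueError("empty pair list")
    e = params.init + params.terminal(pairs[0]) + params.terminal(pairs[-1])
    for left, right in zip(pairs, pairs[1:]):
        u1 = right.pos1 - left.pos1 - 1
        u2 = left.pos2 - right.pos2 - 1
        if u1 < 0 or u2 < 0:
            raise ValueError(
                "pairs must ascend on RNA1 and descend on RNA2 "
                f"(crossing at {left}, {right})"
            )
        if u1 == 0 and u2 == 0:
            e += stacking_energy(params, left, right)
        else:
            e += params.loop_cost(u1, u2)
    return e


def pairs_from_positions(
    s1: NucleotideSequence, s2: NucleotideSequence, positions: list[tuple[int, int]]
) -> list[BasePair]:
    """Build :class:`BasePair` objects from 1-based (pos1, pos2) tuples."""
    return [
        BasePair(i, k, s1.residues[i - 1], s2.residues[k - 1])
        for i, k in positions
    ]
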