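"""Region-wise unpaired probabilities Pu(i..j) and accessibility penalties.

The accessibility of a region is the Boltzmann probability that it is
completely free of intra-molecular base pairs in the equilibrium ensemble of
non-crossing secondary structures of its RNA, computed exactly with a
McCaskill-style inside/outside partition function over the same compact
energy model used for hybridization.  Accessibilities convert to energy
penalties

    ED = -R * T * ln(Pu)

that an interaction must pay to free its binding site.  Pu is clamped below
at :data:`PU_FLOOR` before the logarithm so ED stays finite.

Profiles are precomputed per sequence for all regions up to a maximum
length (normally the configured maximal interaction length) and can be
written to / read from a simple TSV format.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import _access_kernels as K
from .energy import (
    EnergyParameterSet,
    NucleotideSequence,
    PAIR_CODE,
    R_GAS,
)

#: lower clamp applied to Pu before taking the log in :func:`ed_penalty`
PU_FLOOR = 1e-10

#: absolute slack allowed when validating subsequence monotonicity
_MONO_TOL = 1e-9


class ProfileError(ValueError):
    """Malformed or inconsistent accessibility profile data."""


def _canon16() -> np.ndarray:
    canon = np.zeros(16, dtype=np.uint8)
    for x in range(4):
        for y in range(4):
            if PAIR_CODE[x, y] >= 0:
                canon[x * 4 + y] = 1
    return canon


@dataclass
class AccessibilityProfile:
    """Unpaired probabilities for one sequence, banded by region length.

    ``band[i-1, L-1]`` holds Pu(i..i+L-1) for 1 <= L <= max_region_len;
    entries beyond the sequence end are NaN.
    """

    sequence_id: str
    length: int
    max_region_len: int
    band: np.ndarray

    def __post_init__(self) -> None:
        band = np.asarray(self.band, dtype=float)
        if band.shape != (self.length, self.max_region_len):
            raise ProfileError(
                f"profile band for {self.sequence_id!r} has shape {band.shape}, "
                f"expected ({self.length}, {self.max_region_len})"
            )
        self.band = band

    def pu(self, i: int, j: int) -> float:
        """Pu(i..j), 1-based inclusive coordinates."""
        if not (1 <= i <= j <= self.length):
            raise IndexError(f"region {i}..{j} outside 1..{self.length}")
        L = j - i + 1
        if L > self.max_region_len:
            raise IndexError(
                f"region length {L} exceeds profile max {self.max_region_len}"
            )
        return float(self.band[i - 1, L - 1])

    def validate(self) -> None:
        """Check the probability range and subsequence monotonicity
        (Pu of a region never exceeds Pu of any of its subregions)."""
        n, w = self.length, self.max_region_len
        for i0 in range(n):
            lmax = min(w, n - i0)
            vals = self.band[i0, :lmax]
            if np.any(vals < -_MONO_TOL) or np.any(vals > 1.0 + _MONO_TOL):
                raise ProfileError(
                    f"{self.sequence_id}: Pu outside [0,1] near position {i0 + 1}"
                )
            # shrink right end: Pu(i..j) <= Pu(i..j-1)
            if np.any(np.diff(vals) > _MONO_TOL):
                raise ProfileError(
                    f"{self.sequence_id}: monotonicity violated at start {i0 + 1} "
                    "(region less accessible than one of its subregions is allowed; "
                    "the converse is not)"
                )
        # shrink left end: Pu(i..j) <= Pu(i+1..j)
        for L in range(2, w + 1):
            a = self.band[: n - L + 1, L - 1]
            b = self.band[1: n - L + 2, L - 2]
            if np.any(a - b > _MONO_TOL):
                raise ProfileError(
                    f"{self.sequence_id}: monotonicity violated for length {L}"
                )


def ed_penalty(pu: float, temperature: float = 310.15) -> float:
    """Accessibility penalty ED = -R*T*ln(Pu) in kcal/mol.

    ``pu`` is clamped below at :data:`PU_FLOOR`, keeping ED finite and
    energy comparisons total even for numerically unpaired-free regions.
    """
    if not (0.0 <= pu <= 1.0):
        raise ValueError(f"unpaired probability {pu} outside [0, 1]")
    return -R_GAS * temperature * math.log(max(pu, PU_FLOOR))


def _model_tables(params: EnergyParameterSet):
    canon = _canon16()
    beta = 1.0 / params.rt
    wstack = np.exp(-beta * np.where(np.isfinite(params.stack16()),
                                     params.stack16(), np.inf))
    wstack[~np.isfinite(params.stack16())] = 0.0
    return canon, beta, wstack


def _scale_powers(seq_codes1: np.ndarray, n: int, params: EnergyParameterSet,
                  canon: np.ndarray, beta: float) -> np.ndarray:
    """Per-length rescaling factors s**-t from the intra-molecular MFE."""
    mfe = K.intra_mfe(seq_codes1, n, canon, params.stack16(),
                      params.loop_a, params.loop_b,
                      params.multiloop_close, params.multiloop_branch)
    log_s = max(0.0, -beta * 1.05 * mfe / n) if n else 0.0
    log_s = min(log_s, 600.0 / max(n, 1))
    return np.exp(-log_s * np.arange(n + 2, dtype=float))


def _seq_codes1(seq: NucleotideSequence) -> np.ndarray:
    """1-based int8 codes with padding at 0 and n+1."""
    c = np.zeros(len(seq) + 2, dtype=np.int8)
    c[1:-1] = seq.codes
    return c


def compute_unpaired_probabilities(
    seq: NucleotideSequence,
    params: EnergyParameterSet,
    max_region_len: int,
) -> AccessibilityProfile:
    """Exact Pu(i..j) for every region up to ``max_region_len``.

    Uses the inside/outside partition-function algorithm: the probability
    that a region is unpaired decomposes over the innermost base pair
    enclosing it (exterior loop, hairpin, interior loop, or multiloop
    case).  Deterministic; O(n^3) time in the sequence length.
    """
    if max_region_len < 1:
        raise ValueError("max_region_len must be >= 1")
    n = len(seq)
    w = min(max_region_len, n)
    canon, beta, wstack = _model_tables(params)
    codes = _seq_codes1(seq)
    spow = _scale_powers(codes, n, params, canon, beta)
    wml_close = math.exp(-beta * params.multiloop_close)
    wml_branch = math.exp(-beta * params.multiloop_branch)
    Zb, Qm, Qm2, Qpre, Qsuf = K.inside(
        codes, n, canon, wstack, params.loop_a, params.loop_b,
        wml_close, wml_branch, beta, spow, 0, 0)
    Zhat = K.outside(codes, n, wstack, params.loop_a, params.loop_b,
                     wml_close, wml_branch, beta, spow, Zb, Qm, Qpre, Qsuf)
    pu1 = K.pu_regions(codes, n, params.loop_a, params.loop_b, wml_close,
                       beta, spow, w, Zb, Qm, Qm2, Qpre, Qsuf, Zhat)
    band = np.full((n, max_region_len), np.nan)
    band[:, :w] = pu1[1:, 1:]
    return AccessibilityProfile(seq.id, n, max_region_len, band)


def compute_pu_restricted(
    seq: NucleotideSequence,
    params: EnergyParameterSet,
    i: int,
    j: int,
) -> float:
    """Pu(i..j) via a restricted partition function with positions i..j
    forced unpaired.  Independent of the outside-algorithm code path; used
    as a cross-check backend at moderate sequence lengths."""
    n = len(seq)
    if not (1 <= i <= j <= n):
        raise IndexError(f"region {i}..{j} outside 1..{n}")
    canon, beta, wstack = _model_tables(params)
    codes = _seq_codes1(seq)
    spow = _scale_powers(codes, n, params, canon, beta)
    wml_close = math.exp(-beta * params.multiloop_close)
    wml_branch = math.exp(-beta * params.multiloop_branch)
    _, _, _, qpre_full, _ = K.inside(
        codes, n, canon, wstack, params.loop_a, params.loop_b,
        wml_close, wml_branch, beta, spow, 0, 0)
    _, _, _, qpre_res, _ = K.inside(
        codes, n, canon, wstack, params.loop_a, params.loop_b,
        wml_close, wml_branch, beta, spow, i, j)
    return float(qpre_res[n] / qpre_full[n])


def base_pair_probabilities(
    seq: NucleotideSequence, params: EnergyParameterSet
) -> np.ndarray:
    """Intra-molecular pair probabilities P(i,j), 1-based in a padded
    (n+2, n+2) array.  Mainly a consistency check for the outside pass:
    sum_j P(i,j) + Pu(i..i) must equal 1."""
    n = len(seq)
    canon, beta, wstack = _model_tables(params)
    codes = _seq_codes1(seq)
    spow = _scale_powers(codes, n, params, canon, beta)
    wml_close = math.exp(-beta * params.multiloop_close)
    wml_branch = math.exp(-beta * params.multiloop_branch)
    Zb, Qm, Qm2, Qpre, Qsuf = K.inside(
        codes, n, canon, wstack, params.loop_a, params.loop_b,
        wml_close, wml_branch, beta, spow, 0, 0)
    Zhat = K.outside(codes, n, wstack, params.loop_a, params.loop_b,
                     wml_close, wml_branch, beta, spow, Zb, Qm, Qpre, Qsuf)
    return K.pair_probabilities(n, Zb, Zhat, Qpre[n])


# ---------------------------------------------------------------------------
# profile TSV I/O
#
# format:  "#seq_id<TAB>length" header, then rows "i<TAB>j<TAB>Pu" with
# 1-based inclusive coordinates, for all regions with j-i+1 <= max length.

def write_profile(profile: AccessibilityProfile, path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"#{profile.sequence_id}\t{profile.length}\n")
        n, w = profile.length, profile.max_region_len
        for i in range(1, n + 1):
            for L in range(1, min(w, n - i + 1) + 1):
                j = i + L - 1
                fh.write(f"{i}\t{j}\t{profile.band[i - 1, L - 1]:.12g}\n")


def read_profile(path: str | Path) -> AccessibilityProfile:
    path = Path(path)
    lines = path.read_text().splitlines()
    if not lines or not lines[0].startswith("#"):
        raise ProfileError(f"{path}: missing '#seq_id<TAB>length' header")
    head = lines[0][1:].split("\t")
    if len(head) != 2:
        raise ProfileError(f"{path}: malformed header {lines[0]!r}")
    seq_id, n = head[0], int(head[1])
    entries: dict[tuple[int, int], float] = {}
    maxlen = 0
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) != 3:
            raise ProfileError(f"{path}:{lineno}: rows are 'i<TAB>j<TAB>Pu'")
        i, j, v = int(fields[0]), int(fields[1]), float(fields[2])
        if not (1 <= i <= j <= n):
            raise ProfileError(f"{path}:{lineno}: region {i}..{j} outside 1..{n}")
        if not (0.0 <= v <= 1.0):
            raise ProfileError(
                f"{path}:{lineno}: probability {v} outside [0, 1]"
            )
        entries[(i, j)] = v
        maxlen = max(maxlen, j - i + 1)
    if not entries:
        raise ProfileError(f"{path}: no profile rows")
    band = np.full((n, maxlen), np.nan)
    for (i, j), v in entries.items():
        band[i - 1, j - i] = v
    prof = AccessibilityProfile(seq_id, n, maxlen, band)
    prof.validate()
    return prof
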