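"""Deterministic desk-scale benchmark fixtures and enumeration oracles.

The generator emulates the structure of a bacterial sRNA target screen: a
set of sRNAs, a toy genome per synthetic organism with protein-coding genes
whose start-codon windows form the target set, a subset of targets carrying
a planted interaction site (a subsequence reverse-complementary to a
subsequence of the paired sRNA, placed near the start codon), and a
verified-pair table listing exactly the planted pairs.

Planted sites are drawn from a designated A/C-rich, low-self-structure
domain of the sRNA, so the reverse-complementary target site is G/U/C-
leaning and thermodynamically strong; with ``planted_site_accessible`` the
site flanks are composition-biased against intra-molecular pairing.  All
randomness comes from a single :class:`numpy.random.Generator` (PCG64)
seeded from ``rng_seed``; identical specs produce byte-identical files.

This module also hosts :func:`enumerate_structures`, the exhaustive
enumeration of intra-molecular secondary structures used as the independent
oracle for the accessibility partition function.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energy import (
    ALPHABET,
    EnergyParameterSet,
    NucleotideSequence,
    PAIR_CODE,
    ENCODE,
)

_COMPLEMENT = str.maketrans("ACGU", "UGCA")
_RNA2DNA = str.maketrans("U", "T")


def reverse_complement(residues: str) -> str:
    return residues.translate(_COMPLEMENT)[::-1]


# ---------------------------------------------------------------------------
# structure enumeration oracle

#: maximum sequence length accepted by the enumeration oracle
ENUMERATION_BOUND = 15
_MIN_HAIRPIN = 3


def _canonical(a: str, b: str) -> bool:
    return PAIR_CODE[ENCODE[a], ENCODE[b]] >= 0


def count_structures(seq: NucleotideSequence) -> int:
    """Count non-crossing structures (min hairpin 3) by a direct interval
    recursion; an independent check on the enumeration below."""
    s = seq.residues
    n = len(s)
    memo: dict[tuple[int, int], int] = {}

    def c(i: int, j: int) -> int:  # 0-based inclusive interval
        if j - i + 1 < _MIN_HAIRPIN + 2:
            return 1
        key = (i, j)
        if key not in memo:
            total = c(i + 1, j)
            for e in range(i + _MIN_HAIRPIN + 1, j + 1):
                if _canonical(s[i], s[e]):
                    total += c(i + 1, e - 1) * c(e + 1, j)
            memo[key] = total
        return memo[key]

    return c(0, n - 1)


def structure_energy(
    pairs: tuple[tuple[int, int], ...],
    seq: NucleotideSequence,
    params: EnergyParameterSet,
) -> float:
    """Free energy of one intra-molecular structure (pairs 1-based).

    Loop decomposition: hairpins and interior loops/bulges cost
    ``a + b*size``; exactly stacked dyads use the stacking table; a
    multiloop costs the closing constant plus the per-branch constant for
    each inner helix; exterior-loop bases are free.
    """
    if not pairs:
        return 0.0
    s = seq.residues
    by_open = sorted(pairs)
    # children of each pair (direct nesting)
    children: dict[tuple[int, int], list[tuple[int, int]]] = {p: [] for p in by_open}
    roots: list[tuple[int, int]] = []
    stack: list[tuple[int, int]] = []
    for p, q in by_open:
        while stack and stack[-1][1] < p:
            stack.pop()
        if stack:
            children[stack[-1]].append((p, q))
        else:
            roots.append((p, q))
        stack.append((p, q))
    e = 0.0
    for (p, q), kids in children.items():
        if not kids:
            e += params.loop_a + params.loop_b * (q - p - 1)
        elif len(kids) == 1:
            (pp, qq) = kids[0]
            u1, u2 = pp - p - 1, q - qq - 1
            if u1 == 0 and u2 == 0:
                e += float(params.stack[
                    PAIR_CODE[ENCODE[s[p - 1]], ENCODE[s[q - 1]]],
                    PAIR_CODE[ENCODE[s[pp - 1]], ENCODE[s[qq - 1]]],
                ])
            else:
                e += params.loop_cost(u1, u2)
        else:
            e += params.multiloop_close + params.multiloop_branch * len(kids)
    return e


def enumerate_structures(
    seq: NucleotideSequence, params: EnergyParameterSet
) -> list[tuple[tuple[tuple[int, int], ...], float]]:
    """All non-crossing intra-molecular structures (canonical pairs, min
    hairpin loop 3) with their free energies.  1-based pair coordinates.

    Only valid up to :data:`ENUMERATION_BOUND` nt; this is the oracle
    backend for the accessibility tests, not a production folding routine.
    """
    s = seq.residues
    n = len(s)
    if n > ENUMERATION_BOUND:
        raise ValueError(
            f"sequence length {n} exceeds enumeration bound {ENUMERATION_BOUND}"
        )
    memo: dict[tuple[int, int], list[tuple[tuple[int, int], ...]]] = {}

    def structs(i: int, j: int) -> list[tuple[tuple[int, int], ...]]:
        # 1-based inclusive interval
        if j - i + 1 < _MIN_HAIRPIN + 2:
            return [()]
        key = (i, j)
        if key not in memo:
            out = list(structs(i + 1, j))
            for e in range(i + _MIN_HAIRPIN + 1, j + 1):
                if _canonical(s[i - 1], s[e - 1]):
                    for inner in structs(i + 1, e - 1):
                        for rest in structs(e + 1, j):
                            out.append(((i, e),) + inner + rest)
            memo[key] = out
        return memo[key]

    return [
        (st, structure_energy(st, seq, params)) for st in structs(1, n)
    ]


def boltzmann_pu(
    seq: NucleotideSequence,
    params: EnergyParameterSet,
    i: int,
    j: int,
    structures: list[tuple[tuple[tuple[int, int], ...], float]] | None = None,
) -> float:
    """Oracle Pu(i..j): Boltzmann-weighted fraction of structures leaving
    positions i..j unpaired."""
    if structures is None:
        structures = enumerate_structures(seq, params)
    beta = 1.0 / params.rt
    z = 0.0
    zu = 0.0
    for pairs, e in structures:
        w = math.exp(-beta * e)
        z += w
        if all(not (i <= p <= j or i <= q <= j) for p, q in pairs):
            zu += w
    return zu / z


# ---------------------------------------------------------------------------
# fixture generation

#: nucleotide distributions used by the generator.  The sRNA seed domain is
#: purine-only (G-rich): a purine run cannot base-pair with itself, so the
#: domain stays accessible, and the reverse-complementary target site is a
#: pyrimidine run (C-rich) - thermodynamically strong (C:G stacks) yet
#: self-structure-free.  The sRNA background is depleted in C/U (the
#: domain's pairing partners), and accessible-site flanks are A/C-rich.
_SEED_DOMAIN_P = {"A": 0.25, "C": 0.0, "G": 0.75, "U": 0.0}
_SRNA_BACKGROUND_P = {"A": 0.60, "C": 0.10, "G": 0.15, "U": 0.15}
_ACCESSIBLE_FLANK_P = {"A": 0.65, "C": 0.30, "G": 0.02, "U": 0.03}

#: rejection-sampling floor for the unpaired probability of a planted site
#: (target) and of the sRNA seed domain, and the attempt cap per sequence
_SITE_MIN_PU = 0.02
_MAX_RESAMPLE = 80


@dataclass(frozen=True)
class FixtureSpec:
    """Study conditions for one synthetic benchmark fixture."""

    n_srna: int = 15
    n_targets_per_organism: int = 200
    n_verified: int = 30
    target_len: int = 301
    planted_site_len: tuple[int, int] = (9, 12)
    planted_site_accessible: bool = True
    gc_content: float = 0.5
    rng_seed: int = 1
    organisms: tuple[str, ...] = ("synA",)
    srna_len: int = 60
    upstream: int = 200
    downstream: int = 100

    def __post_init__(self) -> None:
        if not (0.0 <= self.gc_content <= 1.0):
            raise ValueError("gc_content must be in [0, 1]")
        cap = self.n_srna * self.n_targets_per_organism * len(self.organisms)
        if self.n_verified > cap:
            raise ValueError(
                f"n_verified={self.n_verified} exceeds sRNA x target capacity {cap}"
            )
        lo, hi = self.planted_site_len
        if not (2 <= lo <= hi):
            raise ValueError("planted_site_len must be a (lo, hi) range, lo >= 2")
        if hi > self.target_len or hi > self.srna_len:
            raise ValueError("planted site longer than target or sRNA")
        if _SEED_DOMAIN_START + hi - 1 > self.srna_len:
            raise ValueError(
                "planted site does not fit the sRNA seed domain "
                f"(domain starts at {_SEED_DOMAIN_START})"
            )
        if self.target_len != self.upstream + self.downstream + 1:
            raise ValueError("target_len must equal upstream + downstream + 1")


@dataclass
class Fixture:
    """In-memory view of a generated fixture plus the files written."""

    spec: FixtureSpec
    srnas: list[NucleotideSequence]
    targets: dict[str, list[NucleotideSequence]]
    genomes: dict[str, str]
    verified: pd.DataFrame        # sRNA_id, target_locus, organism
    planted: pd.DataFrame         # + site coordinates in sRNA/window
    gene_table: dict[str, list[tuple[str, int, str]]]  # locus, start pos, strand
    paths: dict[str, Path] = field(default_factory=dict)


def _draw(rng: np.random.Generator, length: int, probs: dict[str, float]) -> str:
    letters = np.array(list("ACGU"))
    p = np.array([probs[c] for c in "ACGU"])
    p = p / p.sum()
    return "".join(rng.choice(letters, size=length, p=p))


def _random_rna(rng: np.random.Generator, length: int, gc: float) -> str:
    p = {"A": (1 - gc) / 2, "U": (1 - gc) / 2, "C": gc / 2, "G": gc / 2}
    return _draw(rng, length, p)


_GENE_STRIDE = 420
# 1-based start of the sRNA seed domain.  The domain has exactly the length
# of the sRNA's planted site and is planted in full: any unused strong
# domain positions would hand spurious gapped duplexes more firepower than
# the planted site itself.  One seed region per sRNA, reused across its
# targets, mirrors how bacterial sRNAs deploy a single conserved domain.
_SEED_DOMAIN_START = 10
_SITE_WINDOW = (-50, -23)  # planted-site placement relative to the start codon
_FLANK = 20
_CDS_LEN = 90


def _write_fasta(path: Path, seqs: list[NucleotideSequence], as_dna: bool) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            res = s.residues.translate(_RNA2DNA) if as_dna else s.residues
            fh.write(f">{s.id}" + (f" {s.description}" if s.description else "") + "\n")
            for off in range(0, len(res), 60):
                fh.write(res[off: off + 60] + "\n")


def _region_pu(residues: str, i: int, j: int, params) -> float:
    from .accessibility import compute_pu_restricted

    return compute_pu_restricted(NucleotideSequence("w", residues), params, i, j)


def _build_srna(
    rng, spec: FixtureSpec, name: str, params
) -> tuple[NucleotideSequence, int]:
    """An sRNA with an accessible purine seed domain of planted-site
    length: the background is resampled (deterministically) until the
    domain's unpaired probability clears the floor.  Returns the sequence
    and the domain length."""
    lo_len, hi_len = spec.planted_site_len
    dom_len = int(rng.integers(lo_len, hi_len + 1))
    dom = _draw(rng, dom_len, _SEED_DOMAIN_P)
    a = _SEED_DOMAIN_START
    best, best_pu = "", -1.0
    for _ in range(_MAX_RESAMPLE):
        res = list(_draw(rng, spec.srna_len, _SRNA_BACKGROUND_P))
        res[a - 1: a - 1 + dom_len] = dom
        cand = "".join(res)
        pu = _region_pu(cand, a, a + dom_len - 1, params)
        if pu > best_pu:
            best, best_pu = cand, pu
        if pu >= _SITE_MIN_PU:
            break
    return NucleotideSequence(name, best), dom_len


def _build_planted_window(rng, spec: FixtureSpec, srna: NucleotideSequence,
                          s_start: int, site_len: int, w_start: int,
                          params) -> str:
    """A target window carrying the reverse complement of the sRNA site.

    With ``planted_site_accessible`` the flanks are composition-biased and
    the random background is resampled until the planted site's unpaired
    probability clears the floor (low-structure context)."""
    site = srna.residues[s_start - 1: s_start + site_len - 1]
    planted = reverse_complement(site)
    up = spec.upstream
    tries = _MAX_RESAMPLE if spec.planted_site_accessible else 1
    best, best_pu = "", -1.0
    for _ in range(tries):
        win = list(_random_rna(rng, spec.target_len, spec.gc_content))
        win[up: up + 3] = "AUG"
        win[w_start - 1: w_start - 1 + site_len] = planted
        if spec.planted_site_accessible:
            fl = _draw(rng, _FLANK, _ACCESSIBLE_FLANK_P)
            fr = _draw(rng, _FLANK, _ACCESSIBLE_FLANK_P)
            a = max(0, w_start - 1 - _FLANK)
            win[a: w_start - 1] = fl[: w_start - 1 - a]
            b = min(spec.target_len, w_start - 1 + site_len + _FLANK)
            win[w_start - 1 + site_len: b] = fr[: b - (w_start - 1 + site_len)]
        cand = "".join(win)
        if not spec.planted_site_accessible:
            return cand
        pu = _region_pu(cand, w_start, w_start + site_len - 1, params)
        if pu > best_pu:
            best, best_pu = cand, pu
        if pu >= _SITE_MIN_PU:
            break
    return best


def generate_fixture(
    spec: FixtureSpec, outdir: str | Path, params=None
) -> Fixture:
    """Generate the fixture files and return the in-memory view.

    Writes per organism a genome FASTA (DNA) and GFF3, one combined target
    FASTA per organism, the sRNA FASTA, the verified-pair TSV and a
    planted-site detail TSV into ``outdir``.  ``params`` is the energy
    parameter set used when enforcing site accessibility (default preset
    when omitted).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.Generator(np.random.PCG64(spec.rng_seed))
    if params is None:
        from .energy import load_parameters

        params = load_parameters("default")

    built = [
        _build_srna(rng, spec, f"srna{t + 1:02d}", params)
        for t in range(spec.n_srna)
    ]
    srnas = [s for s, _ in built]
    domain_len = {s.id: n for s, n in built}

    # choose verified pairs: distinct targets per organism, round-robin
    n_org = len(spec.organisms)
    per_org = [spec.n_verified // n_org + (1 if k < spec.n_verified % n_org else 0)
               for k in range(n_org)]
    verified_rows = []
    planted_rows = []
    targets: dict[str, list[NucleotideSequence]] = {}
    genomes: dict[str, str] = {}
    gene_table: dict[str, list[tuple[str, int, str]]] = {}

    for org_idx, org in enumerate(spec.organisms):
        n_tgt = spec.n_targets_per_organism
        planted_targets = rng.choice(n_tgt, size=per_org[org_idx], replace=False)
        srna_for_target = {
            int(g): int(rng.integers(spec.n_srna)) for g in planted_targets
        }
        windows: list[NucleotideSequence] = []
        for g in range(n_tgt):
            locus = f"{org.upper()}_{g + 1:04d}"
            if g in srna_for_target:
                srna = srnas[srna_for_target[g]]
                site_len = domain_len[srna.id]  # the full seed domain
                s_start = _SEED_DOMAIN_START    # 1-based
                wlo, whi = _SITE_WINDOW
                rel = int(rng.integers(wlo, whi - site_len + 1))
                w_start = spec.upstream + 1 + rel       # 1-based in window
                win = _build_planted_window(
                    rng, spec, srna, s_start, site_len, w_start, params
                )
                verified_rows.append((srna.id, locus, org))
                planted_rows.append((
                    srna.id, locus, org, s_start, s_start + site_len - 1,
                    w_start, w_start + site_len - 1, site_len,
                ))
            else:
                body = list(_random_rna(rng, spec.target_len, spec.gc_content))
                body[spec.upstream: spec.upstream + 3] = "AUG"
                win = "".join(body)
            windows.append(NucleotideSequence(locus, win))
        targets[org] = windows

        # assemble the toy genome and gene table
        n_len = n_tgt * _GENE_STRIDE + 500
        genome = list(_random_rna(rng, n_len, spec.gc_content))
        genes: list[tuple[str, int, str]] = []
        for g, win_seq in enumerate(windows):
            anchor = 230 + g * _GENE_STRIDE  # 1-based start-codon position
            strand = "-" if rng.random() < 0.3 else "+"
            w = win_seq.residues
            if strand == "+":
                genome[anchor - spec.upstream - 1: anchor + spec.downstream] = w
            else:
                rc = reverse_complement(w)
                genome[anchor - spec.downstream - 1: anchor + spec.upstream] = rc
            genes.append((win_seq.id, anchor, strand))
        genomes[org] = "".join(genome)
        gene_table[org] = genes

    fixture = Fixture(
        spec=spec,
        srnas=srnas,
        targets=targets,
        genomes=genomes,
        verified=pd.DataFrame(
            verified_rows, columns=["sRNA_id", "target_locus", "organism"]
        ),
        planted=pd.DataFrame(
            planted_rows,
            columns=["sRNA_id", "target_locus", "organism",
                     "site_start1", "site_end1", "site_start2", "site_end2",
                     "site_len"],
        ),
        gene_table=gene_table,
    )

    # ---- write files
    paths = fixture.paths
    paths["srna_fasta"] = outdir / "srnas.fa"
    _write_fasta(paths["srna_fasta"], srnas, as_dna=False)
    for org in spec.organisms:
        fa = outdir / f"targets_{org}.fa"
        _write_fasta(fa, targets[org], as_dna=False)
        paths[f"targets_{org}"] = fa
        gfa = outdir / f"genome_{org}.fa"
        contig = f"{org}_chr"
        _write_fasta(
            gfa, [NucleotideSequence(contig, genomes[org])], as_dna=True
        )
        paths[f"genome_{org}"] = gfa
        gff = outdir / f"genome_{org}.gff3"
        with open(gff, "w") as fh:
            fh.write("##gff-version 3\n")
            fh.write(f"##sequence-region {contig} 1 {len(genomes[org])}\n")
            for locus, anchor, strand in gene_table[org]:
                if strand == "+":
                    lo, hi = anchor, anchor + _CDS_LEN - 1
                else:
                    lo, hi = anchor - _CDS_LEN + 1, anchor
                fh.write(
                    f"{contig}\tseedscan\tCDS\t{lo}\t{hi}\t.\t{strand}\t0\t"
                    f"ID=cds-{locus};locus_tag={locus}\n"
                )
        paths[f"gff_{org}"] = gff
    paths["verified"] = outdir / "verified_pairs.tsv"
    fixture.verified.to_csv(paths["verified"], sep="\t", index=False)
    paths["planted"] = outdir / "planted_sites.tsv"
    fixture.planted.to_csv(paths["planted"], sep="\t", index=False)
    return fixture
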