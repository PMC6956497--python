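"""sRNA target-screen benchmarking: window extraction, ranking, top-N
recovery of verified pairs, and parameter sweeps.

The pipeline mirrors a genome-scale sRNA target screen: target sequences
are windows around annotated start codons (by default 200 nt upstream to
100 nt downstream, on the coding strand); each sRNA is scored against
every target; per sRNA the ``topN`` targets with the most stable predicted
interaction (lowest E) are kept and the number of literature-verified
sRNA-target pairs among them is accumulated.  That count is a lower bound
on the true positives among the top predictions.  Parameter sweeps report
recovery and wall-clock time per configuration relative to a named
reference configuration; accessibility profiles are precomputed and shared
so runtimes compare the prediction stage only.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Optional

import gffutils
import numpy as np
import pandas as pd
from Bio import SeqIO

from .accessibility import AccessibilityProfile, compute_unpaired_probabilities
from .energy import NucleotideSequence
from .fixtures import reverse_complement
from .predict import PredictionConfig, predict


class BenchmarkError(ValueError):
    pass


@dataclass(frozen=True)
class TargetWindowSpec:
    """Window around the start codon: positions -upstream..+downstream with
    the start-codon first base at +1 (window length upstream+downstream+1,
    truncated at contig ends)."""

    upstream: int = 200
    downstream: int = 100

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("upstream and downstream must be >= 0")


def extract_target_windows(
    genome_fasta: str | Path,
    annotation_gff: str | Path,
    spec: TargetWindowSpec = TargetWindowSpec(),
) -> list[NucleotideSequence]:
    """One start-codon window per protein-coding gene (CDS features).

    Windows are taken on the coding strand (reverse-complemented for
    minus-strand genes), transcribed to RNA, and named by locus tag.
    Genes with several CDS records use the 5'-most start.  Windows
    truncated by a contig end are flagged in the description.
    """
    contigs = {
        rec.id: str(rec.seq).upper().replace("T", "U")
        for rec in SeqIO.parse(str(genome_fasta), "fasta")
    }
    if not contigs:
        raise BenchmarkError(f"{genome_fasta}: no contigs")
    db = gffutils.create_db(
        str(annotation_gff), dbfn=":memory:", force=True, keep_order=True,
        merge_strategy="create_unique",
    )
    # 5'-most translation start per locus
    starts: dict[str, tuple[str, str, int]] = {}
    for feat in db.features_of_type("CDS"):
        locus = feat.attributes.get("locus_tag", [feat.id])[0]
        if feat.start is None or feat.end is None:
            raise BenchmarkError(f"CDS {locus}: missing coordinates")
        anchor = feat.start if feat.strand == "+" else feat.end
        if locus in starts:
            seqid, strand, prev = starts[locus]
            if strand != feat.strand or seqid != feat.seqid:
                raise BenchmarkError(f"locus {locus}: inconsistent CDS records")
            anchor = min(prev, anchor) if strand == "+" else max(prev, anchor)
        starts[locus] = (feat.seqid, feat.strand, anchor)

    windows = []
    for locus, (seqid, strand, anchor) in starts.items():
        if seqid not in contigs:
            raise BenchmarkError(f"locus {locus}: contig {seqid!r} not in genome")
        contig = contigs[seqid]
        n = len(contig)
        if strand == "+":
            lo, hi = anchor - spec.upstream, anchor + spec.downstream
        else:
            lo, hi = anchor - spec.downstream, anchor + spec.upstream
        clo, chi = max(1, lo), min(n, hi)
        seq = contig[clo - 1: chi]
        if strand == "-":
            seq = reverse_complement(seq)
        truncated = (clo != lo) or (chi != hi)
        desc = f"{seqid}:{clo}-{chi}({strand})" + (" truncated" if truncated else "")
        windows.append(NucleotideSequence(locus, seq, description=desc))
    return windows


# ---------------------------------------------------------------------------
# verified pairs

_VERIFIED_COLUMNS = ["sRNA_id", "target_locus", "organism"]


def read_verified_pairs(path: str | Path) -> pd.DataFrame:
    """Verified sRNA-target pair table (TSV with columns sRNA_id,
    target_locus, organism); duplicate triples are rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in _VERIFIED_COLUMNS if c not in df.columns]
    if missing:
        raise BenchmarkError(
            f"{path}: missing column(s) {', '.join(missing)}"
        )
    df = df[_VERIFIED_COLUMNS]
    if df.isna().any().any():
        raise BenchmarkError(f"{path}: empty fields in verified-pair table")
    if df.duplicated().any():
        dup = df[df.duplicated()].iloc[0]
        raise BenchmarkError(
            f"{path}: duplicate verified pair {tuple(dup)}"
        )
    return df.reset_index(drop=True)


# ---------------------------------------------------------------------------
# profiles, ranking, recovery

class ProfileCache:
    """Computes and memoizes accessibility profiles per sequence id."""

    def __init__(self, params, max_region_len: int):
        self.params = params
        self.max_region_len = max_region_len
        self._store: dict[str, AccessibilityProfile] = {}

    def get(self, seq: NucleotideSequence) -> AccessibilityProfile:
        prof = self._store.get(seq.id)
        if prof is None:
            prof = compute_unpaired_probabilities(
                seq, self.params, min(self.max_region_len, len(seq))
            )
            self._store[seq.id] = prof
        return prof


def rank_targets(
    srna: NucleotideSequence,
    targets: list[NucleotideSequence],
    cfg: PredictionConfig,
    profiles: Optional[ProfileCache] = None,
) -> list[tuple[str, Optional[float]]]:
    """Targets sorted by ascending interaction energy E; targets with no
    reported interaction go last; ties break lexicographically by id."""
    if not targets:
        raise BenchmarkError("empty target set")
    if profiles is None:
        profiles = ProfileCache(cfg.params, cfg.interaction.intLenMax)
    prof1 = profiles.get(srna)
    rows: list[tuple[str, Optional[float]]] = []
    for tgt in targets:
        res = predict(srna, tgt, cfg, prof1, profiles.get(tgt))
        rows.append((tgt.id, None if res is None else float(res.E)))
    rows.sort(key=lambda r: (r[1] is None, r[1] if r[1] is not None else 0.0, r[0]))
    return rows


@dataclass
class RecoveryReport:
    """Per-sRNA ranked-target recovery of verified pairs within topN."""

    topN: int
    per_srna: pd.DataFrame    # organism, sRNA_id, n_verified, recovered
    details: pd.DataFrame     # organism, sRNA_id, target_locus, rank, recovered

    @property
    def total_recovered(self) -> int:
        return int(self.per_srna["recovered"].sum())

    @property
    def total_verified(self) -> int:
        return int(self.per_srna["n_verified"].sum())


def compute_recovery(
    rankings: dict[tuple[str, str], list[tuple[str, Optional[float]]]],
    verified: pd.DataFrame,
    topN: int = 100,
) -> RecoveryReport:
    """Count verified pairs whose target ranks within the first ``topN``
    scored predictions of its sRNA.  Unscored targets (no reported
    interaction) never count as recovered."""
    if topN < 0:
        raise BenchmarkError("topN must be >= 0")
    det_rows = []
    per_rows = []
    groups = verified.groupby(["organism", "sRNA_id"], sort=True)
    for (org, srna_id), grp in groups:
        key = (org, srna_id)
        if key not in rankings:
            raise BenchmarkError(
                f"verified sRNA {srna_id!r} (organism {org!r}) missing from rankings"
            )
        ranked = rankings[key]
        pos = {tid: r + 1 for r, (tid, e) in enumerate(ranked) if e is not None}
        rec = 0
        for locus in grp["target_locus"]:
            rank = pos.get(locus)
            hit = rank is not None and rank <= topN
            rec += int(hit)
            det_rows.append((org, srna_id, locus, rank, hit))
        per_rows.append((org, srna_id, len(grp), rec))
    per = pd.DataFrame(
        per_rows, columns=["organism", "sRNA_id", "n_verified", "recovered"]
    )
    det = pd.DataFrame(
        det_rows,
        columns=["organism", "sRNA_id", "target_locus", "rank", "recovered"],
    )
    return RecoveryReport(topN=topN, per_srna=per, details=det)


# ---------------------------------------------------------------------------
# parameter sweeps

def sweep(
    configs: dict[str, PredictionConfig],
    srnas: list[NucleotideSequence],
    targets: dict[str, list[NucleotideSequence]],
    verified: pd.DataFrame,
    topN: int = 100,
    reference: Optional[str] = None,
    profiles: Optional[dict[str, ProfileCache]] = None,
) -> tuple[pd.DataFrame, dict[str, RecoveryReport]]:
    """Run every configuration over the full screen and compare.

    Returns the comparison table (total recovered, recovery relative to
    the reference configuration, wall-clock seconds and ratio; runtimes
    exclude accessibility precomputation) and the per-config
    :class:`RecoveryReport` with per-pair detail.
    """
    if not configs:
        raise BenchmarkError("no configurations to sweep")
    if reference is None:
        reference = next(iter(configs))
    if reference not in configs:
        raise BenchmarkError(f"reference config {reference!r} not in sweep")
    maxlen = max(c.interaction.intLenMax for c in configs.values())
    caches: dict[tuple[str, str], ProfileCache] = {}

    def cache_for(org: str, cfg: PredictionConfig) -> ProfileCache:
        if profiles is not None:
            return profiles[org]
        key = (org, cfg.params.name)  # accessibility depends on the parameter set
        if key not in caches:
            cache = ProfileCache(cfg.params, maxlen)
            for s in srnas:
                cache.get(s)
            for t in targets[org]:
                cache.get(t)
            caches[key] = cache
        return caches[key]

    for org in targets:  # precompute outside the timed loop
        for cfg in configs.values():
            cache_for(org, cfg)

    reports: dict[str, RecoveryReport] = {}
    rows = []
    for name, cfg in configs.items():
        t0 = time.perf_counter()
        rankings = {}
        for org, tgts in targets.items():
            for srna in srnas:
                rankings[(org, srna.id)] = rank_targets(
                    srna, tgts, cfg, cache_for(org, cfg)
                )
        elapsed = time.perf_counter() - t0
        reports[name] = compute_recovery(rankings, verified, topN)
        rows.append((name, reports[name].total_recovered, elapsed))
    ref_rec = dict((r[0], r[1]) for r in rows)[reference]
    ref_time = dict((r[0], (r[1], r[2])) for r in rows)[reference][1]
    table = pd.DataFrame(rows, columns=["config", "recovered", "runtime_s"])
    table["relative_recovery"] = (
        table["recovered"] / ref_rec if ref_rec else np.nan
    )
    table["runtime_ratio"] = table["runtime_s"] / ref_time if ref_time else np.nan
    return table, reports
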