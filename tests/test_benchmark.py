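"""Target-window extraction, ranking, recovery bookkeeping and sweeps."""

from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from seedscan.bench import (
    BenchmarkError,
    ProfileCache,
    TargetWindowSpec,
    compute_recovery,
    extract_target_windows,
    rank_targets,
    read_verified_pairs,
    sweep,
)
from seedscan.energy import NucleotideSequence
from seedscan.fixtures import reverse_complement
from seedscan.io import read_fasta
from seedscan.predict import (
    InteractionConstraintSet,
    PredictionConfig,
    SeedConstraintSet,
    preset,
)


def _write_toy_genome(tmp_path, contig_seq, features):
    fa = tmp_path / "g.fa"
    fa.write_text(">chr1\n" + contig_seq + "\n")
    gff = tmp_path / "g.gff3"
    lines = ["##gff-version 3"]
    for locus, lo, hi, strand in features:
        lines.append(
            f"chr1\ttoy\tCDS\t{lo}\t{hi}\t.\t{strand}\t0\t"
            f"ID=cds-{locus};locus_tag={locus}"
        )
    gff.write_text("\n".join(lines) + "\n")
    return fa, gff


class TestWindowExtraction:
    def test_plus_strand_manual_slice(self, tmp_path, rng):
        contig = "".join(rng.choice(list("ACGT"), 600))
        fa, gff = _write_toy_genome(tmp_path, contig, [("g1", 300, 389, "+")])
        (win,) = extract_target_windows(fa, gff, TargetWindowSpec(200, 100))
        expected = contig[99:400].replace("T", "U")  # genomic 100..400, 1-based
        assert win.id == "g1"
        assert win.residues == expected
        assert len(win) == 301
        assert "truncated" not in win.description

    def test_minus_strand_reverse_complement(self, tmp_path, rng):
        contig = "".join(rng.choice(list("ACGT"), 600))
        fa, gff = _write_toy_genome(tmp_path, contig, [("g1", 211, 300, "-")])
        (win,) = extract_target_windows(fa, gff, TargetWindowSpec(200, 100))
        # anchor = CDS end = 300; genomic slice 200..500 reverse-complemented
        expected = reverse_complement(contig[199:500].replace("T", "U"))
        assert win.residues == expected

    def test_contig_start_truncation_flagged(self, tmp_path, rng):
        contig = "".join(rng.choice(list("ACGT"), 600))
        fa, gff = _write_toy_genome(tmp_path, contig, [("g1", 50, 139, "+")])
        (win,) = extract_target_windows(fa, gff, TargetWindowSpec(200, 100))
        assert "truncated" in win.description
        assert len(win) == 150  # genomic 1..150

    def test_five_prime_most_start_for_multi_cds(self, tmp_path, rng):
        contig = "".join(rng.choice(list("ACGT"), 900))
        fa, gff = _write_toy_genome(
            tmp_path, contig,
            [("g1", 400, 489, "+"), ("g1", 340, 460, "+")],
        )
        (win,) = extract_target_windows(fa, gff, TargetWindowSpec(200, 100))
        assert win.residues == contig[139:440].replace("T", "U")

    def test_missing_contig_is_error(self, tmp_path):
        fa = tmp_path / "g.fa"
        fa.write_text(">chr1\nACGTACGT\n")
        gff = tmp_path / "g.gff3"
        gff.write_text("##gff-version 3\n"
                       "chr2\ttoy\tCDS\t2\t7\t.\t+\t0\tID=x;locus_tag=x\n")
        with pytest.raises(BenchmarkError, match="contig"):
            extract_target_windows(fa, gff)


class TestVerifiedTable:
    def test_reads_and_rejects_duplicates(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("sRNA_id\ttarget_locus\torganism\n"
                     "s1\tg1\torgA\ns1\tg2\torgA\n")
        df = read_verified_pairs(p)
        assert len(df) == 2
        p.write_text("sRNA_id\ttarget_locus\torganism\n"
                     "s1\tg1\torgA\ns1\tg1\torgA\n")
        with pytest.raises(BenchmarkError, match="duplicate"):
            read_verified_pairs(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "v.tsv"
        p.write_text("sRNA_id\ttarget_locus\ns1\tg1\n")
        with pytest.raises(BenchmarkError, match="organism"):
            read_verified_pairs(p)


class TestRankingAndRecovery:
    def test_rank_order_and_none_last(self, small_fixture, params):
        fx = small_fixture
        cfg = preset("default")
        cache = ProfileCache(params, cfg.interaction.intLenMax)
        srna = fx.srnas[0]
        ranked = rank_targets(srna, fx.targets["synA"][:12], cfg, cache)
        es = [e for _, e in ranked if e is not None]
        assert es == sorted(es)
        tail = [e for _, e in ranked[len(es):]]
        assert all(e is None for e in tail)

    def test_ranking_invariant_under_target_permutation(self, small_fixture, params):
        fx = small_fixture
        cfg = preset("default")
        cache = ProfileCache(params, cfg.interaction.intLenMax)
        srna = fx.srnas[1]
        tgts = fx.targets["synA"][:10]
        fwd = rank_targets(srna, tgts, cfg, cache)
        rev = rank_targets(srna, list(reversed(tgts)), cfg, cache)
        assert fwd == rev

    def test_recovery_rank_definitions(self):
        ranked = [(f"g{r}", -50.0 + r) for r in range(1, 121)]
        verified = pd.DataFrame(
            [("s1", "g5", "o"), ("s1", "g101", "o")],
            columns=["sRNA_id", "target_locus", "organism"],
        )
        rep = compute_recovery({("o", "s1"): ranked}, verified, topN=100)
        det = rep.details.set_index("target_locus")
        assert bool(det.loc["g5", "recovered"]) is True
        assert bool(det.loc["g101", "recovered"]) is False
        assert rep.total_recovered == 1
        assert compute_recovery({("o", "s1"): ranked}, verified,
                                topN=0).total_recovered == 0

    def test_unscored_targets_never_recover(self):
        ranked = [("g1", -3.0), ("g2", None)]
        verified = pd.DataFrame(
            [("s1", "g2", "o")], columns=["sRNA_id", "target_locus", "organism"]
        )
        rep = compute_recovery({("o", "s1"): ranked}, verified, topN=100)
        assert rep.total_recovered == 0

    def test_recovery_monotone_in_topn(self):
        rng = np.random.default_rng(3)
        ranked = [(f"g{r}", float(e)) for r, e in
                  enumerate(np.sort(rng.normal(size=60)))]
        verified = pd.DataFrame(
            [("s1", f"g{r}", "o") for r in (0, 7, 25, 40, 59)],
            columns=["sRNA_id", "target_locus", "organism"],
        )
        counts = [
            compute_recovery({("o", "s1"): ranked}, verified, n).total_recovered
            for n in (0, 5, 10, 30, 60)
        ]
        assert counts == sorted(counts)
        assert all(
            rep <= min(n, 5)
            for rep, n in zip(counts, (0, 5, 10, 30, 60))
        )

    def test_missing_srna_is_error(self):
        verified = pd.DataFrame(
            [("s2", "g1", "o")], columns=["sRNA_id", "target_locus", "organism"]
        )
        with pytest.raises(BenchmarkError, match="missing from rankings"):
            compute_recovery({("o", "s1"): [("g1", -1.0)]}, verified, 10)


class TestSweep:
    def test_self_reference_ratios(self, small_fixture):
        fx = small_fixture
        table, reports = sweep(
            {"default": preset("default")},
            fx.srnas, {"synA": fx.targets["synA"]}, fx.verified, topN=10,
        )
        row = table.iloc[0]
        assert row["relative_recovery"] == pytest.approx(1.0)
        assert row["runtime_ratio"] == pytest.approx(1.0)
        assert reports["default"].total_recovered == row["recovered"]

    def test_degenerate_seed_filter_recovers_nothing(self, small_fixture, params):
        fx = small_fixture
        impossible = PredictionConfig(
            seed=SeedConstraintSet(seedMinPu=1.0),
            interaction=InteractionConstraintSet(),
            params=params,
        )
        table, reports = sweep(
            {"default": preset("default"), "impossible": impossible},
            fx.srnas, {"synA": fx.targets["synA"]}, fx.verified,
            topN=10, reference="default",
        )
        assert int(table.set_index("config").loc["impossible", "recovered"]) == 0

    def test_unknown_reference_rejected(self, small_fixture):
        with pytest.raises(BenchmarkError, match="reference"):
            sweep({"a": preset("default")}, small_fixture.srnas,
                  {"synA": small_fixture.targets["synA"]},
                  small_fixture.verified, reference="b")
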