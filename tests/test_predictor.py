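"""Constrained MFE interaction prediction vs. the exhaustive oracle."""

from dataclasses import replace

import numpy as np
import pytest

from conftest import random_rna
from seedscan.accessibility import compute_unpaired_probabilities, ed_penalty
from seedscan.energy import NucleotideSequence
from seedscan.fixtures import reverse_complement
from seedscan.predict import (
    InteractionConstraintSet,
    PredictionConfig,
    SeedConstraintSet,
    enumerate_seeds,
    predict,
    predict_bruteforce,
    preset,
)


def loose_config(params, seed_required=False, **ic):
    defaults = dict(intLenMax=15, intMaxE=50.0, maxLoop=6)
    defaults.update(ic)
    return PredictionConfig(
        seed=SeedConstraintSet(seed_required=seed_required, seedBP=3),
        interaction=InteractionConstraintSet(**defaults),
        params=params,
    )


def random_config(params, r):
    bp = int(r.integers(2, 6))
    sc = SeedConstraintSet(
        seed_required=bool(r.random() < 0.7),
        seedBP=bp,
        allowGU=bool(r.random() < 0.5),
        seedMaxE=None if r.random() < 0.5 else float(r.uniform(-6, 4)),
        seedMaxEhybrid=None if r.random() < 0.5 else float(r.uniform(-6, 6)),
        seedMinPu=None if r.random() < 0.5 else float(r.choice([0.001, 0.05, 0.3])),
    )
    ic = InteractionConstraintSet(
        intLenMax=int(r.integers(max(bp, 4), 16)),
        intMaxE=float(r.choice([0.0, 2.0, -2.0])),
        intMinPu=None if r.random() < 0.6 else float(r.choice([0.001, 0.1])),
        maxLoop=int(r.integers(0, 5)),
    )
    return PredictionConfig(seed=sc, interaction=ic, params=params)


def profiled(seq, params):
    return compute_unpaired_probabilities(seq, params, len(seq))


class TestAgainstOracle:
    @pytest.mark.parametrize("trial", range(40))
    def test_dp_equals_bruteforce(self, params, trial):
        """predict and predict_bruteforce agree in E and boundaries under
        randomized constraint configurations."""
        r = np.random.default_rng(9000 + trial)
        s1 = random_rna(r, int(r.integers(8, 15)), "q")
        s2 = random_rna(r, int(r.integers(8, 15)), "t")
        cfg = random_config(params, r)
        p1, p2 = profiled(s1, params), profiled(s2, params)
        a = predict(s1, s2, cfg, p1, p2)
        b = predict_bruteforce(s1, s2, cfg, p1, p2)
        assert (a is None) == (b is None)
        if a is not None:
            assert a.E == pytest.approx(b.E, abs=1e-6)
            assert (a.region1, a.region2) == (b.region1, b.region2)

    def test_perfect_complement_forms_full_duplex(self, params):
        s1 = NucleotideSequence("a", "GGCAGCUC")
        s2 = NucleotideSequence("b", reverse_complement("GGCAGCUC"))
        cfg = loose_config(params)
        res = predict(s1, s2, cfg)
        assert res is not None
        assert res.region1 == (1, 8) and res.region2 == (1, 8)
        assert len(res.pairs) == 8
        oracle = predict_bruteforce(s1, s2, cfg)
        assert res.E == pytest.approx(oracle.E, abs=1e-9)

    def test_no_shared_seed_means_no_interaction(self, params):
        s1 = NucleotideSequence("a", "AAAAAAAAAAAA")
        s2 = NucleotideSequence("b", "AAAAAAAAAAAA")  # no A:A pairs at all
        cfg = PredictionConfig(
            seed=SeedConstraintSet(seedBP=7),
            interaction=InteractionConstraintSet(intLenMax=12),
            params=params,
        )
        assert predict(s1, s2, cfg) is None


class TestConstraintMonotonicity:
    def test_any_added_constraint_never_improves_energy(self, params):
        for trial in range(12):
            r = np.random.default_rng(700 + trial)
            s1, s2 = random_rna(r, 12, "q"), random_rna(r, 13, "t")
            p1, p2 = profiled(s1, params), profiled(s2, params)
            base_cfg = loose_config(params, seed_required=True)
            base = predict(s1, s2, base_cfg, p1, p2)
            tighter = [
                replace(base_cfg, seed=replace(base_cfg.seed, allowGU=False)),
                replace(base_cfg, seed=replace(base_cfg.seed, seedMinPu=0.05)),
                replace(base_cfg, seed=replace(base_cfg.seed, seedMaxE=-1.0)),
                replace(base_cfg,
                        interaction=replace(base_cfg.interaction, maxLoop=1)),
                replace(base_cfg,
                        interaction=replace(base_cfg.interaction, intLenMax=6)),
                replace(base_cfg,
                        interaction=replace(base_cfg.interaction, intMinPu=0.05)),
            ]
            for cfg in tighter:
                res = predict(s1, s2, cfg, p1, p2)
                if base is None:
                    assert res is None  # tightening cannot create a hit
                elif res is not None:
                    assert res.E >= base.E - 1e-9

    def test_loop_relaxation_never_hurts(self, params):
        for trial in range(8):
            r = np.random.default_rng(800 + trial)
            s1, s2 = random_rna(r, 13, "q"), random_rna(r, 13, "t")
            p1, p2 = profiled(s1, params), profiled(s2, params)
            energies = []
            for ml in (0, 1, 2, 4):
                cfg = loose_config(params, maxLoop=ml)
                res = predict(s1, s2, cfg, p1, p2)
                energies.append(np.inf if res is None else res.E)
            assert all(b <= a + 1e-9 for a, b in zip(energies, energies[1:]))


class TestSeeds:
    def test_unique_complementary_seed_found(self, params):
        core = "GGGGCCC"
        s1 = NucleotideSequence("a", "AAAA" + core + "AAAA")
        s2 = NucleotideSequence("b", "AAAA" + reverse_complement(core) + "AAAA")
        sc = SeedConstraintSet(seedBP=7)
        seeds = enumerate_seeds(s1, s2, profiled(s1, params),
                                profiled(s2, params), sc, params)
        assert len(seeds) == 1
        (seed,) = seeds
        assert seed.region1 == (5, 11) and seed.region2 == (5, 11)
        assert seed.E_seed == pytest.approx(
            seed.Eh_seed + seed.ED1_seed + seed.ED2_seed
        )

    def test_gu_seed_rejected_when_gu_forbidden(self, params):
        core = "GGGUCCC"  # pairs against its WC complement; plant a GU instead
        s1 = NucleotideSequence("a", "AAAA" + core + "AAAA")
        comp = list(reverse_complement(core))
        # make the U:A pair at seed position 4 a U:G wobble
        comp[3] = "G"
        s2 = NucleotideSequence("b", "AAAA" + "".join(comp) + "AAAA")
        p1, p2 = profiled(s1, params), profiled(s2, params)
        with_gu = enumerate_seeds(s1, s2, p1, p2,
                                  SeedConstraintSet(seedBP=7), params)
        without = enumerate_seeds(s1, s2, p1, p2,
                                  SeedConstraintSet(seedBP=7, allowGU=False),
                                  params)
        assert any(any(p.is_gu for p in s.pairs) for s in with_gu)
        assert without == []

    def test_seed_sets_nest(self, params):
        """Stricter filters and longer seeds only shrink the seed set."""
        for trial in range(10):
            r = np.random.default_rng(300 + trial)
            s1, s2 = random_rna(r, 14, "q"), random_rna(r, 14, "t")
            p1, p2 = profiled(s1, params), profiled(s2, params)

            def anchors(sc):
                return {(s.region1, s.region2[1])
                        for s in enumerate_seeds(s1, s2, p1, p2, sc, params)}

            loose = enumerate_seeds(s1, s2, p1, p2,
                                    SeedConstraintSet(seedBP=3), params)
            left_ends = {(s.region1[0], s.region2[1]) for s in loose}
            longer = enumerate_seeds(s1, s2, p1, p2,
                                     SeedConstraintSet(seedBP=4), params)
            for s in longer:  # every (s+1)-seed starts an s-seed
                assert (s.region1[0], s.region2[1]) in left_ends
            no_gu = enumerate_seeds(s1, s2, p1, p2,
                                    SeedConstraintSet(seedBP=3, allowGU=False),
                                    params)
            assert {s.region1 for s in no_gu} <= {s.region1 for s in loose}
            tight_pu = enumerate_seeds(
                s1, s2, p1, p2, SeedConstraintSet(seedBP=3, seedMinPu=0.1), params
            )
            soft_pu = enumerate_seeds(
                s1, s2, p1, p2, SeedConstraintSet(seedBP=3, seedMinPu=0.001), params
            )
            assert ({(s.region1, s.region2) for s in tight_pu}
                    <= {(s.region1, s.region2) for s in soft_pu})


class TestPresets:
    def test_default_preset_values(self):
        cfg = preset("default")
        assert cfg.seed.seedBP == 7 and cfg.seed.allowGU
        assert cfg.seed.seedMaxE is None and cfg.seed.seedMinPu is None
        assert cfg.interaction.intLenMax == 150
        assert cfg.interaction.maxLoop == 16
        assert cfg.interaction.intMaxE == 0.0

    def test_recommended_preset_values(self):
        cfg = preset("recommended")
        assert cfg.seed.seedBP == 7 and not cfg.seed.allowGU
        assert cfg.seed.seedMinPu == pytest.approx(0.001)
        assert cfg.interaction.intLenMax == 60
        assert cfg.interaction.maxLoop == 8
        assert cfg.interaction.intMinPu == pytest.approx(0.001)

    def test_unknown_preset_rejected(self):
        with pytest.raises(ValueError):
            preset("fast")


class TestOutputContracts:
    def test_energy_decomposition_self_consistent(self, params):
        for trial in range(10):
            r = np.random.default_rng(40 + trial)
            s1, s2 = random_rna(r, 14, "q"), random_rna(r, 14, "t")
            p1, p2 = profiled(s1, params), profiled(s2, params)
            res = predict(s1, s2, loose_config(params), p1, p2)
            if res is None:
                continue
            ed1 = ed_penalty(p1.pu(*res.region1), params.temperature)
            ed2 = ed_penalty(p2.pu(*res.region2), params.temperature)
            assert res.E == pytest.approx(res.Eh + res.ED1 + res.ED2, abs=1e-9)
            assert res.ED1 == pytest.approx(ed1, abs=1e-9)
            assert res.ED2 == pytest.approx(ed2, abs=1e-9)
            # terminal pairs coincide with region boundaries
            assert res.pairs[0].pos1 == res.region1[0]
            assert res.pairs[-1].pos1 == res.region1[1]
            assert res.pairs[0].pos2 == res.region2[1]
            assert res.pairs[-1].pos2 == res.region2[0]

    def test_reported_seed_is_contained_and_canonical(self, params):
        r = np.random.default_rng(77)
        for _ in range(20):
            s1, s2 = random_rna(r, 14, "q"), random_rna(r, 14, "t")
            p1, p2 = profiled(s1, params), profiled(s2, params)
            cfg = loose_config(params, seed_required=True)
            res = predict(s1, s2, cfg, p1, p2)
            if res is None:
                continue
            assert res.seed is not None
            positions = {(p.pos1, p.pos2) for p in res.pairs}
            for p in res.seed.pairs:
                assert (p.pos1, p.pos2) in positions
            assert len(res.seed.pairs) == cfg.seed.seedBP

    def test_hybrid_dp_wellformed(self, params):
        s1 = NucleotideSequence("a", "GGCAGCUC")
        s2 = NucleotideSequence("b", reverse_complement("GGCAGCUC"))
        res = predict(s1, s2, loose_config(params))
        dp = res.hybrid_dp()
        left, right = dp.split("&")
        assert left.count("(") == right.count(")") == len(res.pairs)

    def test_deterministic_reruns(self, params):
        r = np.random.default_rng(123)
        s1, s2 = random_rna(r, 13, "q"), random_rna(r, 13, "t")
        p1, p2 = profiled(s1, params), profiled(s2, params)
        cfg = loose_config(params, seed_required=True)
        a = predict(s1, s2, cfg, p1, p2)
        b = predict(s1, s2, cfg, p1, p2)
        assert (a is None) == (b is None)
        if a is not None:
            assert (a.E, a.region1, a.region2) == (b.E, b.region1, b.region2)

    def test_mismatched_profile_rejected(self, params):
        r = np.random.default_rng(5)
        s1, s2 = random_rna(r, 12, "q"), random_rna(r, 12, "t")
        wrong = compute_unpaired_probabilities(random_rna(r, 9, "x"), params, 9)
        from seedscan.predict import PredictionError

        with pytest.raises(PredictionError, match="covers"):
            predict(s1, s2, loose_config(params), wrong, None)
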