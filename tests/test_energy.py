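"""Nearest-neighbor duplex scoring: parameter loading and Eh computation."""

import math
from pathlib import Path

import numpy as np
import pytest

from seedscan.energy import (
    BasePair,
    EnergyParameterError,
    PAIR_ORDER,
    hybridization_energy,
    load_parameters,
    stacking_energy,
)


def _parse_preset_tsv(name: str) -> dict:
    """Independent parse of a shipped parameter file (test-side oracle)."""
    path = Path(__import__("seedscan").__file__).parent / "data" / f"{name}.tsv"
    stack = {}
    scalars = {}
    section = None
    for line in path.read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if line.startswith("["):
            section = line[1:-1]
            continue
        f = line.split("\t")
        if section == "stack":
            stack[(f[0], f[1])] = float(f[2])
        elif section in ("init", "terminal", "loop"):
            scalars[f[0]] = float(f[1])
    return {"stack": stack, **scalars}


class TestLoading:
    def test_default_preset_is_complete(self, params):
        assert params.stack.shape == (6, 6)
        assert np.all(np.isfinite(params.stack))
        assert params.temperature == pytest.approx(310.15)

    def test_unknown_preset_rejected(self):
        with pytest.raises(EnergyParameterError, match="unknown energy preset"):
            load_parameters("no-such-preset")

    def test_incomplete_stack_table_rejected(self, tmp_path):
        src = Path(__import__("seedscan").__file__).parent / "data" / "default.tsv"
        lines = [l for l in src.read_text().splitlines()
                 if not l.startswith("CG\tGC")]
        bad = tmp_path / "incomplete.tsv"
        bad.write_text("\n".join(lines) + "\n")
        with pytest.raises(EnergyParameterError, match="incomplete stacking table"):
            load_parameters(bad)

    def test_shipped_presets_differ(self):
        a = _parse_preset_tsv("default")["stack"]
        b = _parse_preset_tsv("alt")["stack"]
        assert set(a) == set(b) and len(a) == 36
        assert any(a[d] != b[d] for d in a)


class TestStacking:
    def test_gc_stacks_stronger_than_au(self, params):
        assert stacking_energy(params, "CG", "CG") < stacking_energy(params, "AU", "AU")

    def test_wobble_stacks_weakest(self, params):
        assert stacking_energy(params, "GU", "UG") > stacking_energy(params, "CG", "GC")

    def test_pure_lookup(self, params):
        for l in PAIR_ORDER:
            for r in PAIR_ORDER:
                assert stacking_energy(params, l, r) == stacking_energy(params, l, r)

    def test_noncanonical_rejected(self, params):
        with pytest.raises(EnergyParameterError):
            stacking_energy(params, "AA", "CG")


def _mk_pairs(labels, gaps=None):
    """Helix pair list from pair labels; gaps[t] = (u1, u2) before pair t."""
    pairs = []
    i, k = 1, 100
    for t, lbl in enumerate(labels):
        if t > 0:
            u1, u2 = (0, 0) if gaps is None else gaps[t - 1]
            i += 1 + u1
            k -= 1 + u2
        pairs.append(BasePair(i, k, lbl[0], lbl[1]))
    return pairs


class TestHybridizationEnergy:
    def test_single_cg_pair_is_pure_initiation(self, params):
        assert hybridization_energy(params, _mk_pairs(["CG"])) == pytest.approx(
            params.init
        )

    def test_single_weak_pair_draws_both_end_penalties(self, params):
        e = hybridization_energy(params, _mk_pairs(["AU"]))
        assert e == pytest.approx(params.init + 2 * params.terminal_penalty)

    def test_seven_pair_helix_matches_hand_sum(self, params):
        # independent oracle: re-sum the six dyads straight from the TSV
        raw = _parse_preset_tsv("default")
        labels = ["GC", "CG", "AU", "GU", "UA", "CG", "GC"]
        expected = raw["init"]
        for l, r in zip(labels, labels[1:]):
            expected += raw["stack"][(l, r)]
        # GC ends: no terminal penalty
        got = hybridization_energy(params, _mk_pairs(labels))
        assert got == pytest.approx(expected, abs=1e-12)

    def test_interior_loop_destabilizes(self, params):
        labels = ["GC", "CG", "AU", "CG", "GC"]
        contiguous = hybridization_energy(params, _mk_pairs(labels))
        split = hybridization_energy(
            params, _mk_pairs(labels, gaps=[(0, 0), (1, 1), (0, 0), (0, 0)])
        )
        assert split > contiguous

    def test_crossing_pairs_rejected(self, params):
        pairs = [BasePair(1, 50, "C", "G"), BasePair(2, 55, "G", "C")]
        with pytest.raises(ValueError, match="ascend|crossing"):
            hybridization_energy(params, pairs)

    def test_empty_pair_list_rejected(self, params):
        with pytest.raises(ValueError, match="empty"):
            hybridization_energy(params, [])


def _random_duplex(rng, m):
    labels = [PAIR_ORDER[t] for t in rng.integers(0, 6, m)]
    gaps = [
        (0, 0) if rng.random() < 0.6 else (int(rng.integers(0, 4)),
                                           int(rng.integers(0, 4)))
        for _ in range(m - 1)
    ]
    gaps = [g if g != (0, 0) or True else g for g in gaps]
    return labels, gaps


class TestModelProperties:
    def test_resummation_additivity(self, params, rng):
        """Eh equals a flat re-summation of init, dyad and end terms."""
        raw = _parse_preset_tsv("default")
        for _ in range(200):
            m = int(rng.integers(1, 9))
            labels, gaps = _random_duplex(rng, m)
            pairs = _mk_pairs(labels, gaps)
            expected = raw["init"]
            for lbl in (labels[0], labels[-1]):
                if lbl in ("AU", "UA", "GU", "UG"):
                    expected += raw["end_penalty"]
            for t in range(m - 1):
                u1, u2 = gaps[t]
                if u1 == 0 and u2 == 0:
                    expected += raw["stack"][(labels[t], labels[t + 1])]
                else:
                    expected += raw["a"] + raw["b"] * (u1 + u2)
            assert hybridization_energy(params, pairs) == pytest.approx(
                expected, abs=1e-12
            )

    def test_gu_substitution_never_stabilizes(self, params, rng):
        for _ in range(150):
            m = int(rng.integers(2, 9))
            labels, gaps = _random_duplex(rng, m)
            base = hybridization_energy(params, _mk_pairs(labels, gaps))
            t = int(rng.integers(0, m))
            swapped = list(labels)
            swapped[t] = "GU" if rng.random() < 0.5 else "UG"
            e = hybridization_energy(params, _mk_pairs(swapped, gaps))
            assert e >= base - 1e-12

    def test_orientation_symmetry(self, params, rng):
        """Reading the duplex from the other end leaves Eh unchanged."""
        for _ in range(150):
            m = int(rng.integers(1, 9))
            labels, gaps = _random_duplex(rng, m)
            fwd = hybridization_energy(params, _mk_pairs(labels, gaps))
            rev_labels = [l[::-1] for l in reversed(labels)]
            rev_gaps = [(u2, u1) for (u1, u2) in reversed(gaps)]
            rev = hybridization_energy(params, _mk_pairs(rev_labels, rev_gaps))
            assert rev == pytest.approx(fwd, abs=1e-12)

    def test_loop_cost_monotone(self, params):
        costs = [params.loop_cost(u, 0) for u in range(1, 30)]
        assert all(b >= a for a, b in zip(costs, costs[1:]))
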