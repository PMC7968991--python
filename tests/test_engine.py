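"""Ensemble engine versus brute-force enumeration, plus dimer equilibria."""
import math

import numpy as np
import pytest
from scipy.optimize import brentq

from grnaswitch import (
    EngineParams,
    ReferenceEngine,
    SecondaryStructure,
    complex_equilibrium,
    ensemble_defect,
    mfe_fold,
    partition_function,
)

import _oracles as oracles
from conftest import random_rna


@pytest.fixture(scope="module")
def params():
    return EngineParams()


@pytest.fixture(scope="module")
def eng(params):
    return ReferenceEngine(params)


class TestMfe:
    def test_unpairable_sequence(self, eng):
        s, score = eng.mfe_fold("AAAA")
        assert s.to_dotbracket() == "...."
        assert score == 0

    def test_min_loop_blocks_short_hairpin(self, eng):
        s, score = eng.mfe_fold("ACGU")
        assert s.to_dotbracket() == "...."
        assert score == 0

    def test_gc_hairpin(self, eng):
        s, score = eng.mfe_fold("GGGAAACCC")
        assert s.to_dotbracket() == "(((...)))"
        assert score == 9

    def test_two_strand_duplex_pairs_across_nick(self, eng):
        s, score = eng.mfe_fold(["GGGG", "CCCC"])
        assert score == 12  # 4 GC pairs, nick exempt from min_loop
        assert all(s.pairs[i] == 7 - i for i in range(4))

    def test_tie_break_prefers_fewer_pairs(self):
        # with GU scoring 0, adding a GU pair never helps; the engine
        # must then prefer the structure without it
        params = EngineParams(pair_scores={"GC": 3.0, "AU": 2.0, "GU": 0.0})
        s, score = ReferenceEngine(params).mfe_fold("GAAAU")
        assert score == 0
        assert s.to_dotbracket() == "....."

    def test_determinism(self, eng):
        rng = np.random.default_rng(7)
        seq = random_rna(rng, 40)
        a = eng.mfe_fold(seq)[0]
        b = eng.mfe_fold(seq)[0]
        assert a == b

    def test_input_validation(self, eng):
        with pytest.raises(ValueError):
            eng.mfe_fold("ACGN")
        with pytest.raises(ValueError):
            eng.mfe_fold(["A", "C", "G"])


class TestPartitionFunction:
    def test_unpairable_sequence_only_empty_structure(self, eng):
        q, ppm = eng.partition_function("AAAA")
        assert q == 1.0
        assert ppm.p.max() == 0.0
        assert np.allclose(ppm.p_unpaired, 1.0)

    def test_normalization_identity(self, eng):
        rng = np.random.default_rng(11)
        for _ in range(5):
            _, ppm = eng.partition_function(random_rna(rng, 30))
            ppm.check_normalization()

    @pytest.mark.parametrize("trial", range(60))
    def test_matches_enumeration(self, trial, eng, params):
        """DP partition function and pair probabilities equal exhaustive
        enumeration for short random sequences (1 or 2 strands)."""
        rng = np.random.default_rng(1000 + trial)
        n = int(rng.integers(1, 13))
        seq = random_rna(rng, n)
        if trial % 3 == 0 and n >= 2:
            nick = int(rng.integers(1, n))
            strands = [seq[:nick], seq[nick:]]
        else:
            nick = None
            strands = seq
        z, p, p_un = oracles.brute_partition(seq, params.beta, params.min_loop, nick)
        q, ppm = eng.partition_function(strands)
        assert q == pytest.approx(z, rel=1e-9)
        assert np.max(np.abs(ppm.p - p)) < 1e-9
        assert np.max(np.abs(ppm.p_unpaired - p_un)) < 1e-9
        # MFE dominates every enumerated structure
        _, mfe_score = eng.mfe_fold(strands)
        best, table = oracles.brute_mfe(seq, params.min_loop, nick)
        assert mfe_score == pytest.approx(best, abs=1e-9)

    def test_mfe_tie_break_matches_enumeration_order(self, eng, params):
        rng = np.random.default_rng(2024)
        for _ in range(40):
            n = int(rng.integers(4, 11))
            seq = random_rna(rng, n)
            _, table = oracles.brute_mfe(seq, params.min_loop, None)
            struct, _ = eng.mfe_fold(seq)
            assert np.array_equal(struct.pairs, table), seq

    def test_duplex_init_penalty_mixing(self):
        """With a nonzero bimolecular initiation penalty, Q and pair
        probabilities must match enumeration with the penalty charged
        only to structures containing an inter-strand pair."""
        params = EngineParams(duplex_init_penalty=1.5)
        eng = ReferenceEngine(params)
        rng = np.random.default_rng(5)
        for _ in range(15):
            n = int(rng.integers(4, 11))
            seq = random_rna(rng, n)
            nick = int(rng.integers(1, n))
            z = 0.0
            acc = np.zeros((n, n))
            for pairs in oracles.enumerate_structures(seq, params.min_loop, nick):
                w = oracles.structure_weight(
                    seq, pairs, params.beta, nick, params.duplex_init_penalty
                )
                z += w
                for i, j in pairs:
                    acc[i, j] += w
                    acc[j, i] += w
            q, ppm = eng.partition_function([seq[:nick], seq[nick:]])
            assert q == pytest.approx(z, rel=1e-9)
            assert np.max(np.abs(ppm.p - acc / z)) < 1e-9


class TestEnsembleDefect:
    def test_unpaired_target_of_unpairable_sequence(self, eng):
        target = SecondaryStructure.from_dotbracket("....")
        assert eng.ensemble_defect("AAAA", target) == 0.0

    def test_impossible_hairpin_target(self, eng):
        target = SecondaryStructure.from_dotbracket("(((...)))")
        d = eng.ensemble_defect("AAAAAAAAA", target)
        assert d == pytest.approx(6 / 9)

    def test_matches_enumeration(self, eng, params):
        rng = np.random.default_rng(31)
        for _ in range(25):
            n = int(rng.integers(4, 12))
            seq = random_rna(rng, n)
            # random valid nested target: reuse the oracle's enumeration
            structs = oracles.enumerate_structures(seq, params.min_loop, None)
            pick = structs[int(rng.integers(len(structs)))]
            table = np.full(n, -1, dtype=np.int64)
            for i, j in pick:
                table[i], table[j] = j, i
            target = SecondaryStructure([n], table, min_loop=params.min_loop)
            expected = oracles.brute_defect(seq, table, params.beta, params.min_loop)
            assert eng.ensemble_defect(seq, target) == pytest.approx(expected, abs=1e-9)

    def test_target_length_mismatch(self, eng):
        target = SecondaryStructure.from_dotbracket(".....")
        with pytest.raises(ValueError):
            eng.ensemble_defect("ACGU", target)


class TestComplexEquilibrium:
    def test_vanishing_association(self):
        eq = complex_equilibrium(1.0, 1.0, 1e-300, 1e-6, 1e-6)
        assert eq.fraction_complexed == pytest.approx(0.0, abs=1e-12)

    def test_saturating_association(self):
        eq = complex_equilibrium(1.0, 1.0, 1e30, 1e-6, 1e-6)
        assert eq.fraction_complexed == pytest.approx(1.0, abs=1e-6)

    def test_known_micromolar_case(self):
        # K = 1e6 /M at a = b = 1 uM gives ~38.2% complexed
        eq = complex_equilibrium(1.0, 1.0, 1e6, 1e-6, 1e-6)
        assert eq.ab_complex == pytest.approx(3.8196601e-7, rel=1e-6)
        assert eq.fraction_complexed == pytest.approx(0.38196601, rel=1e-6)

    def test_matches_numeric_root(self):
        for K in [1e3, 1e6, 1e9, 1e12]:
            for c in [1e-9, 1e-7, 1e-6, 1e-5]:
                eq = complex_equilibrium(1.0, 1.0, K, c, c)
                f = brentq(
                    lambda x: K * (c - x) * (c - x) - x, 0.0, c, xtol=1e-30, rtol=1e-14
                )
                assert eq.ab_complex == pytest.approx(f, rel=1e-8)

    def test_mass_conservation(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            K = 10 ** rng.uniform(0, 14)
            a = 10 ** rng.uniform(-9, -4)
            b = 10 ** rng.uniform(-9, -4)
            eq = complex_equilibrium(1.0, 1.0, K, a, b)
            assert eq.a_free + eq.ab_complex == pytest.approx(a, rel=1e-9)
            assert eq.b_free + eq.ab_complex == pytest.approx(b, rel=1e-9)
            assert min(eq.a_free, eq.b_free, eq.ab_complex) >= 0

    def test_monotone_in_K_and_concentration(self):
        fracs = [
            complex_equilibrium(1.0, 1.0, K, 1e-6, 1e-6).fraction_complexed
            for K in np.logspace(2, 12, 30)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))
        fracs = [
            complex_equilibrium(1.0, 1.0, 1e7, c, c).fraction_complexed
            for c in np.logspace(-9, -4, 30)
        ]
        assert all(b >= a for a, b in zip(fracs, fracs[1:]))

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            complex_equilibrium(0.0, 1.0, 1.0, 1e-6, 1e-6)
        with pytest.raises(ValueError):
            complex_equilibrium(1.0, 1.0, 1.0, 0.0, 1e-6)


class TestAdapterContract:
    """Any FoldEngine must satisfy the structural contract; value-level
    agreement between engines is NOT required."""

    def _check(self, engine, strands):
        struct, score = engine.mfe_fold(strands)
        assert isinstance(score, float)
        struct_n = struct.n
        q, ppm = engine.partition_function(strands)
        assert q > 0
        assert ppm.n == struct_n
        total = ppm.p.sum(axis=1) + ppm.p_unpaired
        assert np.allclose(total, 1.0, atol=1e-6)
        target = SecondaryStructure(
            struct.lengths if len(struct.lengths) == 1 else struct.lengths,
            np.full(struct_n, -1),
        )
        d = engine.ensemble_defect(strands, target)
        assert 0.0 <= d <= 1.0

    def test_reference_engine_contract(self, eng):
        self._check(eng, "GGGAAACCCAAGGG")
        self._check(eng, ["GGGAAACCC", "GGGUUUCCC"])

    def test_vienna_adapter_contract(self):
        vienna = pytest.importorskip("grnaswitch.vienna")
        if not vienna.HAVE_VIENNA:
            pytest.skip("ViennaRNA bindings unavailable")
        engine = vienna.ViennaEngine()
        self._check(engine, "GGGAAACCCAAGGG")
        self._check(engine, ["GGGAAACCC", "GGGUUUCCC"])


def test_module_level_wrappers(default_arch):
    s, score = mfe_fold("GGGAAACCC")
    assert score == 9
    q, ppm = partition_function("AAAA")
    assert q == 1.0
    target = SecondaryStructure.from_dotbracket("....")
    assert ensemble_defect("AAAA", target) == 0.0
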