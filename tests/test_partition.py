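"""Folding engine vs the exhaustive-enumeration oracle."""

from collections import Counter

import numpy as np
import pytest
from scipy import stats

from shapefold.exhaustive import (best_mea_structure, boltzmann_ensemble,
                                  mea_score)
from shapefold.partition import (FoldingInputError, PairProbabilityMatrix,
                                 StructureEnsemble, mea_structure,
                                 pair_frequencies, partition_function,
                                 stochastic_sample)
from shapefold.structure import SecondaryStructure

from conftest import random_sequence


class TestPartitionFunction:
    def test_unpairable_sequence_all_zero(self, params, consts):
        P, fe = partition_function("AAAAAA", params, consts)
        assert np.all(P.P == 0.0)
        assert fe == 0.0

    @pytest.mark.parametrize("seed", range(6))
    @pytest.mark.parametrize("with_bonus", [False, True])
    def test_matches_enumeration(self, params, consts, seed, with_bonus):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(8, 15))
        seq = random_sequence(rng, n, gc_bias=0.6)
        bonus = rng.normal(0, 0.6, n) if with_bonus else None
        _, _, Pref, fe_ref = boltzmann_ensemble(seq, params, consts, bonus)
        P, fe = partition_function(seq, params, consts, bonus)
        assert np.max(np.abs(P.P - Pref.P)) <= 1e-9
        assert fe == pytest.approx(fe_ref, rel=1e-9, abs=1e-12)

    def test_structured_sequence_with_multibranch(self, params, consts):
        seq = "GGCGAAAGCCGGCAAAGCC"  # supports two-hairpin/multiloop folds
        _, _, Pref, fe_ref = boltzmann_ensemble(seq, params, consts)
        P, fe = partition_function(seq, params, consts)
        assert np.max(np.abs(P.P - Pref.P)) <= 1e-9
        assert fe == pytest.approx(fe_ref, rel=1e-9)

    def test_pairing_probability_bounds(self, params, consts):
        rng = np.random.default_rng(12)
        for _ in range(5):
            seq = random_sequence(rng, int(rng.integers(10, 30)), gc_bias=0.7)
            P, _ = partition_function(seq, params, consts)
            assert np.all(P.total_pairing() <= 1 + 1e-9)
            assert np.all(P.P >= 0) and np.all(P.P <= 1 + 1e-9)

    def test_input_errors(self, params, consts):
        with pytest.raises(FoldingInputError, match="length"):
            partition_function("ACG", params, consts)
        with pytest.raises(FoldingInputError, match="position 3"):
            partition_function("ACXGGG", params, consts)
        with pytest.raises(FoldingInputError, match="bonus"):
            partition_function("GGGAAAACCC", params, consts, bonus=np.zeros(5))

    def test_zero_bonus_reproduces_unrestrained(self, params, consts):
        seq = "GGCGCAAAAGCGCC"
        P0, fe0 = partition_function(seq, params, consts)
        Pz, fez = partition_function(seq, params, consts,
                                     bonus=np.zeros(len(seq)))
        assert np.array_equal(P0.P, Pz.P)
        assert fe0 == fez


class TestStochasticSample:
    def test_unpairable_sequence_gives_open_chains(self, params, consts):
        ens = stochastic_sample("AAAAAA", params, consts, n=100, seed=5)
        assert len(ens) == 100
        assert all(len(s.pairs) == 0 for s in ens)

    def test_same_seed_same_ensemble(self, params, consts):
        seq = "GGCGAAAACGCC"
        a = stochastic_sample(seq, params, consts, n=2000, seed=9)
        b = stochastic_sample(seq, params, consts, n=2000, seed=9)
        assert all(x.pairs == y.pairs for x, y in zip(a, b))
        c = stochastic_sample(seq, params, consts, n=2000, seed=10)
        assert any(x.pairs != y.pairs for x, y in zip(a, c))

    def test_frequencies_match_boltzmann(self, params, consts):
        seq = "GGCGAAAACGCC"
        n = 20_000
        structs, probs, _, _ = boltzmann_ensemble(seq, params, consts)
        ens = stochastic_sample(seq, params, consts, n=n, seed=2024)
        counts = Counter(s.pairs for s in ens)
        observed = np.array([counts.get(s.pairs, 0) for s in structs])
        assert observed.sum() == n
        se = np.sqrt(probs * (1 - probs) * n)
        z = np.abs(observed - probs * n) / np.maximum(se, 1e-12)
        assert np.all(z[se > 0] <= 4.0)

    def test_sample_size_validation(self, params, consts):
        with pytest.raises(FoldingInputError):
            stochastic_sample("GGGAAAACCC", params, consts, n=0)


class TestPairFrequencies:
    def test_identical_structures(self):
        s = SecondaryStructure.from_pairs(10, [(0, 9), (1, 8)])
        ens = StructureEnsemble([s] * 4)
        P = pair_frequencies(ens)
        assert P.P[0, 9] == 1.0 and P.P[1, 8] == 1.0
        assert P.P.sum() == 2.0

    def test_disjoint_supports(self):
        a = SecondaryStructure.from_pairs(12, [(0, 11)])
        b = SecondaryStructure.from_pairs(12, [(1, 10)])
        P = pair_frequencies(StructureEnsemble([a, b]))
        assert set(np.unique(P.P)) <= {0.0, 0.5}

    def test_empty_ensemble_rejected(self):
        with pytest.raises(Exception):
            pair_frequencies(StructureEnsemble([]))

    def test_large_sample_approaches_partition(self, params, consts):
        seq = "GGCGAAAACGCC"
        Pexact, _ = partition_function(seq, params, consts)
        ens = stochastic_sample(seq, params, consts, n=20_000, seed=77)
        Pemp = pair_frequencies(ens)
        assert np.max(np.abs(Pemp.P - Pexact.P)) < 0.02


class TestMEA:
    def test_dominant_single_pair(self):
        P = np.zeros((12, 12))
        P[0, 9] = 0.9
        s = mea_structure(PairProbabilityMatrix(12, P))
        assert s.pairs == frozenset({(0, 9)})

    def test_all_zero_gives_open_chain(self):
        s = mea_structure(PairProbabilityMatrix(8, np.zeros((8, 8))))
        assert s.pairs == frozenset()

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        n = 8
        raw = np.triu(rng.random((n, n)), k=4)
        # scale rows so total pairing stays a valid probability
        scale = max(1.0, (raw.sum(axis=1) + raw.sum(axis=0)).max())
        P = PairProbabilityMatrix(n, raw / scale / 1.5)
        gamma = float(rng.choice([0.5, 1.0, 2.0]))
        s = mea_structure(P, gamma=gamma)
        score_dp = mea_score(P, s, gamma=gamma)
        score_bf, s_bf = best_mea_structure(P, gamma=gamma)
        assert score_dp == pytest.approx(score_bf, abs=1e-9)
        assert s.pairs == s_bf.pairs or score_dp == pytest.approx(
            mea_score(P, s_bf, gamma=gamma), abs=1e-9)


def test_sampler_chi_square_not_rejected(params, consts):
    """Goodness of fit of sampled structure frequencies to enumerated
    Boltzmann probabilities across several seeds (alpha = 0.01)."""
    seq = "GGCGAAAACGCC"
    structs, probs, _, _ = boltzmann_ensemble(seq, params, consts)
    for seed in (1, 2, 3):
        n = 5000
        ens = stochastic_sample(seq, params, consts, n=n, seed=seed)
        counts = Counter(s.pairs for s in ens)
        observed = np.array([counts.get(s.pairs, 0) for s in structs],
                            dtype=float)
        expected = probs * n
        # pool rare structures so chi-square assumptions hold
        keep = expected >= 5
        obs = np.append(observed[keep], observed[~keep].sum())
        exp = np.append(expected[keep], expected[~keep].sum())
        _, p = stats.chisquare(obs, exp)
        assert p > 0.01
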