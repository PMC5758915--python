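"""Clustering, centroids, Shannon entropy, reference merging."""

import numpy as np
import pytest

from shapefold.cluster import (EnsembleModel, bp_distance, build_ensemble_model,
                               centroid, cluster_structures,
                               merge_equivalent_clusters, shannon_entropy)
from shapefold.partition import PairProbabilityMatrix, StructureEnsemble
from shapefold.synthetic import planted_partition
from shapefold.structure import SecondaryStructure


def hairpin(length, pairs):
    return SecondaryStructure.from_pairs(length, pairs)


class TestBpDistance:
    def test_identical_is_zero(self):
        s = hairpin(12, [(0, 11), (1, 10)])
        assert bp_distance(s, s) == 0

    def test_one_pair_vs_open(self):
        a = hairpin(12, [(0, 11)])
        b = SecondaryStructure(12, frozenset())
        assert bp_distance(a, b) == 1

    def test_symmetric_difference(self):
        a = hairpin(12, [(0, 11), (1, 10)])
        b = hairpin(12, [(0, 11), (2, 9)])
        assert bp_distance(a, b) == 2

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            bp_distance(SecondaryStructure(10, frozenset()),
                        SecondaryStructure(12, frozenset()))


class TestClusterStructures:
    def test_two_separated_registers(self):
        ens, labels = planted_partition(sizes=(60, 40), seed=1)
        res = cluster_structures(ens, seed=0)
        assert res.k == 2
        # assignments match planted groups exactly (up to label names)
        for g in (1, 2):
            got = res.assignments[labels == g]
            assert len(set(got)) == 1

    def test_all_identical_falls_back_to_one_cluster(self):
        s = hairpin(12, [(0, 11), (1, 10)])
        res = cluster_structures(StructureEnsemble([s] * 50))
        assert res.k == 1
        assert np.all(res.assignments == 1)

    def test_three_planted_groups_recovered_exactly(self):
        ens, labels = planted_partition(sizes=(50, 30, 20), seed=2)
        res = cluster_structures(ens, seed=0)
        assert res.k == 3
        sizes = sorted(((res.assignments == k).sum() for k in (1, 2, 3)),
                       reverse=True)
        assert sizes == [50, 30, 20]
        for g in (1, 2, 3):
            assert len(set(res.assignments[labels == g])) == 1

    def test_reproducible_given_seed(self):
        ens, _ = planted_partition(sizes=(40, 30), seed=3)
        a = cluster_structures(ens, seed=11)
        b = cluster_structures(ens, seed=11)
        assert a.k == b.k
        assert np.array_equal(a.assignments, b.assignments)


class TestCentroid:
    def test_identical_cluster_returns_member(self):
        s = hairpin(12, [(0, 11), (1, 10)])
        assert centroid([s] * 7).pairs == s.pairs

    def test_majority_pair_rule(self):
        a = hairpin(12, [(1, 9)])
        b = hairpin(12, [(1, 9)])
        c = hairpin(12, [(2, 8)])
        cent = centroid([a, b, c])
        assert cent.pairs == frozenset({(1, 9)})  # 2/3 > 0.5 > 1/3

    def test_exact_half_excluded(self):
        a = hairpin(12, [(1, 9)])
        b = SecondaryStructure(12, frozenset())
        assert centroid([a, b]).pairs == frozenset()

    def test_empty_cluster_rejected(self):
        with pytest.raises(ValueError):
            centroid([])

    def test_conflicting_majorities_resolved_to_legal_structure(self):
        # (1, 9) unanimous; (2, 8) at 3/5 and (3, 7) at 2/5: only the
        # majority inner pair survives and the result is a legal structure
        members = ([hairpin(12, [(1, 9), (2, 8)])] * 3
                   + [hairpin(12, [(1, 9), (3, 7)])] * 2)
        cent = centroid(members)
        cent.validate()
        assert cent.pairs == frozenset({(1, 9), (2, 8)})


class TestShannonEntropy:
    def test_deterministic_pairing_has_zero_entropy(self):
        P = np.zeros((10, 10))
        P[0, 9] = 1.0
        assert shannon_entropy(PairProbabilityMatrix(10, P)) == 0.0

    def test_hand_value_single_half_probability(self):
        P = np.zeros((10, 10))
        P[0, 9] = 0.5
        s = shannon_entropy(PairProbabilityMatrix(10, P))
        assert s == pytest.approx(-(0.5 * np.log10(0.5)) / 10, abs=1e-12)
        assert s == pytest.approx(0.01505, abs=1e-5)

    def test_entropy_non_negative_and_bounded(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            n = 12
            raw = np.triu(rng.random((n, n)), k=4)
            scale = max(1.0, (raw.sum(0) + raw.sum(1)).max())
            P = PairProbabilityMatrix(n, raw / scale)
            s = shannon_entropy(P)
            max_pairs = np.count_nonzero(np.triu(np.ones((n, n)), k=4))
            assert 0 <= s <= np.log10(np.e) * max_pairs / n + 1.0


class TestEnsembleModel:
    def test_populations_conserved(self):
        ens, _ = planted_partition(sizes=(30, 20), seed=5)
        model = build_ensemble_model(ens, seed=0)
        assert model.populations.sum() == pytest.approx(1.0, abs=1e-9)
        assert model.populations[0] >= model.populations[-1]

    def test_low_population_clusters_flagged(self):
        ens, _ = planted_partition(sizes=(99, 1), seed=6)
        model = build_ensemble_model(ens, seed=0)
        flags = [c.flagged for c in model.conformations]
        if len(flags) == 2:
            assert flags == [False, True]

    def test_invalid_populations_rejected(self):
        from shapefold.cluster import Conformation
        P = PairProbabilityMatrix(10, np.zeros((10, 10)))

        def conf(pop):
            return Conformation(SecondaryStructure(10, frozenset()), pop, P)

        with pytest.raises(ValueError):
            EnsembleModel([conf(0.5), conf(0.4)], 0.0)


class TestMergeEquivalentClusters:
    def _model(self, centroids, pops):
        from shapefold.cluster import Conformation
        P = PairProbabilityMatrix(12, np.zeros((12, 12)))
        confs = [Conformation(c, p, P) for c, p in zip(centroids, pops)]
        return EnsembleModel(confs, 0.0)

    def test_identical_centroid_assigned(self):
        ref = hairpin(12, [(0, 11), (1, 10)])
        model = self._model([ref], [1.0])
        out = merge_equivalent_clusters(model, [ref])
        assert out["assignments"] == [0]
        assert out["populations"][0] == pytest.approx(1.0)

    def test_below_threshold_is_other(self):
        ref = hairpin(12, [(0, 11), (1, 10), (2, 9), (3, 8)])
        far = hairpin(12, [(0, 11)])
        model = self._model([far], [1.0])
        out = merge_equivalent_clusters(model, [ref], accuracy_threshold=0.8)
        assert out["assignments"] == ["other"]

    def test_tie_goes_to_first_reference(self):
        cent = hairpin(12, [(1, 10)])
        refa = hairpin(12, [(1, 10), (2, 9)])
        refb = hairpin(12, [(1, 10), (3, 8)])
        model = self._model([cent], [1.0])
        out = merge_equivalent_clusters(model, [refa, refb],
                                        accuracy_threshold=0.5)
        assert out["assignments"] == [0]

    def test_slipped_register_clusters_pool_population(self):
        ref = hairpin(12, [(0, 11), (1, 10), (2, 9)])
        slipped = hairpin(12, [(1, 10), (2, 9)])
        model = self._model([ref, slipped], [0.7, 0.3])
        out = merge_equivalent_clusters(model, [ref], accuracy_threshold=0.8)
        assert out["populations"][0] == pytest.approx(1.0)
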