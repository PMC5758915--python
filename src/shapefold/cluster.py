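"""Conformation discovery: clustering a Boltzmann sample into an ensemble model.

A sampled ensemble is embedded as binary base-pair indicator vectors
(squared Euclidean distance between two such vectors equals the base-pair
distance, the symmetric difference of their pair sets).  Partitions for
each candidate number of clusters k are scored with the Calinski-Harabasz
index  CH(k) = [B(k)/(k-1)] / [W(k)/(n-k)]  and the k maximizing CH is
chosen; near-degenerate samples fall back to a single cluster.  Each
cluster is summarized by its centroid — the structure built from every
pair present in more than half of the cluster's members — and its
population, the cluster's share of the sample, interpreted as the
conformation's equilibrium abundance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.cluster import KMeans
from sklearn.metrics import calinski_harabasz_score

from .partition import PairProbabilityMatrix, StructureEnsemble, pair_frequencies
from .structure import SecondaryStructure

DEFAULT_K_MAX = 10
DEFAULT_MIN_POPULATION = 0.02


def bp_distance(a: SecondaryStructure, b: SecondaryStructure) -> int:
    """Base-pair distance: size of the symmetric difference of pair sets."""
    if a.length != b.length:
        raise ValueError(f"structure lengths differ: {a.length} vs {b.length}")
    return len(a.pairs ^ b.pairs)


@dataclass
class ClusterResult:
    """Partition of a sampled ensemble into k clusters."""

    assignments: np.ndarray  # labels 1..k, one per sampled structure
    k: int
    ch_scores: dict[int, float]  # CH index per candidate k
    distance_metric: str = "base-pair symmetric difference"

    def __post_init__(self):
        self.assignments = np.asarray(self.assignments, dtype=np.int64)
        if self.k < 1 or self.assignments.min(initial=1) < 1 \
                or (self.assignments.max(initial=1) > self.k):
            raise ValueError("labels must lie in 1..k")


@dataclass
class Conformation:
    """One modeled conformation: centroid structure, population, and the
    within-cluster pair probabilities it summarizes."""

    centroid: SecondaryStructure
    population: float
    within_cluster_pair_probs: PairProbabilityMatrix
    flagged: bool = False  # population below the reporting floor


@dataclass
class EnsembleModel:
    """Final output of the ensemble pipeline."""

    conformations: list[Conformation]
    shannon_entropy: float
    cluster_result: ClusterResult | None = None

    def __post_init__(self):
        pops = np.array([c.population for c in self.conformations])
        if np.any(pops <= 0) or abs(pops.sum() - 1.0) > 1e-9:
            raise ValueError("populations must be positive and sum to 1")
        if self.shannon_entropy < 0:
            raise ValueError("Shannon entropy must be non-negative")

    @property
    def populations(self) -> np.ndarray:
        return np.array([c.population for c in self.conformations])


def _pair_universe(ens: StructureEnsemble) -> dict[tuple[int, int], int]:
    universe: dict[tuple[int, int], int] = {}
    for s in ens:
        for p in sorted(s.pairs):
            if p not in universe:
                universe[p] = len(universe)
    return universe


def _indicator_matrix(ens: StructureEnsemble) -> np.ndarray:
    universe = _pair_universe(ens)
    X = np.zeros((len(ens), max(len(universe), 1)))
    for row, s in enumerate(ens):
        for p in s.pairs:
            X[row, universe[p]] = 1.0
    return X


def cluster_structures(ens: StructureEnsemble, k_max: int = DEFAULT_K_MAX,
                       seed: int | None = 0, ch_floor: float = 0.0,
                       ) -> ClusterResult:
    """Partition a sample and choose k by the Calinski-Harabasz index.

    Falls back to a single cluster when fewer than two distinct structures
    exist, when the sample has no dispersion, or when the best CH score
    over k = 2..k_max stays below ``ch_floor``.
    """
    n = len(ens)
    if n < 2:
        return ClusterResult(np.ones(n, dtype=np.int64), 1, {})
    X = _indicator_matrix(ens)
    distinct = len({s.pairs for s in ens})
    total_dispersion = float(((X - X.mean(axis=0)) ** 2).sum())
    if distinct < 2 or total_dispersion < 1e-12:
        return ClusterResult(np.ones(n, dtype=np.int64), 1, {})

    ch_scores: dict[int, float] = {}
    candidates: dict[int, np.ndarray] = {}
    for k in range(2, min(k_max, distinct) + 1):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed)
        labels = km.fit_predict(X)
        if len(np.unique(labels)) < 2:
            continue
        ch_scores[k] = float(calinski_harabasz_score(X, labels))
        candidates[k] = labels
    if not ch_scores:
        return ClusterResult(np.ones(n, dtype=np.int64), 1, {})
    best_k = max(ch_scores, key=lambda k: (ch_scores[k], -k))
    if ch_scores[best_k] < ch_floor:
        return ClusterResult(np.ones(n, dtype=np.int64), 1, ch_scores)

    labels = candidates[best_k]
    # relabel 1..k by descending cluster size (ties: first appearance)
    sizes = [(-(labels == lbl).sum(), np.argmax(labels == lbl), lbl)
             for lbl in np.unique(labels)]
    order = [lbl for _, _, lbl in sorted(sizes)]
    remap = {old: new + 1 for new, old in enumerate(order)}
    relabeled = np.array([remap[l] for l in labels], dtype=np.int64)
    return ClusterResult(relabeled, best_k, ch_scores)


def centroid(cluster: list[SecondaryStructure] | StructureEnsemble,
             ) -> SecondaryStructure:
    """Centroid of a cluster: all pairs with within-cluster frequency > 0.5.

    If two majority pairs conflict (shared nucleotide or crossing), pairs
    are admitted in order of descending frequency, ties broken
    lexicographically by (i, j), and later conflicting pairs are dropped,
    so the result is always a legal structure.
    """
    members = list(cluster)
    if not members:
        raise ValueError("empty cluster")
    n = len(members)
    length = members[0].length
    counts: dict[tuple[int, int], int] = {}
    for s in members:
        for p in s.pairs:
            counts[p] = counts.get(p, 0) + 1
    majority = sorted((p for p, c in counts.items() if c / n > 0.5),
                      key=lambda p: (-counts[p], p))
    accepted: list[tuple[int, int]] = []
    used: set[int] = set()
    for (i, j) in majority:
        if i in used or j in used:
            continue
        if any(k < i <= l < j or i < k <= j < l for k, l in accepted):
            continue
        accepted.append((i, j))
        used.update((i, j))
    return SecondaryStructure(length, frozenset(accepted))


def shannon_entropy(P: PairProbabilityMatrix) -> float:
    """Mean Shannon entropy of base pairing per nucleotide (log base 10)."""
    upper = np.triu(P.P, k=1)
    nz = upper[upper > 0]
    return float(-(nz * np.log10(nz)).sum() / P.N)


def build_ensemble_model(ens: StructureEnsemble,
                         clusters: ClusterResult | None = None,
                         pair_probs: PairProbabilityMatrix | None = None,
                         k_max: int = DEFAULT_K_MAX, seed: int | None = 0,
                         min_population: float = DEFAULT_MIN_POPULATION,
                         ) -> EnsembleModel:
    """Assemble centroids, populations and entropy from a clustered sample.

    ``pair_probs`` (e.g. the exact restrained pair-probability matrix) is
    used for the Shannon entropy when given; otherwise the sample's
    empirical pair frequencies are used.  Conformations are ordered by
    descending population; those below ``min_population`` are kept but
    flagged.
    """
    if clusters is None:
        clusters = cluster_structures(ens, k_max=k_max, seed=seed)
    structures = list(ens)
    conformations = []
    for label in range(1, clusters.k + 1):
        members = [s for s, l in zip(structures, clusters.assignments) if l == label]
        sub = StructureEnsemble(members, seed=ens.seed, source=ens.source)
        pop = len(members) / len(structures)
        conformations.append(Conformation(
            centroid=centroid(members), population=pop,
            within_cluster_pair_probs=pair_frequencies(sub),
            flagged=pop < min_population))
    conformations.sort(key=lambda c: -c.population)
    entropy_P = pair_probs if pair_probs is not None else pair_frequencies(ens)
    return EnsembleModel(conformations, shannon_entropy(entropy_P), clusters)


def merge_equivalent_clusters(model: EnsembleModel,
                              references: list[SecondaryStructure],
                              accuracy_threshold: float = 0.8,
                              slip: bool = True) -> dict:
    """Assign each modeled conformation to its closest reference structure.

    Several clusters can represent the same underlying conformation; each
    centroid is matched to the reference with the highest geometric-mean
    accuracy, provided that accuracy reaches ``accuracy_threshold``;
    otherwise it is labeled ``"other"``.  Ties go to the earlier reference
    in the given order.  Returns per-centroid assignments and the summed
    population per reference.
    """
    from .metrics import sensitivity_ppv

    assignments: list[int | str] = []
    pooled: dict[int | str, float] = {}
    for conf in model.conformations:
        best_idx: int | str = "other"
        best_acc = -1.0
        for idx, ref in enumerate(references):
            rep = sensitivity_ppv(conf.centroid, ref, slip=slip)
            acc = rep.geometric_mean
            if acc > best_acc + 1e-12:
                best_acc = acc
                best_idx = idx
        if best_acc < accuracy_threshold:
            best_idx = "other"
        assignments.append(best_idx)
        pooled[best_idx] = pooled.get(best_idx, 0.0) + conf.population
    return {"assignments": assignments, "populations": pooled}
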