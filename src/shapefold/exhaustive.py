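"""Brute-force enumeration over all pseudoknot-free structures.

Independent reference ("oracle") route for the dynamic programs in
:mod:`shapefold.partition`: every valid structure of a short sequence is
enumerated explicitly, scored with the loop-decomposition evaluator
``structure_energy``, and Boltzmann-weighted by hand.  Exponential in
sequence length — intended for sequences up to ~16 nt.
"""

from __future__ import annotations

from functools import lru_cache

import numpy as np

from .energy import NearestNeighborParams, ThermoConstants, structure_energy
from .partition import PairProbabilityMatrix, clean_sequence
from .structure import SecondaryStructure


def enumerate_structures(seq: str, params: NearestNeighborParams,
                         ) -> list[SecondaryStructure]:
    """All pseudoknot-free structures of ``seq`` under the model's pairing
    rules (canonical pairs, minimum hairpin size), open chain included."""
    seq = clean_sequence(seq)
    n = len(seq)
    mh = params.min_hairpin

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[frozenset, ...]:
        # all pair sets on the closed interval i..j
        if j - i < mh + 1:
            return (frozenset(),)
        out = list(enum(i + 1, j))  # i unpaired
        for k in range(i + mh + 1, j + 1):
            if not params.pair_allowed(seq[i], seq[k]):
                continue
            for inner in enum(i + 1, k - 1):
                for rest in enum(k + 1, j):
                    out.append(frozenset({(i, k)}) | inner | rest)
        return tuple(out)

    return [SecondaryStructure(n, ps) for ps in enum(0, n - 1)]


def boltzmann_ensemble(seq: str, params: NearestNeighborParams,
                       consts: ThermoConstants | None = None,
                       bonus: np.ndarray | None = None):
    """Exact Boltzmann distribution by enumeration.

    Returns
    -------
    structures : list of SecondaryStructure
    probs : ndarray
        Boltzmann probability of each structure.
    P : PairProbabilityMatrix
        Pair probabilities summed over structures.
    free_energy : float
        Ensemble free energy -kT ln Q, kcal/mol.
    """
    consts = consts or ThermoConstants()
    seq = clean_sequence(seq)
    structures = enumerate_structures(seq, params)
    energies = np.array([structure_energy(seq, s, params, bonus) for s in structures])
    logw = -energies / consts.kT
    shift = logw.max()
    w = np.exp(logw - shift)
    Z = w.sum()
    probs = w / Z
    logQ = shift + np.log(Z)
    N = len(seq)
    P = np.zeros((N, N))
    for s, p in zip(structures, probs):
        for i, j in s.pairs:
            P[i, j] += p
    return structures, probs, PairProbabilityMatrix(N, P), float(-consts.kT * logQ)


def best_mea_structure(P: PairProbabilityMatrix, gamma: float = 1.0,
                       min_hairpin: int = 3) -> tuple[float, SecondaryStructure]:
    """Brute-force maximizer of the MEA objective over all structures
    (any pair geometry respecting the minimum hairpin size)."""
    n = P.N
    prob = np.triu(P.P, k=1)
    q = P.unpaired_probability()

    @lru_cache(maxsize=None)
    def enum(i: int, j: int) -> tuple[frozenset, ...]:
        if j - i < min_hairpin + 1:
            return (frozenset(),)
        out = list(enum(i + 1, j))
        for k in range(i + min_hairpin + 1, j + 1):
            for inner in enum(i + 1, k - 1):
                for rest in enum(k + 1, j):
                    out.append(frozenset({(i, k)}) | inner | rest)
        return tuple(out)

    def score(ps: frozenset) -> float:
        paired = {x for p in ps for x in p}
        return (sum(2.0 * gamma * prob[i, j] for i, j in ps)
                + sum(q[i] for i in range(n) if i not in paired))

    best_ps = max(enum(0, n - 1), key=score)
    return score(best_ps), SecondaryStructure(n, best_ps)


def mea_score(P: PairProbabilityMatrix, s: SecondaryStructure,
              gamma: float = 1.0) -> float:
    """MEA objective value of one structure under ``P``."""
    prob = np.triu(P.P, k=1)
    q = P.unpaired_probability()
    paired = {x for p in s.pairs for x in p}
    return (sum(2.0 * gamma * prob[i, j] for i, j in s.pairs)
            + sum(q[i] for i in range(s.length) if i not in paired))
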