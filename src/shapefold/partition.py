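"""Partition function, base-pair probabilities, Boltzmann sampling, MEA.

The folding engine computes the equilibrium partition function

    Q = sum over pseudoknot-free structures s of exp(-E(s) / kT)

by dynamic programming over the loop decomposition of the energy model in
:mod:`shapefold.energy`, entirely in log space (no overflow for long
sequences).  An inside/outside pass yields the exact probability of every
canonical base pair; stochastic traceback through the inside tables draws
i.i.d. structures with their Boltzmann probabilities; and a separate
dynamic program extracts the maximum-expected-accuracy (MEA) structure
from a pair-probability matrix.

Per-nucleotide pseudo-free-energy bonuses enter the recursions exactly
where base-pair stacks are scored: each of the four stack positions
contributes its bonus once per stack, matching the loop-decomposition
evaluator ``structure_energy``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.special import logsumexp

from .energy import NearestNeighborParams, ThermoConstants
from .structure import SecondaryStructure

NEG_INF = -np.inf


class FoldingInputError(ValueError):
    """Raised for invalid sequences or mismatched restraint vectors."""


def clean_sequence(seq: str) -> str:
    """Uppercase, map T to U, and validate the RNA alphabet."""
    s = seq.strip().upper().replace("T", "U")
    for pos, c in enumerate(s, start=1):
        if c not in "ACGU":
            raise FoldingInputError(f"invalid character {c!r} at position {pos}")
    return s


@dataclass
class PairProbabilityMatrix:
    """Probabilities P[i, j] of each canonical pair (0-based, i < j)."""

    N: int
    P: np.ndarray

    def __post_init__(self):
        self.P = np.asarray(self.P, dtype=np.float64)
        if self.P.shape != (self.N, self.N):
            raise ValueError(f"P must be {self.N}x{self.N}")

    def validate(self, tol: float = 1e-9) -> None:
        if np.any(self.P < -tol) or np.any(self.P > 1 + tol):
            raise ValueError("pair probabilities outside [0, 1]")
        if np.any(self.total_pairing() > 1 + tol):
            raise ValueError("per-nucleotide pairing probability exceeds 1")

    def total_pairing(self) -> np.ndarray:
        """Probability that each nucleotide is paired (to anything)."""
        upper = np.triu(self.P, k=1)
        return upper.sum(axis=1) + upper.sum(axis=0)

    def unpaired_probability(self) -> np.ndarray:
        return 1.0 - self.total_pairing()


@dataclass
class StructureEnsemble:
    """An ordered Boltzmann sample of structures (repeats allowed)."""

    structures: list[SecondaryStructure]
    seed: int | None = None
    source: str = "unrestrained"

    def __post_init__(self):
        lengths = {s.length for s in self.structures}
        if len(lengths) > 1:
            raise ValueError("ensemble structures have differing lengths")

    @property
    def length(self) -> int:
        return self.structures[0].length

    def __len__(self) -> int:
        return len(self.structures)

    def __iter__(self):
        return iter(self.structures)


class _InsideTables:
    """Log-domain inside tables for the loop-decomposition grammar.

    V[i, j]   log partition over i..j given (i, j) paired.
    WM[i, j]  multiloop segment i..j with >= 1 branch (branch penalty and
              per-unpaired penalty included).
    W[j]      exterior prefix 0..j;  Wr[i] exterior suffix i..N-1.
    """

    def __init__(self, seq: str, params: NearestNeighborParams,
                 consts: ThermoConstants, bonus: np.ndarray | None):
        self.seq = seq
        self.params = params
        self.consts = consts
        N = self.N = len(seq)
        if N < params.min_hairpin + 2:
            raise FoldingInputError(
                f"sequence length {N} below minimum {params.min_hairpin + 2}")
        if bonus is None:
            bonus = np.zeros(N)
        bonus = np.asarray(bonus, dtype=np.float64)
        if bonus.shape != (N,):
            raise FoldingInputError(
                f"bonus length {bonus.shape} does not match sequence length {N}")
        self.bonus = bonus

        beta = 1.0 / consts.kT
        p = params
        self.allowed = np.zeros((N, N), dtype=bool)
        for i in range(N):
            for j in range(i + p.min_hairpin + 1, N):
                self.allowed[i, j] = p.pair_allowed(seq[i], seq[j])

        # Log Boltzmann weights for each loop term.
        self.lw_hp = np.full((N, N), NEG_INF)
        self.lw_stack = np.full((N, N), NEG_INF)
        for i in range(N):
            for j in range(i + p.min_hairpin + 1, N):
                if not self.allowed[i, j]:
                    continue
                self.lw_hp[i, j] = -beta * p.hairpin_penalty(j - i - 1)
                if j - i - 2 > p.min_hairpin and self.allowed[i + 1, j - 1]:
                    e = (p.stack_energies[(seq[i] + seq[j], seq[i + 1] + seq[j - 1])]
                         + bonus[i] + bonus[i + 1] + bonus[j - 1] + bonus[j])
                    self.lw_stack[i, j] = -beta * e
        self.lw_il = np.array([-beta * p.internal_bulge_penalty(s)
                               for s in range(2 * N + 1)])
        self.la2 = -beta * (p.multibranch_offset + p.multibranch_per_branch)
        self.lb = -beta * p.multibranch_per_branch
        self.lc = -beta * p.multibranch_per_unpaired

        self._fill_inside()
        self._outside_done = False

    # -- inside ---------------------------------------------------------
    def _fill_inside(self):
        N = self.N
        V = np.full((N, N), NEG_INF)
        WM = np.full((N, N), NEG_INF)
        lc, lb, la2 = self.lc, self.lb, self.la2

        for span in range(self.params.min_hairpin + 1, N):
            for i in range(0, N - span):
                j = i + span
                if self.allowed[i, j]:
                    terms = [self.lw_hp[i, j]]
                    if self.lw_stack[i, j] > NEG_INF and V[i + 1, j - 1] > NEG_INF:
                        terms.append(self.lw_stack[i, j] + V[i + 1, j - 1])
                    il = self._il_sum(V, i, j)
                    if il > NEG_INF:
                        terms.append(il)
                    mb = self._mb_sum(V, WM, i, j)
                    if mb > NEG_INF:
                        terms.append(la2 + mb)
                    V[i, j] = logsumexp(terms)
                # WM over i..j (filled for every span so shorter segments exist)
            # WM must be filled for all (i, j) with j - i == span, paired or not
            for i in range(0, N - span):
                j = i + span
                terms = []
                if WM[i, j - 1] > NEG_INF:
                    terms.append(WM[i, j - 1] + lc)
                ks = np.arange(i, j)
                vcol = V[ks, j]
                fin = vcol > NEG_INF
                if fin.any():
                    ksf = ks[fin]
                    vf = vcol[fin]
                    pre_empty = lc * (ksf - i)
                    terms.append(logsumexp(pre_empty + vf + lb))
                    prev = np.array([WM[i, k - 1] if k - 1 >= i else NEG_INF for k in ksf])
                    pfin = prev > NEG_INF
                    if pfin.any():
                        terms.append(logsumexp(prev[pfin] + vf[pfin] + lb))
                WM[i, j] = logsumexp(terms) if terms else NEG_INF

        # WM spans too short to hold a branch stay -inf (empty product handled
        # by the explicit all-unpaired terms elsewhere)
        self.V = V
        self.WM = WM

        W = np.zeros(N + 1)  # W[j+1] = exterior over 0..j; W[0] = empty prefix
        for j in range(N):
            terms = [W[j]]  # j unpaired
            ks = np.arange(0, j)
            if j >= 1:
                vcol = V[ks, j]
                fin = vcol > NEG_INF
                if fin.any():
                    terms.append(logsumexp(W[ks[fin]] + vcol[fin]))
            W[j + 1] = logsumexp(terms)
        self.W = W  # W[k] = log partition of prefix of length k

        Wr = np.zeros(N + 1)  # Wr[i] = log partition of suffix i..N-1
        for i in range(N - 1, -1, -1):
            terms = [Wr[i + 1]]
            ls = np.arange(i + 1, N)
            if ls.size:
                vrow = V[i, ls]
                fin = vrow > NEG_INF
                if fin.any():
                    terms.append(logsumexp(vrow[fin] + Wr[ls[fin] + 1]))
            Wr[i] = logsumexp(terms)
        self.Wr = Wr
        self.logQ = W[N]

    def _il_sum(self, V, i, j):
        """Internal/bulge contributions to V[i, j] (stack case excluded)."""
        ks = np.arange(i + 1, j - 1)
        ls = np.arange(i + 2, j)
        if ks.size == 0 or ls.size == 0:
            return NEG_INF
        sub = V[np.ix_(ks, ls)]
        sizes = (ks - i - 1)[:, None] + (j - 1 - ls)[None, :]
        total = sub + self.lw_il[sizes]
        mask = (ls[None, :] > ks[:, None]) & (sub > NEG_INF) & (sizes >= 1)
        if not mask.any():
            return NEG_INF
        return logsumexp(total[mask])

    def _mb_sum(self, V, WM, i, j):
        """Multibranch closing sum: last branch (k, l), >=1 branch before it."""
        ks = np.arange(i + 2, j - 1)
        ls = np.arange(i + 3, j)
        if ks.size == 0 or ls.size == 0:
            return NEG_INF
        sub = V[np.ix_(ks, ls)]
        wmpre = WM[i + 1, ks - 1][:, None]
        trail = self.lc * (j - 1 - ls)[None, :]
        total = wmpre + sub + self.lb + trail
        mask = (ls[None, :] > ks[:, None]) & (sub > NEG_INF) & (wmpre > NEG_INF)
        if not mask.any():
            return NEG_INF
        return logsumexp(total[mask])

    # -- outside --------------------------------------------------------
    def fill_outside(self):
        if self._outside_done:
            return
        N = self.N
        V, WM = self.V, self.WM
        lc, lb, la2 = self.lc, self.lb, self.la2
        Vout = np.full((N, N), NEG_INF)

        def wm_or_neg(a, b):
            return WM[a, b] if b >= a else NEG_INF

        for span in range(N - 1, self.params.min_hairpin, -1):
            for i in range(0, N - span):
                j = i + span
                if V[i, j] <= NEG_INF:
                    continue
                terms = [self.W[i] + self.Wr[j + 1]]  # exterior branch
                if i >= 1 and j <= N - 2 and self.lw_stack[i - 1, j + 1] > NEG_INF \
                        and Vout[i - 1, j + 1] > NEG_INF:
                    terms.append(Vout[i - 1, j + 1] + self.lw_stack[i - 1, j + 1])
                ilo = self._il_out(Vout, i, j)
                if ilo > NEG_INF:
                    terms.append(ilo)
                mbo = self._mb_out(Vout, i, j, wm_or_neg)
                if mbo > NEG_INF:
                    terms.append(mbo)
                Vout[i, j] = logsumexp(terms)
        self.Vout = Vout
        self._outside_done = True

    def _il_out(self, Vout, i, j):
        """(i, j) is the single branch of an internal/bulge loop closed by (p, q)."""
        N = self.N
        ps = np.arange(0, i)
        qs = np.arange(j + 1, N)
        if ps.size == 0 or qs.size == 0:
            return NEG_INF
        sub = Vout[np.ix_(ps, qs)]
        sizes = (i - ps - 1)[:, None] + (qs - j - 1)[None, :]
        total = sub + self.lw_il[sizes]
        mask = (sub > NEG_INF) & (sizes >= 1)
        if not mask.any():
            return NEG_INF
        return logsumexp(total[mask])

    def _mb_out(self, Vout, i, j, wm_or_neg):
        """(i, j) is one branch of a multiloop closed by (p, q); at least one
        more branch fills the flanks p+1..i-1 and j+1..q-1."""
        N = self.N
        ps = np.arange(0, i)
        qs = np.arange(j + 1, N)
        if ps.size == 0 or qs.size == 0:
            return NEG_INF
        sub = Vout[np.ix_(ps, qs)]
        if not np.any(sub > NEG_INF):
            return NEG_INF
        wmL = np.array([wm_or_neg(p + 1, i - 1) for p in ps])
        eL = self.lc * (i - 1 - ps)  # all-unpaired left flank
        wmR = np.array([wm_or_neg(j + 1, q - 1) for q in qs])
        eR = self.lc * (qs - 1 - j)
        with np.errstate(invalid="ignore"):
            filler = np.logaddexp(
                np.logaddexp(wmL[:, None] + wmR[None, :],
                             wmL[:, None] + eR[None, :]),
                eL[:, None] + wmR[None, :])
        total = sub + self.la2 + self.lb + filler
        mask = (sub > NEG_INF) & (filler > NEG_INF)
        if not mask.any():
            return NEG_INF
        return logsumexp(total[mask])


def _build_tables(seq: str, params: NearestNeighborParams,
                  consts: ThermoConstants | None = None,
                  bonus: np.ndarray | None = None) -> _InsideTables:
    consts = consts or ThermoConstants()
    return _InsideTables(clean_sequence(seq), params, consts, bonus)


def partition_function(seq: str, params: NearestNeighborParams,
                       consts: ThermoConstants | None = None,
                       bonus: np.ndarray | None = None,
                       ) -> tuple[PairProbabilityMatrix, float]:
    """Exact pair probabilities and ensemble free energy.

    Returns
    -------
    (PairProbabilityMatrix, float)
        P[i, j] is the Boltzmann probability of pair (i, j) over all
        pseudoknot-free structures; the float is the ensemble free energy
        -kT ln Q in kcal/mol (0 when only the open chain exists).
    """
    consts = consts or ThermoConstants()
    t = _build_tables(seq, params, consts, bonus)
    t.fill_outside()
    with np.errstate(invalid="ignore"):
        logP = t.V + t.Vout - t.logQ
    P = np.exp(np.where(np.isfinite(logP), logP, NEG_INF))
    P[~np.isfinite(logP)] = 0.0
    mat = PairProbabilityMatrix(t.N, P)
    mat.validate(tol=1e-9)
    return mat, float(-consts.kT * t.logQ)


# -- stochastic traceback ----------------------------------------------

class _Sampler:
    """Draws structures from the Boltzmann distribution by traceback through
    the inside tables.  Conditional distributions at each grammar state are
    cached, so repeated sampling is fast; option order is fixed
    (lexicographic) so identical seeds give identical ensembles."""

    def __init__(self, tables: _InsideTables):
        self.t = tables
        self._cache: dict[tuple, tuple[list, np.ndarray]] = {}

    def _options(self, state):
        if state in self._cache:
            return self._cache[state]
        t = self.t
        kind = state[0]
        opts: list[tuple] = []
        logs: list[float] = []
        if kind == "W":
            j = state[1]  # decompose prefix 0..j
            opts.append(("unpaired",))
            logs.append(t.W[j])
            for k in range(0, j):
                v = t.V[k, j]
                if v > NEG_INF:
                    opts.append(("branch", k))
                    logs.append(t.W[k] + v)
        elif kind == "V":
            i, j = state[1], state[2]
            opts.append(("hairpin",))
            logs.append(t.lw_hp[i, j])
            if t.lw_stack[i, j] > NEG_INF and t.V[i + 1, j - 1] > NEG_INF:
                opts.append(("stack",))
                logs.append(t.lw_stack[i, j] + t.V[i + 1, j - 1])
            for k in range(i + 1, j - 1):
                for l in range(k + 1, j):
                    if (k, l) == (i + 1, j - 1):
                        continue
                    v = t.V[k, l]
                    if v > NEG_INF:
                        opts.append(("internal", k, l))
                        logs.append(t.lw_il[(k - i - 1) + (j - 1 - l)] + v)
            for k in range(i + 2, j - 1):
                wmpre = t.WM[i + 1, k - 1]
                if wmpre <= NEG_INF:
                    continue
                for l in range(k + 1, j):
                    v = t.V[k, l]
                    if v > NEG_INF:
                        opts.append(("multi", k, l))
                        logs.append(t.la2 + wmpre + v + t.lb + t.lc * (j - 1 - l))
        elif kind == "WM":
            i, j = state[1], state[2]
            if t.WM[i, j - 1] > NEG_INF:
                opts.append(("unpaired",))
                logs.append(t.WM[i, j - 1] + t.lc)
            for k in range(i, j):
                v = t.V[k, j]
                if v <= NEG_INF:
                    continue
                opts.append(("branch_empty", k))
                logs.append(t.lc * (k - i) + v + t.lb)
                if k - 1 >= i and t.WM[i, k - 1] > NEG_INF:
                    opts.append(("branch_more", k))
                    logs.append(t.WM[i, k - 1] + v + t.lb)
        else:  # pragma: no cover
            raise AssertionError(kind)
        logs_arr = np.asarray(logs)
        total = logsumexp(logs_arr)
        cum = np.cumsum(np.exp(logs_arr - total))
        cum[-1] = 1.0
        result = (opts, cum)
        self._cache[state] = result
        return result

    def _choose(self, state, rng):
        opts, cum = self._options(state)
        return opts[int(np.searchsorted(cum, rng.random(), side="right"))]

    def sample_one(self, rng: np.random.Generator) -> SecondaryStructure:
        t = self.t
        pairs: set[tuple[int, int]] = set()
        stack: list[tuple] = [("W", t.N - 1)]
        while stack:
            state = stack.pop()
            kind = state[0]
            if kind == "W":
                j = state[1]
                while j >= 0:
                    choice = self._choose(("W", j), rng)
                    if choice[0] == "unpaired":
                        j -= 1
                    else:
                        k = choice[1]
                        pairs.add((k, j))
                        stack.append(("V", k, j))
                        j = k - 1
            elif kind == "V":
                i, j = state[1], state[2]
                choice = self._choose(state, rng)
                tag = choice[0]
                if tag == "hairpin":
                    pass
                elif tag == "stack":
                    pairs.add((i + 1, j - 1))
                    stack.append(("V", i + 1, j - 1))
                elif tag == "internal":
                    k, l = choice[1], choice[2]
                    pairs.add((k, l))
                    stack.append(("V", k, l))
                else:  # multi
                    k, l = choice[1], choice[2]
                    pairs.add((k, l))
                    stack.append(("V", k, l))
                    stack.append(("WM", i + 1, k - 1))
            else:  # WM
                i, j = state[1], state[2]
                while True:
                    choice = self._choose(("WM", i, j), rng)
                    tag = choice[0]
                    if tag == "unpaired":
                        j -= 1
                        continue
                    k = choice[1]
                    pairs.add((k, j))
                    stack.append(("V", k, j))
                    if tag == "branch_more":
                        j = k - 1
                        continue
                    break
        return SecondaryStructure(t.N, frozenset(pairs))


def stochastic_sample(seq: str, params: NearestNeighborParams,
                      consts: ThermoConstants | None = None,
                      bonus: np.ndarray | None = None,
                      n: int = 1000, seed: int | None = None,
                      source: str = "unrestrained") -> StructureEnsemble:
    """Draw ``n`` i.i.d. structures from the Boltzmann ensemble."""
    if n < 1:
        raise FoldingInputError(f"sample size must be >= 1, got {n}")
    t = _build_tables(seq, params, consts, bonus)
    sampler = _Sampler(t)
    rng = np.random.default_rng(seed)
    structures = [sampler.sample_one(rng) for _ in range(n)]
    return StructureEnsemble(structures, seed=seed, source=source)


def pair_frequencies(ens: StructureEnsemble) -> PairProbabilityMatrix:
    """Empirical pair probabilities: fraction of ensemble structures
    containing each pair."""
    if len(ens) == 0:
        raise FoldingInputError("empty ensemble")
    N = ens.length
    P = np.zeros((N, N))
    for s in ens:
        for i, j in s.pairs:
            P[i, j] += 1.0
    P /= len(ens)
    return PairProbabilityMatrix(N, P)


def mea_structure(P: PairProbabilityMatrix, gamma: float = 1.0,
                  min_hairpin: int = 3) -> SecondaryStructure:
    """Maximum-expected-accuracy structure.

    Maximizes  sum_pairs 2*gamma*P[i,j] + sum_unpaired (1 - p_paired(i))
    over pseudoknot-free structures by a Nussinov-style dynamic program.
    Ties resolve deterministically (unpaired preferred, then smallest k).
    """
    N = P.N
    q = P.unpaired_probability()
    prob = np.triu(P.P, k=1)
    best = np.full((N, N), 0.0)
    choice = np.full((N, N), -1, dtype=np.int64)  # -1: j unpaired; k: pair (k, j)
    for span in range(0, N):
        for i in range(0, N - span):
            j = i + span
            if i == j:
                best[i, j] = q[j]
                continue
            b = best[i, j - 1] + q[j]
            c = -1
            for k in range(i, j - min_hairpin):
                left = best[i, k - 1] if k - 1 >= i else 0.0
                inner = best[k + 1, j - 1] if k + 1 <= j - 1 else 0.0
                val = left + 2.0 * gamma * prob[k, j] + inner
                if val > b + 1e-13:
                    b = val
                    c = k
            best[i, j] = b
            choice[i, j] = c
    pairs = set()
    stack = [(0, N - 1)]
    while stack:
        i, j = stack.pop()
        while j > i:
            c = choice[i, j]
            if c == -1:
                j -= 1
            else:
                pairs.add((int(c), int(j)))
                if c + 1 <= j - 1:
                    stack.append((int(c) + 1, int(j) - 1))
                j = int(c) - 1
        # single position left: unpaired
    return SecondaryStructure(N, frozenset(pairs))
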