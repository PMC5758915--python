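"""SHAPE reactivity model: classification, estimation, simulation.

SHAPE probing reports per-nucleotide backbone flexibility.  The model
distinguishes three structural contexts with distinct reactivity
distributions: unpaired nucleotides, paired nucleotides at helix ends,
and paired nucleotides in helix interiors.  All three distributions peak
near zero with right tails; the unpaired distribution skews farthest
toward high reactivity, helix ends are intermediate, and helix interiors
are the least reactive.

A paired nucleotide i with partner j is classified as helix-interior only
when both flanking pairs (i-1, j+1) and (i+1, j-1) exist (the strict
flanking-pair rule; a lone pair has two helix-end nucleotides).

The module also contains the forward simulator used for synthetic data:
given a mixture of known conformations with populations, the observed
SHAPE profile is the population-weighted mean of per-structure draws —
the physics that makes ensemble reactivities ambiguous for any single
structure and that the refinement pipeline is designed to untangle.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

from .partition import StructureEnsemble
from .structure import SecondaryStructure

MISSING = -999.0  #: sentinel for "no data" in SHAPE files


class NucleotideClass(IntEnum):
    UNPAIRED = 0
    HELIX_END = 1
    HELIX_INTERIOR = 2


@dataclass
class ReactivityProfile:
    """Per-nucleotide normalized SHAPE reactivities with a missing-data mask.

    Values are unitless normalized reactivities (typically ~0 to ~2.5, may
    be slightly negative).  Masked positions are excluded from every
    statistic downstream.
    """

    values: np.ndarray
    missing_mask: np.ndarray | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.missing_mask is None:
            self.missing_mask = np.zeros(self.values.shape, dtype=bool)
        else:
            self.missing_mask = np.asarray(self.missing_mask, dtype=bool)
        if self.missing_mask.shape != self.values.shape:
            raise ValueError("missing_mask length differs from values length")

    def __len__(self) -> int:
        return len(self.values)

    @classmethod
    def all_missing(cls, length: int) -> "ReactivityProfile":
        return cls(np.full(length, MISSING), np.ones(length, dtype=bool))


@dataclass(frozen=True)
class ClassDistribution:
    """Reactivity density for one structural context: an exponential body
    (mode at 0, heavy right tail) plus Gaussian measurement noise, which
    allows slightly negative normalized values."""

    exp_mean: float
    noise_sd: float = 0.05

    @property
    def mean(self) -> float:
        return self.exp_mean

    def sample(self, size, rng: np.random.Generator) -> np.ndarray:
        return rng.exponential(self.exp_mean, size) + rng.normal(0.0, self.noise_sd, size)


@dataclass(frozen=True)
class ReactivityDistributions:
    """The three named context distributions.

    Defaults follow the qualitative ordering seen in probing compilations:
    mean(unpaired) > mean(helix_end) >= mean(helix_interior).
    """

    unpaired: ClassDistribution = ClassDistribution(0.9)
    helix_end: ClassDistribution = ClassDistribution(0.35)
    helix_interior: ClassDistribution = ClassDistribution(0.15)

    def __post_init__(self):
        if not (self.unpaired.mean > self.helix_end.mean >= self.helix_interior.mean):
            raise ValueError("class means must satisfy "
                             "unpaired > helix_end >= helix_interior")

    def by_class(self, cls: NucleotideClass) -> ClassDistribution:
        return (self.unpaired, self.helix_end, self.helix_interior)[int(cls)]

    @property
    def means(self) -> np.ndarray:
        return np.array([self.unpaired.mean, self.helix_end.mean,
                         self.helix_interior.mean])

    @classmethod
    def from_config(cls, cfg: dict) -> "ReactivityDistributions":
        def make(name):
            block = cfg.get(name, {})
            defaults = {"unpaired": 0.9, "helix_end": 0.35, "helix_interior": 0.15}
            return ClassDistribution(float(block.get("mean", defaults[name])),
                                     float(block.get("noise_sd", 0.05)))
        return cls(make("unpaired"), make("helix_end"), make("helix_interior"))


def classify(s: SecondaryStructure) -> np.ndarray:
    """Structural context of every nucleotide in one structure.

    Returns an int array of :class:`NucleotideClass` values.  A paired
    nucleotide is HELIX_INTERIOR iff both flanking pairs exist, else
    HELIX_END; everything else is UNPAIRED.
    """
    classes = np.full(s.length, int(NucleotideClass.UNPAIRED), dtype=np.int64)
    pairs = s.pairs
    for i, j in pairs:
        interior = ((i - 1, j + 1) in pairs) and ((i + 1, j - 1) in pairs)
        cls = NucleotideClass.HELIX_INTERIOR if interior else NucleotideClass.HELIX_END
        classes[i] = int(cls)
        classes[j] = int(cls)
    return classes


def class_frequencies(ens: StructureEnsemble) -> np.ndarray:
    """(N, 3) matrix of per-nucleotide class frequencies across an ensemble."""
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    N = ens.length
    freq = np.zeros((N, 3))
    for s in ens:
        cls = classify(s)
        for c in range(3):
            freq[cls == c, c] += 1.0
    return freq / len(ens)


def estimate_rcalc(ens: StructureEnsemble, dists: ReactivityDistributions,
                   mode: str = "expectation",
                   seed: int | None = None) -> ReactivityProfile:
    """Ensemble-estimated SHAPE reactivity (Rcalc) per nucleotide.

    ``expectation`` (default): the deterministic large-sample limit — for
    each nucleotide the class frequencies across the ensemble weighted by
    the class-distribution means.  ``montecarlo``: one random draw from the
    appropriate class distribution per nucleotide per sampled structure,
    averaged across structures.
    """
    if len(ens) == 0:
        raise ValueError("empty ensemble")
    if mode == "expectation":
        values = class_frequencies(ens) @ dists.means
    elif mode == "montecarlo":
        rng = np.random.default_rng(seed)
        N = ens.length
        acc = np.zeros(N)
        for s in ens:
            cls = classify(s)
            draw = np.empty(N)
            for c in range(3):
                idx = cls == c
                if idx.any():
                    draw[idx] = dists.by_class(NucleotideClass(c)).sample(
                        int(idx.sum()), rng)
            acc += draw
        values = acc / len(ens)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return ReactivityProfile(values)


def simulate_shape(mixture: list[tuple[SecondaryStructure, float]],
                   dists: ReactivityDistributions | None = None,
                   seed: int | None = None,
                   replicates: int = 50) -> ReactivityProfile:
    """Synthesize an observed SHAPE profile from a known structure mixture.

    Each conformation contributes per-nucleotide draws from its class
    distributions (one draw per replicate, averaged), and the observed
    profile is the population-weighted mean across conformations — the
    forward model of ensemble probing.
    """
    dists = dists or ReactivityDistributions()
    if not mixture:
        raise ValueError("mixture must contain at least one structure")
    pops = np.array([w for _, w in mixture], dtype=np.float64)
    if np.any(pops < 0):
        raise ValueError("populations must be non-negative")
    if abs(pops.sum() - 1.0) > 1e-6:
        raise ValueError(f"populations sum to {pops.sum():.6f}, expected 1")
    lengths = {s.length for s, _ in mixture}
    if len(lengths) != 1:
        raise ValueError("mixture structures must share one length")
    N = lengths.pop()
    rng = np.random.default_rng(seed)
    values = np.zeros(N)
    for (s, w) in mixture:
        cls = classify(s)
        acc = np.zeros(N)
        for _ in range(replicates):
            draw = np.empty(N)
            for c in range(3):
                idx = cls == c
                if idx.any():
                    draw[idx] = dists.by_class(NucleotideClass(c)).sample(
                        int(idx.sum()), rng)
            acc += draw
        values += w * acc / replicates
    return ReactivityProfile(values)
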