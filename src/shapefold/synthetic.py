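"""Synthetic study systems: designed sequences and planted ensembles.

These builders provide ground-truth systems for exercising the ensemble
pipeline: a designed bistable RNA whose two mutually exclusive hairpins
mimic a riboswitch-like conformational switch, and planted-partition
structure samples for validating the clustering stage.  SHAPE profiles
for these systems come from :func:`shapefold.reactivity.simulate_shape`,
the forward model that turns a structure mixture with populations into a
population-weighted reactivity profile.
"""

from __future__ import annotations

import numpy as np

from .partition import StructureEnsemble
from .structure import SecondaryStructure

#: 23-nt designed bistable sequence: a central strand (GCGGC) that can pair
#: with either the 5' arm or the 3' arm, forming two mutually exclusive
#: 5-bp hairpins of equal stability (A-rich loops avoid spurious pairs).
BISTABLE_SEQ = "GCCGC" + "AAAA" + "GCGGC" + "AAAA" + "GCCGC"


def bistable_system() -> tuple[str, SecondaryStructure, SecondaryStructure]:
    """The designed bistable RNA and its two ground-truth conformations.

    Conformation A pairs the 5' arm with the central strand; conformation
    B pairs the central strand with the 3' arm.  Both stems are 5 bp of
    Watson-Crick pairs with near-identical stack sums, so the unrestrained
    thermodynamic ensemble splits them roughly evenly.
    """
    seq = BISTABLE_SEQ
    struct_a = SecondaryStructure.from_pairs(len(seq),
                                             [(i, 13 - i) for i in range(5)])
    struct_b = SecondaryStructure.from_pairs(len(seq),
                                             [(9 + i, 22 - i) for i in range(5)])
    return seq, struct_a, struct_b


def planted_partition(sizes: tuple[int, ...] = (500, 300, 200),
                      helix_pairs: int = 6,
                      seed: int | None = 0,
                      ) -> tuple[StructureEnsemble, np.ndarray]:
    """Structure sample with known group memberships for clustering tests.

    Group g is built around a ``helix_pairs``-bp helix in its own region of
    a shared sequence length; each member randomly drops at most one of the
    helix pairs (``helix_pairs + 1`` variants per group), so within-group
    base-pair distances are <= 2 while between-group distances are >=
    2 * helix_pairs - 2.  The variant count per group mimics the graded
    within-conformation variability of a real Boltzmann sample.  Returns
    the ensemble and the 1-based group label per structure.
    """
    n_groups = len(sizes)
    region = 2 * helix_pairs + 4  # helix + loop per group
    length = n_groups * region
    rng = np.random.default_rng(seed)
    structures = []
    labels = []
    for g, size in enumerate(sizes):
        base = [(g * region + i, g * region + region - 1 - i)
                for i in range(helix_pairs)]
        for _ in range(size):
            drop = int(rng.integers(0, helix_pairs + 1))  # == helix_pairs: none
            pairs = [p for idx, p in enumerate(base) if idx != drop]
            structures.append(SecondaryStructure(length, frozenset(pairs)))
            labels.append(g + 1)
    return (StructureEnsemble(structures, seed=seed, source="planted"),
            np.array(labels, dtype=np.int64))
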