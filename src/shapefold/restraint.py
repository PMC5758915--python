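"""Pseudo-free-energy restraints from reactivity mismatch.

The refinement signal is the per-nucleotide discrepancy between the
measured SHAPE reactivity Rexp and the ensemble-estimated reactivity
Rcalc:

    dG_bonus_i = C * ln( (Rexp_i + Offset) / (Rcalc_i + Offset) )

C (kcal/mol) sets the energy scale of the restraint and Offset shifts the
ratio so that normalized reactivities at or below zero remain usable.  A
positive bonus (measured more reactive than estimated) penalizes pairing
of that nucleotide; a negative bonus promotes it; equal reactivities give
no restraint, so the thermodynamic prior stands wherever the model already
matches the experiment.  Missing-data positions receive bonus 0 for the
same reason.  The bonus vector feeds the folding engine, where each
base-pair stack collects the bonus of each of its four positions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reactivity import ReactivityProfile

#: default energy scale and offset, from grid-search calibration on
#: structured RNAs with known SHAPE profiles
DEFAULT_C = 0.5
DEFAULT_OFFSET = 1.1


@dataclass(frozen=True)
class RestraintParams:
    """Parameters of the reactivity-mismatch restraint.

    C : energy scale, kcal/mol (> 0).
    Offset : unitless shift added to both reactivities (> 0).
    epsilon : positivity floor applied to each shifted reactivity before
        the log, protecting against values below -Offset.
    """

    C: float = DEFAULT_C
    Offset: float = DEFAULT_OFFSET
    epsilon: float = 1e-4

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError(f"C must be > 0, got {self.C}")
        if self.Offset <= 0:
            raise ValueError(f"Offset must be > 0, got {self.Offset}")
        if self.epsilon <= 0:
            raise ValueError(f"epsilon must be > 0, got {self.epsilon}")


def compute_bonus(rexp: ReactivityProfile, rcalc: ReactivityProfile,
                  params: RestraintParams | None = None) -> np.ndarray:
    """Per-nucleotide pseudo-free-energy bonuses, kcal/mol.

    Positions masked as missing in either profile get bonus 0 (no
    restraint).  Each shifted reactivity is floored at ``params.epsilon``
    so the log argument stays positive and finite.
    """
    params = params or RestraintParams()
    if len(rexp) != len(rcalc):
        raise ValueError(f"profile lengths differ: {len(rexp)} vs {len(rcalc)}")
    num = np.maximum(rexp.values + params.Offset, params.epsilon)
    den = np.maximum(rcalc.values + params.Offset, params.epsilon)
    bonus = params.C * np.log(num / den)
    bonus[rexp.missing_mask | rcalc.missing_mask] = 0.0
    return bonus
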