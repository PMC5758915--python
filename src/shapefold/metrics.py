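"""Accuracy metrics and restraint-parameter calibration.

Structure accuracy is scored as sensitivity (fraction of reference pairs
found in the prediction) and positive predictive value (fraction of
predicted pairs found in the reference), optionally with the standard
one-position "slipped pair" allowance: pair (i, j) matches any of
(i, j), (i+1, j), (i-1, j), (i, j+1), (i, j-1).  Matching is greedy in
reference order and each pair can be consumed at most once, so slipped
matches are never double counted.

Calibration of the restraint parameters C and Offset is a two-dimensional
grid search (default 0.1 to 1.5 in steps of 0.1 on both axes, 225
combinations) maximizing the mean geometric-mean accuracy of
single-structure predictions over a training set, with a leave-one-out
jackknife to assess stability.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np

from .energy import ThermoConstants
from .reactivity import ReactivityProfile
from .structure import SecondaryStructure

_SLIP_OFFSETS = ((0, 0), (1, 0), (-1, 0), (0, 1), (0, -1))


@dataclass(frozen=True)
class AccuracyReport:
    """Sensitivity/PPV summary; undefined fractions are NaN (e.g. the
    sensitivity of an empty reference)."""

    sensitivity: float
    ppv: float
    matched_pairs: int

    @property
    def geometric_mean(self) -> float:
        return math.sqrt(self.sensitivity * self.ppv)


def _greedy_matches(source: frozenset, target: frozenset, slip: bool) -> int:
    """Number of pairs in ``source`` (iterated in sorted order) matched to a
    distinct pair of ``target``, with optional slip variants."""
    available = set(target)
    matched = 0
    for (i, j) in sorted(source):
        variants = [(i + di, j + dj) for di, dj in _SLIP_OFFSETS] if slip else [(i, j)]
        for v in variants:
            if v in available:
                available.remove(v)
                matched += 1
                break
    return matched


def sensitivity_ppv(predicted: SecondaryStructure, reference: SecondaryStructure,
                    slip: bool = True) -> AccuracyReport:
    """Score a predicted structure against a reference."""
    if predicted.length != reference.length:
        raise ValueError(f"structure lengths differ: {predicted.length} "
                         f"vs {reference.length}")
    found = _greedy_matches(reference.pairs, predicted.pairs, slip)
    correct = _greedy_matches(predicted.pairs, reference.pairs, slip)
    sens = found / len(reference.pairs) if reference.pairs else math.nan
    ppv = correct / len(predicted.pairs) if predicted.pairs else math.nan
    return AccuracyReport(sens, ppv, found)


def population_ddg(ratio_a: tuple[float, float], ratio_b: tuple[float, float],
                   consts: ThermoConstants | None = None) -> float:
    """Free-energy distance between two two-state population ratios.

    |RT ln(p/(1-p)) - RT ln(q/(1-q))| in kcal/mol — how far apart two
    equilibria are on the free-energy scale at temperature ``consts.T``.
    """
    consts = consts or ThermoConstants()
    for name, (x, y) in (("ratio_a", ratio_a), ("ratio_b", ratio_b)):
        if not (0 < x < 1 and 0 < y < 1):
            raise ValueError(f"{name}={x, y} is degenerate; populations must "
                             "lie strictly between 0 and 1")
    rt = consts.kT
    return abs(rt * math.log(ratio_a[0] / ratio_a[1])
               - rt * math.log(ratio_b[0] / ratio_b[1]))


def reactivity_rmsd(a: ReactivityProfile, b: ReactivityProfile) -> float:
    """Root-mean-square deviation over positions unmasked in both profiles."""
    if len(a) != len(b):
        raise ValueError(f"profile lengths differ: {len(a)} vs {len(b)}")
    ok = ~(a.missing_mask | b.missing_mask)
    if not ok.any():
        raise ValueError("no overlapping unmasked positions")
    d = a.values[ok] - b.values[ok]
    return float(np.sqrt(np.mean(d * d)))


# -- calibration --------------------------------------------------------

def default_grid() -> tuple[np.ndarray, np.ndarray]:
    """Default calibration grid: C and Offset each 0.1..1.5 step 0.1."""
    vals = np.round(np.arange(0.1, 1.5 + 1e-9, 0.1), 10)
    return vals.copy(), vals.copy()


@dataclass
class GridSearchResult:
    best_C: float
    best_Offset: float
    C_values: np.ndarray
    Offset_values: np.ndarray
    scores: np.ndarray  # (len(C_values), len(Offset_values)), NaN where failed
    skipped: list


def grid_search(dataset, C_values=None, Offset_values=None,
                **pipeline_kwargs) -> GridSearchResult:
    """Calibrate C and Offset on (sequence, Rexp, reference) triples.

    For every (C, Offset) combination the single-structure pipeline is run
    on each dataset entry and the geometric-mean accuracies are averaged;
    the maximizing combination is returned (ties resolve to smaller C,
    then smaller Offset).  Entries whose pipeline run fails are skipped
    with a warning and recorded in ``skipped``.  Additional keyword
    arguments are forwarded to the pipeline configuration (sample sizes,
    seeds, ...).
    """
    from .pipeline import RunConfig, run_pipeline
    from .restraint import RestraintParams

    if not dataset:
        raise ValueError("dataset must be non-empty")
    if C_values is None or Offset_values is None:
        dC, dO = default_grid()
        C_values = dC if C_values is None else np.asarray(C_values, dtype=float)
        Offset_values = dO if Offset_values is None else np.asarray(Offset_values,
                                                                    dtype=float)
    C_values = np.asarray(C_values, dtype=float)
    Offset_values = np.asarray(Offset_values, dtype=float)
    if C_values.size == 0 or Offset_values.size == 0:
        raise ValueError("C and Offset value lists must be non-empty")

    scores = np.full((C_values.size, Offset_values.size), np.nan)
    skipped: list = []
    best = (-np.inf, None, None)
    for ci, C in enumerate(C_values):
        for oi, Offset in enumerate(Offset_values):
            accs = []
            for entry_idx, (seq, rexp, ref) in enumerate(dataset):
                cfg = RunConfig(mode="single",
                                restraint=RestraintParams(C=float(C),
                                                          Offset=float(Offset)),
                                **pipeline_kwargs)
                try:
                    result = run_pipeline(seq, rexp, cfg)
                    rep = sensitivity_ppv(result.structure, ref, slip=True)
                    acc = rep.geometric_mean
                    if math.isnan(acc):
                        acc = 0.0
                    accs.append(acc)
                except Exception as exc:  # noqa: BLE001 - record and move on
                    warnings.warn(f"grid entry {entry_idx} failed at "
                                  f"C={C}, Offset={Offset}: {exc}")
                    skipped.append((entry_idx, float(C), float(Offset), str(exc)))
            if accs:
                mean_acc = float(np.mean(accs))
                scores[ci, oi] = mean_acc
                if mean_acc > best[0] + 1e-12:
                    best = (mean_acc, float(C), float(Offset))
    if best[1] is None:
        raise RuntimeError("every grid evaluation failed")
    return GridSearchResult(best[1], best[2], C_values, Offset_values,
                            scores, skipped)


def jackknife(dataset, C_values=None, Offset_values=None,
              **pipeline_kwargs) -> dict:
    """Leave-one-out stability of the grid-search optimum.

    Returns the per-subset optima, the full-data optimum, and the fraction
    of subsets agreeing with it.
    """
    if len(dataset) < 2:
        raise ValueError("jackknife needs at least 2 dataset entries")
    full = grid_search(dataset, C_values, Offset_values, **pipeline_kwargs)
    optima = []
    agree = 0
    for leave in range(len(dataset)):
        subset = [e for i, e in enumerate(dataset) if i != leave]
        res = grid_search(subset, C_values, Offset_values, **pipeline_kwargs)
        optima.append((res.best_C, res.best_Offset))
        if (res.best_C, res.best_Offset) == (full.best_C, full.best_Offset):
            agree += 1
    return {"optima": optima,
            "full": (full.best_C, full.best_Offset),
            "stability": agree / len(dataset)}
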