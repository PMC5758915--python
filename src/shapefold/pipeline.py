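"""The full refinement pipeline: thermodynamics -> restraints -> ensemble.

One run executes, exactly once:

1. unrestrained partition function;
2. a large stochastic sample (default 10 000 structures) of the
   unrestrained Boltzmann ensemble;
3. per-nucleotide estimated reactivities (Rcalc) from that sample;
4. pseudo-free-energy bonuses from the Rexp/Rcalc mismatch, and a second,
   restrained partition function;

then either

5. the maximum-expected-accuracy structure (single-structure mode), or
6. a restrained sample (default 1000 structures), 7. clustering with
   automatic selection of the number of conformations, and 8. centroid
   structures with populations (ensemble mode).

Refinement is single-pass by construction: there is no option to feed the
restrained ensemble back into step 3, because iterating over-interprets
the mapping data and pulls the ensemble away from the thermodynamic
prior, degrading accuracy.

Each sampling step draws a fresh sample with its own seed derived
deterministically from the master seed, so identical configurations give
identical outputs.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .cluster import (DEFAULT_K_MAX, DEFAULT_MIN_POPULATION, EnsembleModel,
                      build_ensemble_model, cluster_structures)
from .energy import NearestNeighborParams, ThermoConstants, load_params
from .partition import (PairProbabilityMatrix, StructureEnsemble,
                        mea_structure, partition_function, stochastic_sample)
from .reactivity import (ReactivityDistributions, ReactivityProfile,
                         estimate_rcalc)
from .restraint import RestraintParams, compute_bonus
from .structure import SecondaryStructure

logger = logging.getLogger("shapefold")


@dataclass
class RunConfig:
    """Resolved configuration of one pipeline run."""

    mode: str = "ensemble"  # "ensemble" | "single"
    restraint: RestraintParams = field(default_factory=RestraintParams)
    reactivity_sample: int = 10_000  # step-2 sample used to estimate Rcalc
    cluster_sample: int = 1_000      # step-6 sample that is clustered
    k_max: int = DEFAULT_K_MAX
    min_population: float = DEFAULT_MIN_POPULATION
    seed: int = 1
    temperature: float = 310.15
    gamma: float = 1.0               # MEA pair weight (single mode)
    rcalc_mode: str = "expectation"  # "expectation" | "montecarlo"
    params_source: str = "default"
    dists: ReactivityDistributions = field(default_factory=ReactivityDistributions)

    def __post_init__(self):
        if self.mode not in ("ensemble", "single"):
            raise ValueError(f"mode must be 'ensemble' or 'single', got {self.mode!r}")
        if self.reactivity_sample < 1 or self.cluster_sample < 1:
            raise ValueError("sample sizes must be >= 1")

    def child_seeds(self) -> dict[str, int]:
        """Deterministic per-stage seeds derived from the master seed
        (kept below 2**31)."""
        state = np.random.SeedSequence(self.seed).generate_state(3)
        names = ("reactivity_sample", "rcalc_draws", "cluster_sample")
        return {n: int(v & 0x7FFFFFFF) for n, v in zip(names, state)}

    def summary(self) -> dict:
        d = {k: v for k, v in asdict(self).items() if k != "dists"}
        d["restraint"] = {"C": self.restraint.C, "Offset": self.restraint.Offset,
                          "epsilon": self.restraint.epsilon}
        d["dists"] = {name: {"mean": dist.mean, "noise_sd": dist.noise_sd}
                      for name, dist in (("unpaired", self.dists.unpaired),
                                         ("helix_end", self.dists.helix_end),
                                         ("helix_interior", self.dists.helix_interior))}
        d["seeds"] = self.child_seeds()
        return d


@dataclass
class PipelineResult:
    """Everything one pipeline run computed."""

    mode: str
    structure: SecondaryStructure | None  # single mode
    model: EnsembleModel | None           # ensemble mode
    rcalc: ReactivityProfile
    bonus: np.ndarray
    unrestrained_pair_probs: PairProbabilityMatrix
    restrained_pair_probs: PairProbabilityMatrix
    unrestrained_free_energy: float
    restrained_free_energy: float
    config: RunConfig


def run_pipeline(seq: str, rexp: ReactivityProfile | None,
                 config: RunConfig | None = None,
                 params: NearestNeighborParams | None = None) -> PipelineResult:
    """Run the refinement pipeline on one sequence.

    ``rexp`` may be None or all-missing, in which case all bonuses are
    zero and the run reduces to the unrestrained control (thermodynamic
    sampling followed by clustering).
    """
    config = config or RunConfig()
    params = params or load_params(config.params_source)
    consts = ThermoConstants(T=config.temperature)
    seeds = config.child_seeds()
    stage = "partition_function(unrestrained)"
    try:
        t0 = time.perf_counter()
        P0, fe0 = partition_function(seq, params, consts)
        logger.info("step 1 %s done in %.2fs (free energy %.3f kcal/mol)",
                    stage, time.perf_counter() - t0, fe0)

        stage = "stochastic_sample(reactivity)"
        t0 = time.perf_counter()
        ens0 = stochastic_sample(seq, params, consts, n=config.reactivity_sample,
                                 seed=seeds["reactivity_sample"],
                                 source="unrestrained")
        logger.info("step 2 %s: %d structures, seed %d, %.2fs", stage,
                    len(ens0), seeds["reactivity_sample"], time.perf_counter() - t0)

        stage = "estimate_rcalc"
        rcalc = estimate_rcalc(ens0, config.dists, mode=config.rcalc_mode,
                               seed=seeds["rcalc_draws"])

        stage = "compute_bonus"
        if rexp is None:
            rexp = ReactivityProfile.all_missing(len(seq))
        if len(rexp) != len(rcalc):
            raise ValueError(f"SHAPE profile length {len(rexp)} does not match "
                             f"sequence length {len(rcalc)}")
        bonus = compute_bonus(rexp, rcalc, config.restraint)

        stage = "partition_function(restrained)"
        t0 = time.perf_counter()
        P1, fe1 = partition_function(seq, params, consts, bonus=bonus)
        logger.info("step 4 %s done in %.2fs (free energy %.3f kcal/mol)",
                    stage, time.perf_counter() - t0, fe1)

        if config.mode == "single":
            stage = "mea_structure"
            structure = mea_structure(P1, gamma=config.gamma,
                                      min_hairpin=params.min_hairpin)
            return PipelineResult("single", structure, None, rcalc, bonus,
                                  P0, P1, fe0, fe1, config)

        stage = "stochastic_sample(cluster)"
        t0 = time.perf_counter()
        ens1 = stochastic_sample(seq, params, consts, bonus=bonus,
                                 n=config.cluster_sample,
                                 seed=seeds["cluster_sample"],
                                 source="restrained")
        logger.info("step 6 %s: %d structures, seed %d, %.2fs", stage,
                    len(ens1), seeds["cluster_sample"], time.perf_counter() - t0)

        stage = "cluster_structures"
        clusters = cluster_structures(ens1, k_max=config.k_max,
                                      seed=seeds["cluster_sample"])
        stage = "build_ensemble_model"
        model = build_ensemble_model(ens1, clusters, pair_probs=P1,
                                     min_population=config.min_population)
        logger.info("steps 7-8: %d conformations, populations %s",
                    len(model.conformations),
                    np.round(model.populations, 3).tolist())
        return PipelineResult("ensemble", None, model, rcalc, bonus,
                              P0, P1, fe0, fe1, config)
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage}: {exc}") from exc


def save_results(result: PipelineResult, seq: str, outdir: str | Path,
                 name: str = "run") -> Path:
    """Write structures, populations, entropy and a checksummed manifest.

    Returns the manifest path.  Partial outputs are removed if writing
    fails midway.
    """
    from . import io as sio

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        extras: dict = {"mode": result.mode,
                        "ensemble_free_energy_unrestrained": result.unrestrained_free_energy,
                        "ensemble_free_energy_restrained": result.restrained_free_energy}
        if result.mode == "single":
            ct = outdir / f"{name}_mea.ct"
            db = outdir / f"{name}_mea.db"
            sio.write_ct(ct, seq, result.structure, title=f"{name} MEA")
            sio.write_dotbracket(db, seq, result.structure, name=f"{name}_mea")
            written += [ct, db]
        else:
            model = result.model
            extras["shannon_entropy"] = model.shannon_entropy
            extras["conformations"] = []
            for idx, conf in enumerate(model.conformations, start=1):
                ct = outdir / f"{name}_conf{idx}.ct"
                db = outdir / f"{name}_conf{idx}.db"
                sio.write_ct(ct, seq, conf.centroid,
                             title=f"{name} conformation {idx} "
                                   f"population {conf.population:.3f}")
                sio.write_dotbracket(db, seq, conf.centroid,
                                     name=f"{name}_conf{idx}")
                written += [ct, db]
                extras["conformations"].append(
                    {"index": idx, "population": conf.population,
                     "flagged_low_population": conf.flagged,
                     "ct": ct.name, "dotbracket": db.name})
            if model.cluster_result is not None:
                extras["ch_scores"] = {str(k): v for k, v
                                       in model.cluster_result.ch_scores.items()}
        manifest = outdir / f"{name}_manifest.json"
        sio.write_manifest(manifest, result.config.summary(), written, extras)
        return manifest
    except Exception:
        for f in written:
            f.unlink(missing_ok=True)
        raise
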