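# shapefold

**RNA secondary-structure ensembles from SHAPE probing data.**

Most RNAs do not fold into a single structure: riboswitches, mRNAs and many
regulatory RNAs populate several conformations at equilibrium, and chemical
probing experiments such as SHAPE report a *population-weighted average*
over that ensemble. Methods that force the data onto one structure
misinterpret exactly the sequences where structure matters most.

`shapefold` is for structural-RNA researchers who have a sequence and a
per-nucleotide normalized SHAPE profile and want to know **which
conformations the molecule populates and in what proportions**. It predicts
an ensemble model — centroid structures with populations, per-cluster pair
probabilities and the Shannon entropy of base pairing — from a single
sequence plus one reactivity profile.

## Method

The pipeline refines a thermodynamic Boltzmann ensemble so that its
*estimated* reactivities match the *measured* ones:

1. **Unrestrained partition function.** Over all pseudoknot-free
   structures $s$, $Q=\sum_s e^{-\Delta G(s)/kT}$ under a nearest-neighbor
   energy model, giving base-pair probabilities $P_{i,j}$.
2. **Stochastic sampling.** 10 000 structures drawn with Boltzmann
   probabilities by traceback.
3. **Reactivity estimation.** Each nucleotide in each sampled structure is
   one of three states — unpaired, paired at a helix end, paired in a helix
   interior — each with its own reactivity distribution. The estimate
   $R^{calc}_i$ is the ensemble average of the state means.
4. **Pseudo-free-energy restraint.** The mismatch between measured and
   estimated reactivity becomes a per-nucleotide energy term,

   $$\Delta G_{bonus,i} = C \,\ln\!\frac{R^{exp}_i + \textit{Offset}}{R^{calc}_i + \textit{Offset}},$$

   with defaults $C=0.5$ kcal/mol and $\textit{Offset}=1.1$ from grid-search
   calibration. The bonus is added to the free energy of every base-pair
   stack containing nucleotide $i$ (helix-interior nucleotides feel it
   twice, helix-end nucleotides once), and the partition function is
   recomputed once — a single pass; iterating degrades accuracy.
5. **Ensemble model.** 1000 structures sampled from the restrained
   ensemble are clustered (binary pair-indicator vectors; number of
   clusters chosen by the Calinski–Harabasz index). Each cluster yields a
   centroid (all pairs with within-cluster frequency > 0.5) and a
   population (its share of the sample). Ensemble diversity is summarized
   by the mean Shannon entropy per nucleotide,
   $S = -\sum_{i<j} P_{i,j}\log_{10} P_{i,j}\,/\,N$.
   A single-structure mode returns the maximum-expected-accuracy (MEA)
   structure from the restrained pair probabilities instead.

The dynamic programs (inside/outside partition function, stochastic
traceback, MEA) are validated against exhaustive enumeration of all
structures on short sequences, to machine precision.

## Worked example

A designed 23-nt bistable RNA can pair its central strand with either the
5′ or the 3′ arm — two mutually exclusive hairpins of equal stability. We
simulate SHAPE data from a 70/30 mixture of the two conformations and ask
the pipeline to recover the ensemble:

```bash
python examples/fold_bistable_ensemble.py
```

```text
sequence (23 nt): GCCGCAAAAGCGGCAAAAGCCGC
conformation A (70%):     (((((....))))).........
conformation B (30%):     .........(((((....)))))

recovered ensemble:
  1. population 0.715  (((((....))))).........  closest to A (accuracy 1.00)
  2. population 0.280  .........(((((....)))))  closest to B (accuracy 1.00)
  3. population 0.003  .((((....))))..........  closest to A (accuracy 0.89)  [below 2% population floor]
  4. population 0.002  ..........((((....)))).  closest to B (accuracy 0.89)  [below 2% population floor]
Shannon entropy per nucleotide: 0.0553
```

The two substantive clusters reproduce the generating structures exactly,
and the recovered 71.5/28.0 split sits within a small fraction of $kT$ of
the true 70/30 ratio on the free-energy scale
($RT\,\lvert\ln\frac{p/(1-p)}{0.7/0.3}\rvert \approx 0.06$ kcal/mol,
versus the $2kT \approx 1.23$ kcal/mol band of thermally accessible
ratios). Without SHAPE data the same pipeline returns an uninformative
~50/50 split. The other examples demonstrate the forward simulator
(`simulate_shape_profile.py`), accuracy scoring with slipped-pair
tolerance (`evaluate_prediction.py`), and restraint calibration
(`calibrate_restraint.py`).

The same operations are available from the shell:

```bash
shapefold fold seq.fa --shape seq.shape --out results/
shapefold simulate a.db b.db --populations 0.7,0.3 --out sim.shape
shapefold evaluate predicted.ct reference.ct
shapefold calibrate dataset.yaml
```

## Layout

- `src/shapefold/energy.py` — nearest-neighbor parameters, loop-decomposition energies
- `src/shapefold/partition.py` — partition function, pair probabilities, sampling, MEA
- `src/shapefold/exhaustive.py` — brute-force enumeration oracle for short sequences
- `src/shapefold/reactivity.py` — three-state classification, Rcalc, SHAPE simulator
- `src/shapefold/restraint.py` — the reactivity-mismatch pseudo-free energy
- `src/shapefold/cluster.py` — clustering, centroids, populations, Shannon entropy
- `src/shapefold/metrics.py` — sensitivity/PPV, population ΔΔG, calibration
- `src/shapefold/io.py`, `pipeline.py`, `cli.py` — formats, orchestration, CLI
- `src/shapefold/synthetic.py` — designed bistable system, planted partitions
- `docs/methods.md` — model assumptions, parameter choices, limitations
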