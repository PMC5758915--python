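# Methods

This note documents the models, parameter choices and numerical decisions
behind `shapefold`, and what the tests do and do not establish.

## Energy model

Folding free energies come from a compact nearest-neighbor model:

- **Stacks.** A 6×6 table of free-energy increments, keyed by the outer
  pair (i, j) and inner pair (i+1, j−1), over the canonical pairs AU, UA,
  GC, CG, GU, UG. The shipped defaults (`src/shapefold/data/
  default_params.txt`) are representative 37 °C Watson–Crick/wobble values
  (GC-rich stacks near −3.3 kcal/mol, AU-rich near −1 kcal/mol).
- **Hairpin loops.** `base + log_coeff · ln(n / min_hairpin)` for n
  unpaired nucleotides (defaults 5.4 + 1.08·ln(n/3) kcal/mol).
- **Internal/bulge loops.** `base + log_coeff · ln(max(n, 1))` on the total
  unpaired count (defaults 3.2 + 1.08·ln n).
- **Multibranch loops.** Linear: offset + per-branch (counting the closing
  helix) + per-unpaired (defaults 3.4 / 0.4 / 0.1 kcal/mol).
- Dangling ends, coaxial stacking, terminal-AU penalties and
  sequence-dependent loop bonuses are deliberately omitted; the parameter
  file is the extension point. The minimum hairpin size is 3 and
  pseudoknots are outside the structure space.

The algorithm — not the parameter set — is the point of the package, so
the model is chosen for being *structurally faithful* (the same loop
classes the full nearest-neighbor model uses) while staying small enough
to ship, inspect and randomize in tests. Absolute free energies and
benchmark-level accuracy against published ensembles are **not** expected
to match tools carrying the complete experimental parameter tables.

Temperature defaults to 310.15 K; the thermal energy kT = RT ≈ 0.616
kcal/mol at 310 K. The population ΔΔG helper takes temperature explicitly.

## Partition function and sampling

Inside/outside dynamic programming over the loop decomposition, entirely
in log space (`logsumexp`), so no rescaling is needed and sequences of
hundreds of nucleotides cannot overflow. Internal loops are not
size-capped, which makes the recursion O(N⁴); the intended scale is the
tens-to-low-hundreds of nucleotides where multi-conformation analysis is
practiced. Restraint bonuses enter exactly where stacks are scored: the
stack term for (i, j) over (i+1, j−1) carries the bonuses of its four
positions, making the dynamic program provably consistent with the
loop-decomposition evaluator (tested identity).

Stochastic sampling is exact traceback through the inside tables. The
conditional distribution at each grammar state is cached with a fixed
(lexicographic) option order, so sampling is fast and a seed fully
determines the ensemble. Each pipeline stage draws a fresh sample with its
own seed derived from the master seed via `SeedSequence`; samples are
never reused across stages.

The MEA structure maximizes Σ 2γ·P(i,j) + Σ (1 − p_paired(i)) by a
Nussinov-style recursion; γ defaults to 1 and is exposed. Ties prefer
unpaired, then the smallest opening index, so output is deterministic.

**Verification route.** `exhaustive.py` enumerates every pseudoknot-free
structure of short sequences and Boltzmann-weights them with
`structure_energy`. Pair probabilities, ensemble free energies, MEA scores
and sampled frequencies are all checked against this independent oracle
(machine precision for the DPs; binomial/chi-square bands for the
sampler).

## Reactivity model

Three structural states per nucleotide: unpaired, helix end, helix
interior. A paired nucleotide is helix-interior only when **both**
flanking pairs exist (strict rule; a lone pair contributes two helix-end
nucleotides, and a 1-nt bulge interrupts interior status). This convention
is one of several defensible readings of "helix end"; it is applied
consistently in classification, simulation and estimation, which is what
the refinement requires.

Each state has a configurable reactivity distribution. Defaults are an
exponential body plus Gaussian noise (σ = 0.05, allowing slightly negative
normalized values), with means 0.9 (unpaired), 0.35 (helix end), 0.15
(interior): all three peak near zero, the unpaired distribution skews
farthest right, helix ends are intermediate — the qualitative shape seen
in probing compilations of structured RNAs. Only the state means enter the
default (expectation-mode) estimate of R^calc, so users with fitted
empirical histograms can substitute their own means/samplers in config.
Monte-Carlo mode (one draw per nucleotide per sampled structure, averaged)
is retained and converges to expectation mode by the law of large numbers
(tested).

The forward simulator generates a profile for a known mixture as the
population-weighted mean of per-structure draws. It emulates ensemble
averaging, normalization-scale reactivities and missing data, but **not**
sequence-dependent reagent bias, adduct-detection artifacts, correlated
noise along the backbone, or tertiary-contact protection. Passing
recovery tests on simulated data therefore demonstrates the machinery is
self-consistent, not that field data of arbitrary quality will yield the
same accuracy.

## Restraint

ΔG_bonus,i = C·ln((R^exp_i + Offset)/(R^calc_i + Offset)), C = 0.5
kcal/mol, Offset = 1.1 by default. Both shifted reactivities are floored
at ε = 1e−4 before the log so reactivities below −Offset (possible under
some normalizations) stay finite; ε is configurable. Missing-data
positions get bonus 0 — no restraint means the thermodynamic prior stands,
the same behavior as a perfect Rexp/Rcalc match. Refinement is single-pass
by construction (no iteration option): feeding the restrained ensemble
back into reactivity estimation over-interprets the data and demonstrably
degrades single-structure accuracy, so the pipeline hard-codes one pass.

## Clustering and the ensemble model

Sampled structures are embedded as binary pair-indicator vectors; squared
Euclidean distance in that space equals the base-pair (symmetric
difference) distance, the field's standard metric. Partitions for k =
2..k_max (default 10) are computed with seeded k-means on the indicator
vectors and scored by the Calinski–Harabasz index; the maximizing k wins.
k-means on binary indicators minimizes exactly the within-cluster
base-pair dispersion that CH measures, and the library implementation is
deterministic given a seed. Fallbacks to a single cluster: fewer than two
distinct structures, zero dispersion, or best CH below a configurable
floor (default 0, i.e. disabled).

A caveat discovered while validating on planted data: when a sample
contains only a handful of distinct structures, CH degenerates — every
distinct structure becomes its own zero-dispersion cluster and CH grows
without bound in k. Real Boltzmann samples of non-trivial sequences carry
many low-frequency variants per conformation, which keeps within-cluster
dispersion positive; the planted-partition generator mimics this by
giving each group more variants than k_max.

Centroids take every pair with within-cluster frequency > 0.5 (strict);
marginally conflicting majority pairs are admitted in order of descending
frequency (ties lexicographic) and later conflicts dropped, so centroids
are always legal structures. Populations are cluster shares of the
sample; clusters below 2 % of the sample are reported but flagged as low
population. Duplicates in the sample are kept — they carry the population
weight. For evaluation against known references, multiple clusters whose
centroids match the same reference at ≥ 80 % geometric-mean accuracy are
treated as one conformation and their populations pooled; centroids
matching nothing are labeled "other".

Shannon entropy is −Σ_{i<j} P_{i,j} log₁₀ P_{i,j} / N with 0·log 0 = 0,
computed on the exact restrained pair-probability matrix when available.

## Calibration

C and Offset are calibrated by a two-dimensional grid search, 0.1–1.5 in
steps of 0.1 on both axes (225 combinations), maximizing mean
geometric-mean accuracy of single-structure predictions over a training
set; ties resolve toward the smaller C then smaller Offset. A
leave-one-out jackknife reports the fraction of subsets reproducing the
full-data optimum. Grid search accepts pipeline keyword overrides (sample
sizes, seeds); the documentation examples use reduced sample sizes, and
the accuracy surface on easy fixtures is typically a flat plateau at 1.0.

## Accuracy scoring

Sensitivity = matched reference pairs / reference pairs; PPV = matched
predicted pairs / predicted pairs; a pair (i, j) matches (i, j), (i±1, j)
or (i, j±1) when slip tolerance is on. Matching is greedy in sorted pair
order and consumes the matched partner, so one predicted pair can satisfy
at most one reference pair. Undefined fractions (empty reference or empty
prediction) are NaN, never 0, so they cannot silently deflate averages;
the grid search maps NaN accuracy to 0 explicitly.

## Problem sizes and statistical checks

Default pipeline sizes are 10 000 structures for reactivity estimation and
1000 for clustering. Tests exercise the identical code paths at reduced
sizes (hundreds to a few thousand samples, sequences of 8–30 nt for oracle
comparisons, 50 000 draws for sampler fidelity) — sizes chosen so the
exhaustive oracle stays exact and sampling noise stays well inside the
asserted bands. Sampler fidelity uses a 4-standard-error band where the
normal approximation is valid (expected count ≥ 10) and an exact binomial
tail test at the matching two-sided 4σ level for rare structures, plus a
pooled chi-square at α = 0.01.

## Known limitations

- No pseudoknots, by construction of the structure space.
- Simplified energy parameters: relative, not literature-grade absolute,
  free energies; conclusions about specific natural RNAs require the full
  experimental parameter tables.
- O(N⁴) internal-loop sums: exact but not intended for transcripts of
  thousands of nucleotides.
- Three reactivity states; non-canonical pairs with distinctive
  reactivities (G–G, A–A) are not separately modeled.
- The default reactivity distributions are parametric stand-ins shaped to
  the qualitative form of probing data, not fits to a training corpus;
  the config path for substituting fitted distributions is the supported
  route for quantitative work.
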