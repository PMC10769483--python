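# Methods

## Competitive-occupancy model

All potency values are interpreted through a Langmuir-type competitive
binding model. For `n` inhibitors at concentrations `I_j` (nM) with
affinities `K_ij` (nM) against kinase `i`, the cumulative fractional
occupancy is

    I_T = S / (1 + S),   S = Σ_j I_j / K_ij

reported as a percent ("activity"). The model deliberately ignores ATP
competition, kinase depletion and binding kinetics: it is a pure
fractional-occupancy approximation, adequate for ranking mixtures by
target engagement but not for kinetic or cellular-phenotype
predictions. Occupancies are additive on the `S` scale, which gives two
useful exact identities used throughout the package and its tests:

* scaling all concentrations by a common factor scales `S` by the same
  factor, so dilution to a threshold has a closed form;
* the equivalent combination affinity `K_eq = (1/f − 1)·ΣI_j`
  (`f = I_T/100`) is invariant under fixed-ratio rescaling and reduces
  to the component `K` for a single compound. For an equimolar mixture
  `K_eq = n / Σ(1/K_j)` — e.g. single-compound EC50s of 82 nM, 4.6 µM
  and 1.8 µM pool to 231 nM.

K_d, K_i and apparent K_d values are treated equivalently. Affinities
are mapped to a common activity scale at a configurable reference
concentration (default 1000 nM = 1 µM): `activity = 100·(ref/K)/(1 +
ref/K)`, inverse `K = ref·(100/a − 1)`. The reference frame is an input
standardization only; mixture arithmetic runs on (pseudo-)affinities.

**Missing data.** Unmeasured compound–kinase pairs are treated as "no
detectable binding": activity 0, affinity +∞. The kinase still belongs
to the off-target universe, so its zero activity contributes mass to
the lowest histogram bin. Sparse screening matrices therefore bias
scores optimistically — an unmeasured potent off-target looks inert.

**Single-concentration screening data.** Percent-displacement panels
(PKIS2-style, 0–100 at a stated screening concentration) are converted
to pseudo-affinities by inverting the occupancy equation; activities of
exactly 100 are clamped to 99.995 first (100% would map to K = 0).
Because single-point values near the 90% threshold are imprecise and
the inversion amplifies that imprecision into fold-level concentration
errors, mixtures built on activity-kind matrices are kept equimolar and
concentration optimization is skipped for them.

## Penalty distributions

The penalty distribution encodes which off-target activity ranges cost
how much. It is a left-skewed probability distribution on the 0–100%
activity axis with mode at 100%. Two shapes are supported:

* **Poisson left tail** — counts `k ~ Poisson(µ)` with `k ≤ µ` are
  mapped to activities `x = 100 − (µ − k)`, i.e. one activity percent
  per count with the mode pinned at 100; draws mapping below 0 are
  discarded. The source description does not fix this count→activity
  mapping; the unit-scale choice is adopted because it reproduces the
  documented preset widths — tight (µ = 200, σ ≈ 14) fades out near
  50% activity, medium (µ = 700, σ ≈ 26.5) reaches ≈ 20%, broad
  (µ = 1200, σ ≈ 34.6) spans the full range.
* **Beta(α, β)** scaled to [0, 100]; left-skewed whenever α > 1 and
  α > β.

Distributions are realized by Monte-Carlo sampling (default 100,000
draws — small enough to be cheap, large enough that bin-level
Monte-Carlo noise is ~10⁻³), binned at 5% into 20 bins ([0,5) … [90,95),
final bin [95,100] closed), then an additional *high off-target penalty*
mass (default 0.1, recommended up to 0.3 for multi-target runs) is added
to the [95,100] bin and the vector renormalized to sum 1. The extra mass
compensates for the activity scale's compression of large affinity
differences near saturation (52 nM and 5.2 pM both bin at ≥ 95%). The
whole penalty is resampled for every technical replicate.

## Off-target distribution and JSD score

At the mixture concentrations needed for threshold on-target activity,
each off-target kinase's activity becomes the mean of a Gaussian with
variance 2.5 (matching the 5% bin width); each Gaussian is sampled 100
times, samples are clipped — not reflected or discarded — to [0, 100]
so every kinase keeps equal weight, pooled, and binned at 5%.

Selectivity is the Jensen–Shannon *distance* (square root of the
divergence, base-2 logarithms so the range is exactly [0, 1]) between
the off-target distribution and the penalty distribution. 1 means no
overlap (maximally selective); 0 means identical distributions. An
empty off-target universe scores 1 by definition, and a score of
exactly 1 emits a warning, since it may just mean the penalty is too
narrow for the data.

## Pipeline

1. **Pool.** Compounds with activity ≥ threshold (default 90%) at the
   reference frame against ≥ 1 target (K ≤ 111 nM at 1 µM). Multi-target
   pools deliberately admit compounds potent at only one target — such a
   compound can anchor a combination even though it is useless alone.
2. **Enumerate.** All subsets of 1..max_i pool compounds; a subset is
   kept only if cumulative activity can reach the threshold at *every*
   target with each component dosed at the concentration cap (max_conc
   if set, else the reference concentration). Because occupancy is
   monotone in every concentration, dosing all components at the cap is
   the exact existence check.
3. **Dilute.** Mixtures are scaled by R2 steps (default 1.1) so every
   target sits within one R2 step above the threshold; mixtures starting
   below threshold are scaled up, with max_conc the only feasibility
   limit. Smaller R2 scores more accurately (a compound dosed to 92%
   rather than 90% looks artificially less selective).
4. **Optimize.** Hill climbing: each round generates both orientations
   of the R1-fold variation (default 5) for every unordered pair of
   components, clamps to [min_conc, max_conc], re-dilutes each candidate
   to threshold and rescores all of them under one shared noise seed;
   the best candidate replaces the incumbent until no candidate improves
   the score by more than 1e-6. Both orientations (2·C(i,2) candidates
   per round) are generated to avoid directional search bias. One
   scoring seed is used per (combination, replicate) for the entire
   climb: comparisons within and across rounds are then paired, the
   incumbent score is provably non-decreasing, and rescoring the
   returned mixture reproduces its stored score exactly. Ties break by
   lower total concentration, then lexicographic order.
5. **Verdict.** Five technical replicates (fresh penalty sample and
   fresh Gaussian noise each); combinations are keyed by compound set
   across replicates. The best i > 1 set beats the best single only
   with p < 0.05 (two-sample two-sided Student's t-test, n = 5 per
   side) *and* mean ΔJSD ≥ 0.001 — the absolute cutoff screens out
   statistically significant but functionally negligible gains.
   Reproducibility is the percent of replicates whose rank-1 compound
   set equals the modal rank-1 set (modal ties broken lexicographically
   on sorted compound IDs).

Kinase mutants (flagged via a sidecar list or a name pattern such as
`FLT3(D835Y)`) may be *targets* but are always excluded from off-target
universes: a mutant and its parent kinase are not independent
off-target observations.

## Synthetic panels

The generator emulates the *structure* of large kinome screens: mostly
inactive compound–kinase pairs with rare potent hits. A parent profile
is a 20-bin activity distribution; activities are drawn i.i.d. (bin by
probability, uniform within the bin). Kinds:

* `pkis2_like` — 80% of mass in [0,5), geometric decay (ratio 0.6)
  across the mid-range, hit probability (mass ≥ 90%) 0.02. This is a
  parameterized approximation of a screening-average profile, not a
  published vector.
* `reduced_selectivity` / `least_selective` — the non-hit part mixed
  with a uniform distribution at weight 0.35 / 0.75, hit probability
  held fixed so potency eligibility stays comparable across kinds; the
  least-selective profile has nonzero mass in every bin.
* `binary` — hit probability in [95,100], the rest in [0,5).

What the generator does **not** emulate: correlated selectivity within
chemotypes, kinase-family structure (off-targets of real compounds
cluster in sequence space), assay noise heterogeneity, and
missing-data patterns of real screens. Passing simulation tests
therefore demonstrates the pipeline's internal correctness and its
qualitative trends, not quantitative transfer to any real dataset.

Two simulation studies sit on top:

* **Set-size scan** — panels of increasing size against 100 kinases;
  for each kinase as a single target the full replicated pipeline runs
  and the fraction of targets with a significant combination verdict is
  reported. As panels grow, both the best single inhibitor and the
  combinatorial options improve; the improvable fraction trends upward.
* **Fold-error propagation** — component affinities drawn log-uniformly
  from 1–1000 nM (the potency-eligible range; the sampling range is a
  package choice), each perturbed by an independent factor
  f ~ Uniform(1, 4), multiplied or divided with equal probability
  (symmetric perturbation is a package choice; only "randomly varied"
  is specified). The equimolar combination affinity is computed from
  true and perturbed components; fold-error = max/min ≥ 1 by
  construction, and the median fold-error shrinks with combination size
  as component errors average out.

## Numerical choices and degenerate inputs

* Dilution uses the closed form `m = floor(log(S_min/S_thr)/log R2)`
  with floating-point guard loops; results are identical to iterative
  R2 division but O(components × targets).
* Occupancy handles +∞ affinities (contribution 0) exactly; a target
  with no binding component is an explicit infeasibility error, never a
  silent zero.
* Activities of exactly 100 clamp to 99.995 before inversion; all-zero
  activity vectors are errors for Gini / relative selectivity factor.
* t-tests on constant identical replicate sets return p = 1 (no
  evidence of difference) rather than NaN.
* All randomness flows through `numpy.random.Generator` seeded by
  spawned `SeedSequence`s: one branch per replicate, one per
  combination; fixed seeds give bit-identical results.

## Problem sizes used by the test suite

The oracle comparison between the hill climb and an exhaustive 61-point
log-grid (ratio 10⁻³–10³) uses symmetric two-compound toys (shared
target, disjoint single off-targets, equal affinities) with R1 = 2,
R2 = 1.01 and 10,000 noise samples per kinase, so the score landscape
is stable enough for a 0.005 agreement band to be meaningful. On
strongly asymmetric toys the R1-quantized ratio grid (steps of R1²) can
stop a few thousandths short of the continuous-grid optimum — the
documented precision cost of larger R1 values. The set-size scan in the
test suite runs the binary profile at sizes 50/150/600 × 100 kinases ×
3 seeds with pair combinations (max_i = 2) and 5 replicates, a size
chosen to keep the full suite in the minutes range on one CPU.

## Limitations

* Pure occupancy model: no ATP/kinase concentration effects, no
  kinetics, no pharmacokinetics — optimized concentrations are assay
  concentrations, not doses.
* Scores inherit the input matrix's blind spots; sparse matrices
  overstate selectivity.
* The hill climb is a heuristic: for i > 2 no exhaustive search is
  attempted, and multimodal score landscapes can hold it at a local
  optimum (by design — this is the method).
* JSD values are comparable only within one penalty shape and
  parameterization; always report the penalty used, and preferably run
  two complementary penalties.
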