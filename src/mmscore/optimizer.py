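"""Combination enumeration, concentration optimization, and the full
replicated selectivity pipeline.

The pipeline, for a target set within a potency matrix:

1. *Pool*: compounds potent enough against at least one target —
   activity >= threshold (default 90%) at the reference concentration,
   i.e. K better than 111 nM in the 1 uM frame.
2. *Enumerate*: all combinations of up to ``max_i`` pool compounds;
   combinations that cannot maintain the threshold at every target with
   all components dosed at the concentration cap are eliminated.
3. *Score*: each combination, diluted to threshold, is scored as the
   Jensen-Shannon distance between its smoothed off-target distribution
   and the penalty distribution.
4. *Optimize*: component concentrations are hill-climbed: every pair of
   compounds is varied R1-fold in both orientations (one up, one down),
   each candidate is re-diluted to threshold and rescored, the best is
   kept, and rounds repeat until the score stops improving.
5. *Compare*: across technical replicates (fresh penalty sample and
   fresh Gaussian noise each), the best combination is compared to the
   best single inhibitor (delta-JSD, two-sided t-test, absolute cutoff).

Matrices holding single-concentration percent-activity screening data
(``value_kind="activity"``) are treated equimolar throughout: the
screening values are too imprecise near the 90% threshold to support
meaningful concentration optimization, so step 4 is skipped.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np

from .dataio import PotencyMatrix, TargetSpec
from .mixture import (
    InfeasibleMixtureError,
    Mixture,
    _activities_at,
    dilute_to_threshold,
)
from .penalty import PenaltyConfig, PenaltyDistribution
from .scoring import (
    DEFAULT_NOISE_VARIANCE,
    DEFAULT_SAMPLES_PER_KINASE,
    DeltaJSD,
    SelectivityScore,
    build_offtarget_distribution,
    delta_jsd,
    jsd_score,
    reproducibility,
)

__all__ = [
    "OptimizerConfig",
    "CombinationResult",
    "MMSResult",
    "eligible_pool",
    "enumerate_combinations",
    "optimize_concentrations",
    "run_mms",
]


@dataclass
class OptimizerConfig:
    """All tunable pipeline settings with their standard defaults."""

    max_i: int = 3
    R1: float = 5.0          # pairwise concentration variation fold
    R2: float = 1.1          # dilution step toward the on-target threshold
    min_conc: float = 1e-6   # nM; below this a component is flagged negligible
    max_conc: float | None = None  # nM cap; None = no solubility limit
    n_replicates: int = 5
    abs_cutoff: float = 0.001
    p_cutoff: float = 0.05
    noise_variance: float = DEFAULT_NOISE_VARIANCE
    samples_per_kinase: int = DEFAULT_SAMPLES_PER_KINASE
    convergence_eps: float = 1e-6

    def __post_init__(self):
        if self.R1 <= 1 or self.R2 <= 1:
            raise ValueError("R1 and R2 must both be > 1")
        if self.max_i < 1:
            raise ValueError("max_i must be >= 1")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 technical replicates")


@dataclass
class CombinationResult:
    """Replicate-aggregated outcome for one compound set."""

    compounds: tuple[str, ...]
    mixture: Mixture
    scores: list[float]

    @property
    def i(self) -> int:
        return len(self.compounds)

    @property
    def mean_jsd(self) -> float:
        return float(np.mean(self.scores))

    @property
    def sd_jsd(self) -> float:
        return float(np.std(self.scores, ddof=1)) if len(self.scores) > 1 else 0.0


@dataclass
class MMSResult:
    """Full pipeline outcome for one target set and one penalty."""

    verdict: str  # combination_better | single_better_or_tied | infeasible
    best_single: CombinationResult | None = None
    best_combination: CombinationResult | None = None
    delta: DeltaJSD | None = None
    reproducibility: float | None = None
    best_per_i: dict[int, CombinationResult] = field(default_factory=dict)
    ranked: list[CombinationResult] = field(default_factory=list)
    rank1_sets: list[tuple[str, ...]] = field(default_factory=list)
    seed: int | None = None


def eligible_pool(matrix: PotencyMatrix, spec: TargetSpec) -> list[str]:
    """Compounds potent enough against at least one target.

    Potency is judged on the activity scale at the reference frame:
    activity >= threshold, equivalent to K <= ref*(100/thr - 1) nM
    (111 nM for the 90% threshold at 1 uM).  For multi-target sets a
    compound need only qualify at one target — a compound weak at one
    target can still anchor a combination — while combination-level
    feasibility enforces the threshold at every target.
    """
    acts = matrix.activities()[:, spec.target_indices(matrix)]
    ok = np.any(acts >= spec.on_target_threshold, axis=1)
    return [c for c, keep in zip(matrix.compounds, ok) if keep]


def _combo_feasible(combo_rows, aff, tcols, thr, cap) -> bool:
    # max achievable activity at each target: every component at the cap
    sub = aff[np.asarray(combo_rows, dtype=int)][:, tcols]
    with np.errstate(divide="ignore"):
        s = np.where(np.isfinite(sub), cap / sub, 0.0).sum(axis=0)
    return bool(np.all(100.0 * s / (1.0 + s) >= thr))


def enumerate_combinations(
    pool: list[str],
    max_i: int,
    matrix: PotencyMatrix,
    spec: TargetSpec,
    max_conc: float | None = None,
) -> dict[int, list[tuple[str, ...]]]:
    """All feasible compound subsets of size 1..max_i, keyed by size.

    A subset is feasible when cumulative activity can reach the
    threshold at every target with each component dosed at the
    concentration cap (``max_conc`` if given, else the matrix reference
    concentration — the frame in which potency is defined).
    """
    aff = matrix.affinities()
    tcols = spec.target_indices(matrix)
    thr = spec.on_target_threshold
    cap = max_conc if max_conc is not None else matrix.reference_conc
    rows = {c: matrix.compound_index(c) for c in pool}
    out: dict[int, list[tuple[str, ...]]] = {}
    for i in range(1, min(max_i, len(pool)) + 1):
        feas = []
        for combo in itertools.combinations(pool, i):
            if _combo_feasible([rows[c] for c in combo], aff, tcols, thr, cap):
                feas.append(combo)
        out[i] = feas
    return out


def _score_mixture(mix, aff_rows, ocols, penalty, config, seed) -> float:
    acts = _activities_at(mix, aff_rows, ocols) if len(ocols) else np.empty(0)
    dist = build_offtarget_distribution(
        acts,
        noise_variance=config.noise_variance,
        samples_per_kinase=config.samples_per_kinase,
        seed=np.random.default_rng(seed),
    )
    with warnings.catch_warnings():
        # JSD=1 warnings are expected in bulk enumeration; surfaced in reports
        warnings.simplefilter("ignore")
        return jsd_score(dist, penalty)


def optimize_concentrations(
    combo,
    matrix: PotencyMatrix,
    spec: TargetSpec,
    penalty: PenaltyDistribution,
    config: OptimizerConfig,
    seed=None,
    return_trace: bool = False,
):
    """Branch-and-bound concentration optimization of one combination.

    Starts equimolar at the reference concentration, diluted to the
    on-target threshold.  Each round generates both orientations of the
    R1-fold variation for every unordered pair of compounds
    ((a*R1, b/R1) and (a/R1, b*R1)), clamps to [min_conc, max_conc],
    re-dilutes every candidate to threshold and rescores them all under
    the same noise seed; the best candidate replaces the incumbent and
    rounds continue until no candidate improves the score.  Single
    compounds have no pairs, so optimization is a no-op beyond dilution.

    Activity-kind matrices are scored equimolar with no optimization.

    Returns ``(Mixture, SelectivityScore)``; with ``return_trace=True``
    the per-round incumbent scores are appended.
    """
    combo = tuple(combo)
    seed = int(np.random.default_rng(seed).integers(2**31)) if not isinstance(seed, (int, np.integer)) else int(seed)
    aff_rows = matrix.affinities()[[matrix.compound_index(c) for c in combo], :]
    ocols = spec.offtarget_indices(matrix)
    mix = Mixture.equimolar(combo, matrix.reference_conc)
    if config.max_conc is not None:
        mix = mix.with_concentrations(
            np.minimum(mix.concentrations, config.max_conc)
        )
    mix = dilute_to_threshold(
        mix, matrix, spec, R2=config.R2, max_conc=config.max_conc,
        min_conc=config.min_conc, _aff_rows=aff_rows,
    )
    best = _score_mixture(mix, aff_rows, ocols, penalty, config, seed)
    trace = [best]

    optimize = matrix.value_kind == "affinity" and len(combo) >= 2
    while optimize:
        candidates = []
        for a, b in itertools.combinations(range(len(combo)), 2):
            for up, down in ((a, b), (b, a)):
                conc = mix.concentrations.copy()
                conc[up] *= config.R1
                conc[down] /= config.R1
                conc = np.clip(conc, config.min_conc, config.max_conc or np.inf)
                try:
                    cand = dilute_to_threshold(
                        mix.with_concentrations(conc), matrix, spec,
                        R2=config.R2, max_conc=config.max_conc,
                        min_conc=config.min_conc, _aff_rows=aff_rows,
                    )
                except InfeasibleMixtureError:
                    continue
                score = _score_mixture(cand, aff_rows, ocols, penalty, config, seed)
                candidates.append((score, cand))
        if not candidates:
            break
        # deterministic tie-break: higher score, then lower total
        # concentration, then the concentration vector itself
        candidates.sort(
            key=lambda sc: (-sc[0], sc[1].total_concentration, tuple(sc[1].concentrations))
        )
        top_score, top_mix = candidates[0]
        if top_score > best + config.convergence_eps:
            best, mix = top_score, top_mix
            trace.append(best)
        else:
            break

    score = SelectivityScore(jsd=best, mixture=mix)
    if return_trace:
        return mix, score, trace
    return mix, score


def run_mms(
    matrix: PotencyMatrix,
    spec: TargetSpec,
    penalty_config: PenaltyConfig,
    config: OptimizerConfig | None = None,
    seed: int | None = None,
) -> MMSResult:
    """Run the full replicated pipeline for one target set.

    Each technical replicate resamples the penalty distribution and the
    Gaussian activity noise, optimizes every feasible combination, and
    ranks them.  Combinations are keyed by compound set across
    replicates.  The verdict is ``combination_better`` only when the
    best i>1 set beats the best single inhibitor with p < p_cutoff and
    a mean delta-JSD of at least the absolute cutoff.  Mutant kinases
    never enter the off-target distributions.
    """
    config = config or OptimizerConfig()
    pool = eligible_pool(matrix, spec)
    result_seed = None if seed is None else int(seed)
    if not pool:
        return MMSResult(verdict="infeasible", seed=result_seed)
    combos_by_i = enumerate_combinations(pool, config.max_i, matrix, spec, config.max_conc)
    all_combos = [c for i in sorted(combos_by_i) for c in combos_by_i[i]]
    if not all_combos:
        return MMSResult(verdict="infeasible", seed=result_seed)

    ss = np.random.SeedSequence(seed)
    rep_seeds = ss.spawn(config.n_replicates)

    per_combo_scores: dict[tuple[str, ...], list[float]] = {c: [] for c in all_combos}
    per_combo_best: dict[tuple[str, ...], tuple[float, Mixture]] = {}
    rank1_sets: list[tuple[str, ...]] = []

    for rep, rep_ss in enumerate(rep_seeds):
        children = rep_ss.spawn(len(all_combos) + 1)
        penalty = penalty_config.build(np.random.default_rng(children[0]))
        rep_scores = []
        for combo, child in zip(all_combos, children[1:]):
            combo_seed = int(np.random.default_rng(child).integers(2**31))
            mix, score = optimize_concentrations(
                combo, matrix, spec, penalty, config, seed=combo_seed
            )
            per_combo_scores[combo].append(score.jsd)
            prev = per_combo_best.get(combo)
            if prev is None or score.jsd > prev[0]:
                per_combo_best[combo] = (score.jsd, mix)
            rep_scores.append((score.jsd, mix.total_concentration, combo))
        rep_scores.sort(key=lambda t: (-t[0], t[1], t[2]))
        rank1_sets.append(rep_scores[0][2])

    results = [
        CombinationResult(
            compounds=c, mixture=per_combo_best[c][1], scores=per_combo_scores[c]
        )
        for c in all_combos
    ]
    results.sort(key=lambda r: (-r.mean_jsd, r.mixture.total_concentration, r.compounds))
    best_per_i: dict[int, CombinationResult] = {}
    for r in results:
        if r.i not in best_per_i:
            best_per_i[r.i] = r

    singles = [r for r in results if r.i == 1]
    multis = [r for r in results if r.i > 1]
    best_single = singles[0] if singles else None
    best_combo = multis[0] if multis else None

    delta = None
    verdict = "single_better_or_tied"
    if best_single is None:
        # no potent single exists; any feasible combination wins by default
        verdict = "combination_better" if best_combo is not None else "infeasible"
    elif best_combo is not None:
        delta = delta_jsd(
            best_combo.scores, best_single.scores,
            abs_cutoff=config.abs_cutoff, p_cutoff=config.p_cutoff,
        )
        if delta.significant:
            verdict = "combination_better"

    return MMSResult(
        verdict=verdict,
        best_single=best_single,
        best_combination=best_combo,
        delta=delta,
        reproducibility=reproducibility(rank1_sets),
        best_per_i=best_per_i,
        ranked=results,
        rank1_sets=rank1_sets,
        seed=result_seed,
    )
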