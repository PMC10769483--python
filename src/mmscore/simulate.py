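"""Synthetic inhibitor panels and the Monte-Carlo studies built on them.

Real kinome screens are proprietary-to-download tables; this module
generates panels with the same structure so the whole pipeline is
testable (and the simulation studies runnable) without external data.

A *parent profile* is a 20-bin probability distribution over the 0-100%
activity axis from which per-kinase activities of a simulated inhibitor
are drawn i.i.d.  Four kinds are provided:

* ``pkis2_like`` — mostly inactive (80% of mass below 5% activity) with
  a geometrically decaying mid-range and rare potent hits, emulating
  the average selectivity profile of a large screening set;
* ``reduced_selectivity`` / ``least_selective`` — the same profile
  smoothed toward uniform (mixing weight 0.35 / 0.75), holding the hit
  probability fixed so the chance of a potent on-target hit stays
  comparable across kinds; the least-selective profile has nonzero
  mass in every bin;
* ``binary`` — hypothetical compounds that are either potent (>=95%
  activity) or inactive.

On top of the sampler sit the two simulation studies: the *set-size
scan* (how the fraction of targets that benefit from an inhibitor
combination grows with the size of the available inhibitor set) and the
*fold-error propagation* study (how measurement error in component
affinities propagates into the predicted combination affinity).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dataio import PotencyMatrix, TargetSpec
from .mixture import equivalent_affinity
from .optimizer import OptimizerConfig, run_mms
from .penalty import N_BINS, PenaltyConfig

__all__ = [
    "ParentProfile",
    "make_parent_profile",
    "sample_inhibitor_set",
    "set_size_scan",
    "summarize_scan",
    "fold_error_simulation",
]

PROFILE_KINDS = ("pkis2_like", "reduced_selectivity", "least_selective", "binary")

#: Default smoothing (mixing weight toward uniform) per profile kind.
DEFAULT_SMOOTHING = {
    "pkis2_like": 0.0,
    "reduced_selectivity": 0.35,
    "least_selective": 0.75,
    "binary": 0.0,
}

_HIT_BINS = slice(18, 20)  # activity >= 90%


@dataclass
class ParentProfile:
    """A 20-bin activity distribution defining one inhibitor archetype."""

    kind: str
    bin_probs: np.ndarray

    def __post_init__(self):
        self.bin_probs = np.asarray(self.bin_probs, dtype=float)
        if self.bin_probs.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bin probabilities")
        if np.any(self.bin_probs < 0) or abs(self.bin_probs.sum() - 1.0) > 1e-9:
            raise ValueError("bin_probs must be a probability vector")

    @property
    def hit_prob(self) -> float:
        """Probability that a drawn activity is >= 90% (a potent hit)."""
        return float(self.bin_probs[_HIT_BINS].sum())


def _base_low_profile() -> np.ndarray:
    """Non-hit part of the screening-like profile (bins [0,90)), mass 1.

    80/98 of the mass sits in [0,5); the remainder decays geometrically
    (ratio 0.6) across [5,90).
    """
    low = np.zeros(18)
    low[0] = 0.80
    decay = 0.6 ** np.arange(17)
    low[1:] = 0.18 * decay / decay.sum()
    return low / low.sum()


def make_parent_profile(
    kind: str,
    hit_prob: float = 0.02,
    smoothing: float | None = None,
    seed=None,
) -> ParentProfile:
    """Build a parent profile of the requested kind.

    ``hit_prob`` fixes the mass at >= 90% activity for every kind, so
    the chance of a compound qualifying as potent against a given
    kinase is comparable across profiles.  ``smoothing`` in [0, 1]
    mixes the non-hit part of the profile with a uniform distribution
    over the non-hit bins (0 = unchanged); defaults depend on the kind.
    The construction is deterministic; ``seed`` is accepted for API
    symmetry with the samplers.
    """
    if kind not in PROFILE_KINDS:
        raise ValueError(f"unknown profile kind {kind!r}; choose from {PROFILE_KINDS}")
    if not 0 < hit_prob < 1:
        raise ValueError("hit_prob must lie in (0, 1)")
    if smoothing is None:
        smoothing = DEFAULT_SMOOTHING[kind]
    if not 0 <= smoothing <= 1:
        raise ValueError("smoothing must lie in [0, 1]")

    bins = np.zeros(N_BINS)
    if kind == "binary":
        bins[0] = 1.0 - hit_prob
        bins[N_BINS - 1] = hit_prob
        return ParentProfile(kind=kind, bin_probs=bins)

    low = _base_low_profile()
    uniform_low = np.full(18, 1.0 / 18)
    low = (1.0 - smoothing) * low + smoothing * uniform_low
    bins[:18] = (1.0 - hit_prob) * low / low.sum()
    # potent hits split evenly across [90,95) and [95,100]
    bins[18] = bins[19] = hit_prob / 2.0
    return ParentProfile(kind=kind, bin_probs=bins)


def sample_inhibitor_set(
    profile: ParentProfile,
    n_inhibitors: int,
    n_kinases: int = 100,
    seed=None,
) -> PotencyMatrix:
    """Bootstrap an activity-kind panel from a parent profile.

    Every compound-kinase activity is drawn i.i.d.: a bin from
    ``bin_probs``, then uniform within the bin.  The result is a dense
    percent-activity matrix with no mutants and no missing values.
    """
    if n_inhibitors < 1:
        raise ValueError("n_inhibitors must be >= 1")
    if n_kinases < 2:
        raise ValueError("n_kinases must be >= 2")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    shape = (n_inhibitors, n_kinases)
    idx = rng.choice(N_BINS, size=shape, p=profile.bin_probs)
    values = 5.0 * idx + rng.uniform(0.0, 5.0, size=shape)
    compounds = [f"C{i + 1:04d}" for i in range(n_inhibitors)]
    kinases = [f"K{j + 1:03d}" for j in range(n_kinases)]
    return PotencyMatrix(
        compounds=compounds,
        kinases=kinases,
        values=values,
        value_kind="activity",
    )


def set_size_scan(
    profile: ParentProfile,
    set_sizes,
    n_kinases: int = 100,
    penalty_config: PenaltyConfig | None = None,
    config: OptimizerConfig | None = None,
    seed=None,
) -> pd.DataFrame:
    """Scan inhibitor set sizes: does a larger repertoire help more targets?

    For each set size a fresh panel is bootstrapped and the full
    replicated pipeline runs once per kinase (that kinase as the single
    target, all others as off-targets).  Returns one row per
    (set size, target): the best-single mean JSD, the delta-JSD of the
    best combination, and whether the combination verdict was
    significant.  Targets with no potent inhibitor count as neither
    improvable nor scored.
    """
    sizes = list(set_sizes)
    if sizes != sorted(sizes):
        raise ValueError("set_sizes must be ascending")
    penalty_config = penalty_config or PenaltyConfig(mu=200.0)
    config = config or OptimizerConfig()
    ss = np.random.SeedSequence(seed)
    rows = []
    for size, size_ss in zip(sizes, ss.spawn(len(sizes))):
        panel_ss, mms_ss = size_ss.spawn(2)
        panel = sample_inhibitor_set(
            profile, size, n_kinases, seed=np.random.default_rng(panel_ss)
        )
        target_seeds = mms_ss.spawn(n_kinases)
        for kinase, kseed in zip(panel.kinases, target_seeds):
            spec = TargetSpec(targets=(kinase,))
            res = run_mms(
                panel, spec, penalty_config, config,
                seed=int(np.random.default_rng(kseed).integers(2**31)),
            )
            rows.append(
                {
                    "set_size": size,
                    "target": kinase,
                    "feasible": res.verdict != "infeasible",
                    "best_single_jsd": (
                        res.best_single.mean_jsd if res.best_single else np.nan
                    ),
                    "delta_jsd": (
                        res.delta.mean_delta if res.delta is not None else np.nan
                    ),
                    "combination_better": res.verdict == "combination_better",
                }
            )
    return pd.DataFrame(rows)


def summarize_scan(scan: pd.DataFrame) -> pd.DataFrame:
    """Per-size summary of a set-size scan."""
    grouped = scan.groupby("set_size")
    return pd.DataFrame(
        {
            "n_targets": grouped.size(),
            "n_feasible": grouped["feasible"].sum(),
            "mean_best_single_jsd": grouped["best_single_jsd"].mean(),
            "percent_improvable": 100.0 * grouped["combination_better"].mean(),
        }
    ).reset_index()


def fold_error_simulation(
    combo_sizes=(1, 2, 3, 4),
    n_cases: int = 1000,
    max_fold: float = 4.0,
    kd_range: tuple[float, float] = (1.0, 1000.0),
    seed=None,
) -> dict[int, np.ndarray]:
    """Propagate per-compound affinity fold-errors into combination K.

    For each case, component affinities are drawn log-uniformly from
    ``kd_range`` (nM) and each is perturbed by an independent factor
    f ~ Uniform(1, max_fold), multiplied or divided with equal
    probability.  The equimolar combination affinity is computed from
    the true and perturbed components and the fold-error
    max(pred, obs)/min(pred, obs) is recorded; averaging over several
    components shrinks the typical error below that of a single
    compound.
    """
    if max_fold <= 1:
        raise ValueError("max_fold must be > 1")
    if n_cases < 1:
        raise ValueError("n_cases must be >= 1")
    lo, hi = kd_range
    if not 0 < lo < hi:
        raise ValueError("kd_range must satisfy 0 < low < high")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out: dict[int, np.ndarray] = {}
    for n in combo_sizes:
        kds = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n_cases, n)))
        folds = rng.uniform(1.0, max_fold, size=(n_cases, n))
        direction = rng.integers(0, 2, size=(n_cases, n))
        perturbed = np.where(direction == 1, kds * folds, kds / folds)
        conc = np.ones(n)  # equimolar; equivalent K is scale-invariant
        errs = np.empty(n_cases)
        for i in range(n_cases):
            pred = equivalent_affinity(conc, kds[i])
            obs = equivalent_affinity(conc, perturbed[i])
            errs[i] = max(pred, obs) / min(pred, obs)
        out[int(n)] = errs
    return out
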