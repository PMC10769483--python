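"""Selectivity scoring: off-target distributions, JSD, and comparators.

A mixture's off-target profile (one activity percent per off-target
kinase, evaluated at the concentrations needed for threshold on-target
activity) is smoothed into a probability distribution: each activity is
the mean of a Gaussian (default variance 2.5, matching the 5% bin
width), each Gaussian is sampled 100 times, samples are clipped to
[0, 100], pooled across kinases and binned at 5%.

Selectivity is the Jensen-Shannon *distance* (base-2 logarithms, so the
range is exactly [0, 1]) between this off-target distribution and a
penalty distribution: 1 means no off-target mass in penalized activity
ranges (maximally selective), 0 means complete overlap.

Comparison metrics for single compounds (Gini coefficient, S-score,
relative selectivity factor) and the replicate statistics (delta-JSD
with a two-sample t-test, rank-1 reproducibility) live here too.
"""

from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import jensenshannon
from scipy.stats import ttest_ind

from .mixture import Mixture
from .penalty import N_BINS, PenaltyDistribution, bin_distribution

__all__ = [
    "OffTargetDistribution",
    "SelectivityScore",
    "DeltaJSD",
    "build_offtarget_distribution",
    "jsd_score",
    "delta_jsd",
    "gini_coefficient",
    "s_score",
    "relative_selectivity_factor",
    "reproducibility",
]

DEFAULT_NOISE_VARIANCE = 2.5
DEFAULT_SAMPLES_PER_KINASE = 100


@dataclass
class OffTargetDistribution:
    """Binned, Gaussian-smoothed off-target activity distribution.

    ``bins`` is None for an empty off-target universe (a distinguished
    value: scoring such a distribution returns a JSD of 1).
    """

    bins: np.ndarray | None
    raw_activities: np.ndarray
    noise_variance: float = DEFAULT_NOISE_VARIANCE
    samples_per_kinase: int = DEFAULT_SAMPLES_PER_KINASE

    @property
    def empty(self) -> bool:
        return self.bins is None


@dataclass
class SelectivityScore:
    """A single JSD score with its provenance."""

    jsd: float
    mixture: Mixture | None = None
    replicate_id: int | None = None

    def __post_init__(self):
        if not 0.0 <= self.jsd <= 1.0:
            raise ValueError(f"JSD must lie in [0, 1], got {self.jsd}")


def build_offtarget_distribution(
    activities,
    noise_variance: float = DEFAULT_NOISE_VARIANCE,
    samples_per_kinase: int = DEFAULT_SAMPLES_PER_KINASE,
    seed=None,
) -> OffTargetDistribution:
    """Pool Gaussian noise around each off-target activity and bin at 5%.

    Samples are clipped (not reflected or discarded) at 0 and 100 so
    every kinase contributes exactly ``samples_per_kinase`` draws.
    """
    acts = np.asarray(activities, dtype=float).ravel()
    if noise_variance <= 0:
        raise ValueError("noise_variance must be positive")
    if samples_per_kinase < 1:
        raise ValueError("samples_per_kinase must be >= 1")
    if acts.size == 0:
        return OffTargetDistribution(
            bins=None,
            raw_activities=acts,
            noise_variance=noise_variance,
            samples_per_kinase=samples_per_kinase,
        )
    if np.any(acts < 0) or np.any(acts > 100):
        raise ValueError("activities must lie in [0, 100]")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sd = float(np.sqrt(noise_variance))
    samples = rng.normal(acts[:, None], sd, size=(acts.size, samples_per_kinase))
    np.clip(samples, 0.0, 100.0, out=samples)
    return OffTargetDistribution(
        bins=bin_distribution(samples),
        raw_activities=acts,
        noise_variance=noise_variance,
        samples_per_kinase=samples_per_kinase,
    )


def jsd_score(offdist: OffTargetDistribution, penalty: PenaltyDistribution) -> float:
    """Jensen-Shannon distance (base 2) between off-target and penalty bins.

    Returns a value in [0, 1]: 0 for identical distributions, 1 for
    disjoint supports.  An empty off-target universe scores 1 by
    definition.  A score of exactly 1 triggers a warning, since it may
    mean no off-target activity falls inside the penalty's range and a
    broader penalty would be more informative.
    """
    if offdist.empty:
        return 1.0
    p = np.asarray(offdist.bins, dtype=float)
    q = np.asarray(penalty.bins, dtype=float)
    if p.shape != q.shape or p.shape != (N_BINS,):
        raise ValueError(f"both distributions must have {N_BINS} bins")
    d = float(jensenshannon(p, q, base=2))
    d = min(max(d, 0.0), 1.0)
    if d == 1.0:
        warnings.warn(
            "JSD score is exactly 1: no off-target mass overlaps the penalty "
            "range; consider a broader penalty distribution",
            stacklevel=2,
        )
    return d


@dataclass
class DeltaJSD:
    """Replicate comparison of a combination against the best single."""

    mean_delta: float
    combo_mean: float
    combo_sd: float
    single_mean: float
    single_sd: float
    p_value: float
    significant: bool
    abs_cutoff: float
    p_cutoff: float


def delta_jsd(
    combo_scores,
    single_scores,
    abs_cutoff: float = 0.001,
    p_cutoff: float = 0.05,
) -> DeltaJSD:
    """Delta-JSD summary with a two-sided two-sample Student's t-test.

    The verdict is significant only when both p < ``p_cutoff`` and the
    mean improvement reaches the absolute cutoff (default 0.001), which
    screens out statistically significant but functionally negligible
    gains.
    """
    combo = np.asarray([s.jsd if isinstance(s, SelectivityScore) else s for s in combo_scores],
                       dtype=float)
    single = np.asarray([s.jsd if isinstance(s, SelectivityScore) else s for s in single_scores],
                        dtype=float)
    if combo.size < 2 or single.size < 2:
        raise ValueError("need at least 2 replicate scores on each side")
    mean_delta = float(combo.mean() - single.mean())
    if np.allclose(combo, combo[0]) and np.allclose(single, single[0]) and combo[0] == single[0]:
        p = 1.0  # identical constant replicates: no evidence of difference
    else:
        with np.errstate(invalid="ignore", divide="ignore"), warnings.catch_warnings():
            # near-identical replicates trip scipy's precision-loss warning;
            # the resulting p is still used only against the 0.05 cutoff
            warnings.simplefilter("ignore", RuntimeWarning)
            p = float(ttest_ind(combo, single, equal_var=True).pvalue)
        if np.isnan(p):
            p = 1.0
    return DeltaJSD(
        mean_delta=mean_delta,
        combo_mean=float(combo.mean()),
        combo_sd=float(combo.std(ddof=1)),
        single_mean=float(single.mean()),
        single_sd=float(single.std(ddof=1)),
        p_value=p,
        significant=bool(p < p_cutoff and mean_delta >= abs_cutoff),
        abs_cutoff=abs_cutoff,
        p_cutoff=p_cutoff,
    )


def gini_coefficient(activities) -> float:
    """Gini coefficient of a compound's activity vector across kinases.

    0 for a uniform nonzero vector (no selectivity), approaching 1 when
    all activity concentrates on a single kinase.  Compound-level: the
    same value applies to every target of the compound.
    """
    x = np.sort(np.asarray(activities, dtype=float).ravel())
    if x.size == 0:
        raise ValueError("empty activity vector")
    if np.any(x < 0):
        raise ValueError("activities must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValueError("all-zero activity vector has undefined Gini")
    n = x.size
    i = np.arange(1, n + 1)
    return float(2.0 * np.sum(i * x) / (n * total) - (n + 1.0) / n)


def s_score(activities, activity_threshold: float = 50.0) -> float:
    """Fraction of kinases inhibited above the activity threshold."""
    x = np.asarray(activities, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty kinase universe")
    if not 0 < activity_threshold < 100:
        raise ValueError("activity_threshold must lie in (0, 100)")
    return float(np.mean(x > activity_threshold))


def relative_selectivity_factor(on_target_activity: float, all_activities) -> float:
    """On-target activity divided by total activity over all kinases
    (target included)."""
    x = np.asarray(all_activities, dtype=float).ravel()
    total = x.sum()
    if total <= 0:
        raise ValueError("total activity must be positive")
    return float(on_target_activity / total)


def reproducibility(rank1_sets) -> float:
    """Percent of replicates whose rank-1 compound set is the modal set.

    Sets are compared by compound identity only (not concentrations).
    Ties for the modal set are broken lexicographically on the sorted
    compound IDs, so the statistic is deterministic.
    """
    sets = [tuple(sorted(s)) for s in rank1_sets]
    if not sets:
        raise ValueError("no replicate results")
    counts = Counter(sets)
    modal = min(counts, key=lambda s: (-counts[s], s))
    return 100.0 * counts[modal] / len(sets)
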