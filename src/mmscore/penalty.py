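"""Penalty distributions: which off-target activity ranges cost how much.

A penalty distribution is a left-skewed probability distribution over
the 0-100% activity axis with its mode at 100%: potent off-target
inhibition is penalized most, and the tail parameter controls how far
down the activity axis penalties reach.  Two shapes are supported:

* the left tail of a Poisson pmf with mean ``mu``, mapped onto the
  activity axis by x = 100 - (mu - k) for counts k <= mu (one activity
  percent per count, mode pinned at 100%); presets ``tight`` (mu = 200,
  reaches ~50%), ``medium`` (mu = 700, ~20%) and ``broad`` (mu = 1200,
  full range);
* a Beta(alpha, beta) density scaled to [0, 100] (left-skewed whenever
  alpha > 1 and alpha > beta).

Distributions are realized by Monte-Carlo sampling (default 100,000
draws), binned at 5% into 20 bins, an extra high-off-target penalty
mass (default 0.1) is added to the [95, 100] bin, and the result is
normalized to sum 1.  The sampling rng is passed in so that technical
replicates of the scoring pipeline can resample the penalty.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "PenaltyDistribution",
    "PenaltyConfig",
    "bin_distribution",
    "build_poisson_penalty",
    "build_beta_penalty",
    "penalty_preset",
    "PRESET_MU",
]

N_BINS = 20
BIN_WIDTH = 5.0
#: Left edges of the 20 activity bins [0,5), [5,10), ..., [95,100].
BIN_EDGES = np.arange(0.0, 100.0 + BIN_WIDTH, BIN_WIDTH)

#: Poisson shape presets.
PRESET_MU = {"tight": 200.0, "medium": 700.0, "broad": 1200.0}

DEFAULT_N_SAMPLES = 100_000
DEFAULT_HIGH_PENALTY_MASS = 0.1


def _as_rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def bin_distribution(samples) -> np.ndarray:
    """Bin activity samples at 5% into a normalized 20-bin vector.

    Bins are half-open [0,5), ..., [90,95) with a closed final bin
    [95,100].  Samples must lie in [0, 100]; an empty sample set is an
    error.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("cannot bin an empty sample set")
    if np.any(x < 0) or np.any(x > 100):
        raise ValueError("activity samples must lie in [0, 100]")
    idx = np.minimum((x // BIN_WIDTH).astype(np.intp), N_BINS - 1)
    counts = np.bincount(idx, minlength=N_BINS).astype(float)
    return counts / counts.sum()


@dataclass
class PenaltyDistribution:
    """A realized, binned penalty distribution."""

    bins: np.ndarray
    shape: str
    params: dict
    n_samples: int = DEFAULT_N_SAMPLES
    high_penalty_mass: float = DEFAULT_HIGH_PENALTY_MASS

    def __post_init__(self):
        self.bins = np.asarray(self.bins, dtype=float)
        if self.bins.shape != (N_BINS,):
            raise ValueError(f"expected {N_BINS} bins, got {self.bins.shape}")
        if np.any(self.bins < 0) or abs(self.bins.sum() - 1.0) > 1e-9:
            raise ValueError("penalty bins must be non-negative and sum to 1")

    def to_csv(self, path) -> None:
        """Export the binned vector as ``bin_start,bin_end,probability``."""
        lines = ["bin_start,bin_end,probability"]
        for i, p in enumerate(self.bins):
            lines.append(f"{BIN_EDGES[i]:g},{BIN_EDGES[i + 1]:g},{repr(float(p))}")
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)


def _finalize(samples, shape, params, n_samples, high_penalty_mass) -> PenaltyDistribution:
    bins = bin_distribution(samples)
    bins[N_BINS - 1] += high_penalty_mass
    bins /= bins.sum()
    return PenaltyDistribution(
        bins=bins,
        shape=shape,
        params=dict(params),
        n_samples=n_samples,
        high_penalty_mass=high_penalty_mass,
    )


def build_poisson_penalty(
    mu: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    high_penalty_mass: float = DEFAULT_HIGH_PENALTY_MASS,
    seed=None,
) -> PenaltyDistribution:
    """Penalty from the left tail of a Poisson pmf.

    Counts ``k ~ Poisson(mu)`` with ``k <= mu`` are mapped to activities
    ``x = 100 - (mu - k)``; draws mapping below 0 are discarded.  The
    high-off-target penalty mass is then added to the [95, 100] bin and
    the vector renormalized.
    """
    if mu <= 0:
        raise ValueError("mu must be positive")
    if n_samples < 10_000:
        raise ValueError("n_samples must be at least 10000")
    if not 0 <= high_penalty_mass < 1:
        raise ValueError("high_penalty_mass must lie in [0, 1)")
    rng = _as_rng(seed)
    k = rng.poisson(mu, size=n_samples)
    x = 100.0 - (mu - k[k <= mu])
    x = x[x >= 0]
    if x.size == 0:
        raise ValueError("all Poisson samples were discarded; increase mu")
    return _finalize(x, "poisson", {"mu": float(mu)}, n_samples, high_penalty_mass)


def build_beta_penalty(
    alpha: float,
    beta: float,
    n_samples: int = DEFAULT_N_SAMPLES,
    high_penalty_mass: float = DEFAULT_HIGH_PENALTY_MASS,
    seed=None,
) -> PenaltyDistribution:
    """Penalty from a Beta(alpha, beta) density scaled to [0, 100]."""
    if alpha <= 0 or beta <= 0:
        raise ValueError("alpha and beta must be positive")
    if n_samples < 10_000:
        raise ValueError("n_samples must be at least 10000")
    if not 0 <= high_penalty_mass < 1:
        raise ValueError("high_penalty_mass must lie in [0, 1)")
    rng = _as_rng(seed)
    x = 100.0 * rng.beta(alpha, beta, size=n_samples)
    return _finalize(
        x, "beta", {"alpha": float(alpha), "beta": float(beta)}, n_samples, high_penalty_mass
    )


@dataclass
class PenaltyConfig:
    """Unrealized penalty settings; ``build(rng)`` draws a fresh sample.

    Technical replicates of the scoring pipeline resample the penalty,
    so pipelines carry a config rather than a realized distribution.
    """

    shape: str = "poisson"
    mu: float | None = PRESET_MU["medium"]
    alpha: float | None = None
    beta: float | None = None
    n_samples: int = DEFAULT_N_SAMPLES
    high_penalty_mass: float = DEFAULT_HIGH_PENALTY_MASS

    def build(self, seed=None) -> PenaltyDistribution:
        if self.shape == "poisson":
            return build_poisson_penalty(
                self.mu, self.n_samples, self.high_penalty_mass, seed=seed
            )
        if self.shape == "beta":
            return build_beta_penalty(
                self.alpha, self.beta, self.n_samples, self.high_penalty_mass, seed=seed
            )
        raise ValueError(f"unknown penalty shape {self.shape!r}")


def penalty_preset(
    name: str,
    n_samples: int = DEFAULT_N_SAMPLES,
    high_penalty_mass: float = DEFAULT_HIGH_PENALTY_MASS,
) -> PenaltyConfig:
    """Named Poisson preset: ``tight`` / ``medium`` / ``broad``."""
    if name not in PRESET_MU:
        raise ValueError(f"unknown preset {name!r}; choose from {sorted(PRESET_MU)}")
    return PenaltyConfig(
        shape="poisson",
        mu=PRESET_MU[name],
        n_samples=n_samples,
        high_penalty_mass=high_penalty_mass,
    )
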