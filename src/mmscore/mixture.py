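"""Cumulative competitive-occupancy arithmetic for inhibitor mixtures.

For ``n`` competitive inhibitors at concentrations ``I_j`` (nM) with
affinities ``K_j`` (nM) against one kinase, the total fractional
occupancy is

    I_T = S / (1 + S),   S = sum_j I_j / K_j

reported as a percent.  This is a pure Langmuir-type competition
approximation: ATP competition and depletion of the kinase are ignored.
Occupancies are additive on the S scale, so mixture activity never
exceeds 100% and is monotone in every component concentration.

The *equivalent combination affinity* is the K a fixed-ratio mixture
behaves as if it had at its total concentration:

    K_eq = (1/f - 1) * sum_j I_j,   f = I_T / 100

which is invariant under rescaling all concentrations by a common
factor and reduces to the component K for a single compound.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np

from .dataio import PotencyMatrix, TargetSpec

__all__ = [
    "Mixture",
    "InfeasibleMixtureError",
    "cumulative_activity",
    "equivalent_affinity",
    "dilute_to_threshold",
    "mixture_profile",
    "MixtureProfile",
]

#: Concentrations below this (nM) are reported but flagged negligible.
DEFAULT_MIN_CONC = 1e-6


class InfeasibleMixtureError(RuntimeError):
    """The on-target threshold cannot be reached within the allowed
    concentration range."""


@dataclass(frozen=True)
class Mixture:
    """An ordered set of (compound, concentration nM) components."""

    components: tuple[tuple[str, float], ...]

    def __post_init__(self):
        comps = tuple((str(c), float(conc)) for c, conc in self.components)
        object.__setattr__(self, "components", comps)
        names = [c for c, _ in comps]
        if len(set(names)) != len(names):
            raise ValueError("component compound IDs must be unique")
        if any(conc < 0 for _, conc in comps):
            raise ValueError("concentrations must be non-negative")

    @classmethod
    def equimolar(cls, compounds, concentration: float) -> "Mixture":
        return cls(tuple((c, concentration) for c in compounds))

    @property
    def compounds(self) -> tuple[str, ...]:
        return tuple(c for c, _ in self.components)

    @property
    def concentrations(self) -> np.ndarray:
        return np.array([conc for _, conc in self.components], dtype=float)

    @property
    def total_concentration(self) -> float:
        return float(self.concentrations.sum())

    def scaled(self, factor: float) -> "Mixture":
        return Mixture(tuple((c, conc * factor) for c, conc in self.components))

    def with_concentrations(self, concentrations) -> "Mixture":
        concentrations = np.asarray(concentrations, dtype=float)
        if concentrations.shape != (len(self.components),):
            raise ValueError("one concentration per component required")
        return Mixture(tuple(zip(self.compounds, concentrations)))

    def molar_ratios(self) -> np.ndarray:
        """Ratios normalized so the smallest positive component is 1.00."""
        conc = self.concentrations
        pos = conc[conc > 0]
        if pos.size == 0:
            raise ValueError("mixture has no positive concentration")
        return conc / pos.min()

    def negligible_components(self, min_conc: float = DEFAULT_MIN_CONC) -> tuple[str, ...]:
        return tuple(c for c, conc in self.components if conc < min_conc)

    # -- serialization -------------------------------------------------
    def to_csv(self, path) -> None:
        lines = ["compound,concentration_nM"]
        lines += [f"{c},{repr(float(conc))}" for c, conc in self.components]
        text = "\n".join(lines) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)

    def to_dict(self) -> dict:
        ratios = self.molar_ratios() if np.any(self.concentrations > 0) else None
        return {
            "components": [
                {"compound": c, "concentration_nM": conc} for c, conc in self.components
            ],
            "total_concentration_nM": self.total_concentration,
            "molar_ratios": None if ratios is None else [float(r) for r in ratios],
        }

    def to_json(self, path) -> None:
        text = json.dumps(self.to_dict(), indent=2) + "\n"
        if hasattr(path, "write"):
            path.write(text)
        else:
            with open(path, "w", encoding="utf-8") as fh:
                fh.write(text)


def cumulative_activity(concentrations, affinities) -> float:
    """Percent occupancy of one kinase by a mixture.

    ``affinities`` may contain +inf (no detectable binding, contributes
    0).  Returns ``100 * S / (1 + S)`` in [0, 100).
    """
    conc = np.asarray(concentrations, dtype=float)
    aff = np.asarray(affinities, dtype=float)
    if np.any(conc < 0):
        raise ValueError("concentrations must be non-negative")
    finite = np.isfinite(aff)
    if np.any(aff[finite] <= 0):
        raise ValueError("affinities must be positive")
    with np.errstate(divide="ignore"):
        s = np.where(np.isfinite(aff), conc / aff, 0.0).sum()
    return float(100.0 * s / (1.0 + s))


def equivalent_affinity(concentrations, affinities) -> float:
    """Equivalent combination affinity ``(1/f - 1) * sum(I_j)`` in nM.

    For an equimolar mixture this is ``n / sum(1/K_j)``; for a single
    compound it returns its own K exactly.  Undefined (error) when the
    mixture produces zero occupancy.
    """
    conc = np.asarray(concentrations, dtype=float)
    it = cumulative_activity(conc, affinities)
    if it == 0.0:
        raise ValueError("equivalent affinity undefined for zero occupancy")
    f = it / 100.0
    return float((1.0 / f - 1.0) * conc.sum())


def _component_affinities(mix: Mixture, matrix: PotencyMatrix) -> np.ndarray:
    """(n_components, n_kinases) pseudo-affinity rows for the mixture."""
    rows = [matrix.compound_index(c) for c in mix.compounds]
    return matrix.affinities()[rows, :]


def _activities_at(mix: Mixture, aff_rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    conc = mix.concentrations
    sub = aff_rows[:, cols]
    with np.errstate(divide="ignore"):
        terms = np.where(np.isfinite(sub), conc[:, None] / sub, 0.0)
    s = terms.sum(axis=0)
    return 100.0 * s / (1.0 + s)


@dataclass
class MixtureProfile:
    """Per-kinase activities of a mixture, targets and off-targets apart."""

    mixture: Mixture
    targets: tuple[str, ...]
    target_activities: np.ndarray
    offtargets: tuple[str, ...]
    offtarget_activities: np.ndarray


def mixture_profile(mix: Mixture, matrix: PotencyMatrix, spec: TargetSpec) -> MixtureProfile:
    """Cumulative activity of a mixture at every target and off-target."""
    aff = _component_affinities(mix, matrix)
    tcols = spec.target_indices(matrix)
    ocols = spec.offtarget_indices(matrix)
    offs = tuple(spec.resolve_offtargets(matrix))
    return MixtureProfile(
        mixture=mix,
        targets=spec.targets,
        target_activities=_activities_at(mix, aff, tcols),
        offtargets=offs,
        offtarget_activities=(
            _activities_at(mix, aff, ocols) if len(ocols) else np.empty(0)
        ),
    )


def dilute_to_threshold(
    mix: Mixture,
    matrix: PotencyMatrix,
    spec: TargetSpec,
    R2: float = 1.1,
    max_conc: float | None = None,
    min_conc: float = DEFAULT_MIN_CONC,
    _aff_rows: np.ndarray | None = None,
) -> Mixture:
    """Scale a mixture (fixed ratios) to sit just above the on-target
    threshold.

    Concentrations are repeatedly divided by ``R2`` while cumulative
    activity stays >= threshold at *every* target; the last compliant
    mixture is returned, so the result is within one R2 step of the
    threshold.  A mixture starting below threshold is scaled *up* by R2
    steps; if compliance would require some component to exceed
    ``max_conc``, :class:`InfeasibleMixtureError` is raised.
    """
    if R2 <= 1:
        raise ValueError("R2 must be > 1")
    aff = _component_affinities(mix, matrix) if _aff_rows is None else _aff_rows
    tcols = spec.target_indices(matrix)
    thr = spec.on_target_threshold
    conc = mix.concentrations
    if not np.any(conc > 0):
        raise InfeasibleMixtureError("mixture has no positive concentration")

    # S = sum I_j/K_j is linear in a common scale factor, so the number of
    # R2 steps has a closed form: the result equals the step-by-step
    # division/multiplication but costs O(components x targets).
    sub = aff[:, tcols]
    with np.errstate(divide="ignore"):
        s = np.where(np.isfinite(sub), conc[:, None] / sub, 0.0).sum(axis=0)
    s_min = float(s.min())
    s_thr = thr / (100.0 - thr)
    if s_min <= 0.0:
        raise InfeasibleMixtureError(
            f"threshold {thr}% unreachable: a target has no binding component"
        )
    log_ratio = (np.log(s_min) - np.log(s_thr)) / np.log(R2)
    if s_min >= s_thr * (1.0 - 1e-12):
        m = max(int(np.floor(log_ratio + 1e-9)), 0)
        while m > 0 and s_min * R2**-m < s_thr * (1.0 - 1e-12):
            m -= 1  # guard against floating-point overshoot of floor()
        return mix.with_concentrations(conc * R2**-m)

    m = max(int(np.ceil(-log_ratio - 1e-9)), 1)
    while s_min * R2**m < s_thr * (1.0 - 1e-12):
        m += 1
    scaled = conc * R2**m
    if max_conc is not None and scaled.max() > max_conc * (1.0 + 1e-12):
        raise InfeasibleMixtureError(
            f"threshold {thr}% unreachable within max_conc={max_conc} nM"
        )
    return mix.with_concentrations(scaled)
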