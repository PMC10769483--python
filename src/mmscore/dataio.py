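"""Potency matrices and the activity <-> affinity conversion.

The method works on a common *activity* scale: the fractional occupancy
(in percent) of a kinase by a competitive inhibitor dosed at a reference
concentration (default 1 uM).  For a dissociation constant ``K`` (nM) and
reference concentration ``ref`` (nM),

    activity = 100 * (ref / K) / (1 + ref / K)

so a 100 nM compound sits at ~91% activity at 1 uM, and 1 uM at exactly
50%.  K_d, K_i and apparent K_d values are treated equivalently.

A :class:`PotencyMatrix` stores either affinities (nM) or single-
concentration percent-activity values (PKIS2-style screening data) for
``compounds x kinases``, with an explicit missing-value mask and
per-kinase mutant flags.  Missing entries are interpreted downstream as
"no detectable binding" (activity 0, affinity +inf): the kinase still
belongs to the off-target universe and its zero activity contributes
mass to the lowest histogram bin.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

__all__ = [
    "PotencyMatrix",
    "TargetSpec",
    "affinity_to_activity",
    "activity_to_affinity",
    "load_matrix",
    "load_long_matrix",
    "write_matrix",
    "write_long_matrix",
    "subset_universe",
]

#: Default reference concentration, nM (1 uM).
DEFAULT_REFERENCE_CONC = 1000.0

#: Activities of exactly 100% are clamped here before inversion to a
#: pseudo-affinity (an activity of 100 maps to K = 0, which is not
#: representable on the affinity scale).
ACTIVITY_CLAMP = 99.995

#: Kinase names matching this pattern are flagged as engineered/clinical
#: mutants by default, e.g. "FLT3(D835Y)" or "ABL1(T315I)-phosphorylated".
DEFAULT_MUTANT_PATTERN = r"\("

_MISSING_SENTINELS = {"", "na", "nan", "n/a", "none", "null"}


def affinity_to_activity(k, ref: float = DEFAULT_REFERENCE_CONC):
    """Convert affinity (nM) to percent occupancy at ``ref`` nM.

    ``activity = 100 * (ref/k) / (1 + ref/k)``; strictly decreasing in
    ``k`` and increasing in ``ref``, with values in the open interval
    (0, 100).  Scalar or array input.
    """
    k = np.asarray(k, dtype=float)
    ref = float(ref)
    if ref <= 0:
        raise ValueError(f"reference concentration must be positive, got {ref}")
    finite = np.isfinite(k)
    if np.any(k[finite] <= 0):
        raise ValueError("affinities must be positive")
    with np.errstate(divide="ignore"):
        s = ref / k  # k = +inf => s = 0 => activity 0
    out = 100.0 * s / (1.0 + s)
    return out if out.ndim else float(out)


def activity_to_affinity(a, ref: float = DEFAULT_REFERENCE_CONC):
    """Invert :func:`affinity_to_activity`: ``K = ref * (100/a - 1)``.

    Defined for activities strictly inside (0, 100); 0 and 100 would map
    to an infinite / zero affinity.
    """
    a = np.asarray(a, dtype=float)
    ref = float(ref)
    if ref <= 0:
        raise ValueError(f"reference concentration must be positive, got {ref}")
    if np.any(a <= 0) or np.any(a >= 100):
        raise ValueError("activities must lie strictly between 0 and 100")
    out = ref * (100.0 / a - 1.0)
    return out if out.ndim else float(out)


@dataclass
class PotencyMatrix:
    """Compounds x kinases potency data on either value scale.

    Parameters
    ----------
    compounds, kinases
        Unique row / column identifiers.
    values
        ``(n_compounds, n_kinases)`` float array.  Affinities are in nM
        (positive); activities are percent in [0, 100].  Entries under
        the missing mask are ignored.
    value_kind
        ``"affinity"`` or ``"activity"``.
    reference_conc
        Concentration (nM) at which the activity scale is defined.
    missing
        Boolean mask, True where no measurement exists.
    mutant_flags
        Per-kinase boolean; mutants may be targeted but are excluded
        from off-target universes.
    """

    compounds: list[str]
    kinases: list[str]
    values: np.ndarray
    value_kind: str
    reference_conc: float = DEFAULT_REFERENCE_CONC
    missing: np.ndarray | None = None
    mutant_flags: np.ndarray | None = None

    def __post_init__(self):
        self.compounds = list(map(str, self.compounds))
        self.kinases = list(map(str, self.kinases))
        self.values = np.asarray(self.values, dtype=float)
        if self.value_kind not in ("affinity", "activity"):
            raise ValueError(f"value_kind must be 'affinity' or 'activity', got {self.value_kind!r}")
        if self.values.shape != (len(self.compounds), len(self.kinases)):
            raise ValueError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.compounds)} compounds x {len(self.kinases)} kinases"
            )
        if len(set(self.compounds)) != len(self.compounds):
            raise ValueError("duplicate compound identifiers")
        if len(set(self.kinases)) != len(self.kinases):
            raise ValueError("duplicate kinase identifiers")
        if self.reference_conc <= 0:
            raise ValueError("reference_conc must be positive")
        if self.missing is None:
            self.missing = ~np.isfinite(self.values)
        self.missing = np.asarray(self.missing, dtype=bool) | ~np.isfinite(self.values)
        if self.missing.shape != self.values.shape:
            raise ValueError("missing mask shape must equal values shape")
        if self.mutant_flags is None:
            self.mutant_flags = np.zeros(len(self.kinases), dtype=bool)
        self.mutant_flags = np.asarray(self.mutant_flags, dtype=bool)
        if self.mutant_flags.shape != (len(self.kinases),):
            raise ValueError("mutant_flags must have one entry per kinase")
        self._validate_values()
        self._cidx = {c: i for i, c in enumerate(self.compounds)}
        self._kidx = {k: i for i, k in enumerate(self.kinases)}
        self._activity_cache: np.ndarray | None = None
        self._affinity_cache: np.ndarray | None = None

    def _validate_values(self):
        present = ~self.missing
        vals = self.values
        if self.value_kind == "affinity":
            bad = present & (vals <= 0)
            msg = "affinity must be positive"
        else:
            bad = present & ((vals < 0) | (vals > 100))
            msg = "activity must lie in [0, 100]"
        if np.any(bad):
            i, j = map(int, np.argwhere(bad)[0])
            raise ValueError(
                f"{msg}: cell ({self.compounds[i]!r}, {self.kinases[j]!r}) = {vals[i, j]}"
            )

    # -- index helpers -------------------------------------------------
    @property
    def n_compounds(self) -> int:
        return len(self.compounds)

    @property
    def n_kinases(self) -> int:
        return len(self.kinases)

    def compound_index(self, compound: str) -> int:
        try:
            return self._cidx[compound]
        except KeyError:
            raise KeyError(f"unknown compound {compound!r}") from None

    def kinase_index(self, kinase: str) -> int:
        try:
            return self._kidx[kinase]
        except KeyError:
            raise KeyError(f"unknown kinase {kinase!r}") from None

    # -- scale views ---------------------------------------------------
    def activities(self) -> np.ndarray:
        """Dense activity matrix (percent); missing entries are 0.

        The conversion is computed once and cached (treat as read-only).
        """
        if self._activity_cache is None:
            if self.value_kind == "activity":
                out = np.where(self.missing, 0.0, self.values)
            else:
                k = np.where(self.missing, np.inf, self.values)
                out = affinity_to_activity(k, self.reference_conc)
            self._activity_cache = out
        return self._activity_cache

    def affinities(self) -> np.ndarray:
        """Dense pseudo-affinity matrix (nM); missing entries are +inf.

        Activity values are inverted through the occupancy equation;
        activities of exactly 100% are clamped to 99.995 first, and
        activities of 0 are treated as no detectable binding (+inf).
        """
        if self._affinity_cache is None:
            if self.value_kind == "affinity":
                out = np.where(self.missing, np.inf, self.values)
            else:
                a = np.where(self.missing, 0.0, self.values)
                a = np.where(a >= 100.0, ACTIVITY_CLAMP, a)
                out = np.full_like(a, np.inf)
                pos = a > 0
                out[pos] = activity_to_affinity(a[pos], self.reference_conc)
            self._affinity_cache = out
        return self._affinity_cache


@dataclass
class TargetSpec:
    """The target set and the off-target universe scored against it.

    ``offtarget_universe = None`` means "all non-mutant kinases of the
    matrix that are not targets".  Mutant-flagged kinases may be
    *targets* but are always removed from the off-target universe.
    """

    targets: tuple[str, ...]
    offtarget_universe: tuple[str, ...] | None = None
    on_target_threshold: float = 90.0

    def __post_init__(self):
        if isinstance(self.targets, str):
            self.targets = (self.targets,)
        self.targets = tuple(self.targets)
        if not self.targets:
            raise ValueError("target set must be non-empty")
        if len(set(self.targets)) != len(self.targets):
            raise ValueError("duplicate targets")
        if self.offtarget_universe is not None:
            self.offtarget_universe = tuple(self.offtarget_universe)
            overlap = set(self.targets) & set(self.offtarget_universe)
            if overlap:
                raise ValueError(f"targets also in off-target universe: {sorted(overlap)}")
        if not 0 < self.on_target_threshold < 100:
            raise ValueError("on_target_threshold must lie in (0, 100)")

    def resolve_offtargets(self, matrix: PotencyMatrix) -> list[str]:
        """Off-target kinases actually scored: the universe minus targets
        and minus all mutant-flagged kinases."""
        for t in self.targets:
            matrix.kinase_index(t)
        mutants = {k for k, m in zip(matrix.kinases, matrix.mutant_flags) if m}
        if self.offtarget_universe is None:
            pool = [k for k in matrix.kinases if k not in self.targets]
        else:
            for k in self.offtarget_universe:
                matrix.kinase_index(k)
            pool = [k for k in self.offtarget_universe]
        return [k for k in pool if k not in mutants]

    def target_indices(self, matrix: PotencyMatrix) -> np.ndarray:
        return np.array([matrix.kinase_index(t) for t in self.targets], dtype=int)

    def offtarget_indices(self, matrix: PotencyMatrix) -> np.ndarray:
        return np.array(
            [matrix.kinase_index(k) for k in self.resolve_offtargets(matrix)], dtype=int
        )


# ---------------------------------------------------------------------
# IO
# ---------------------------------------------------------------------

def _read_table(path, sep=None) -> pd.DataFrame:
    return pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        index_col=0,
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )


def _parse_cell(raw: str) -> float:
    if raw is None or raw.strip().lower() in _MISSING_SENTINELS:
        return np.nan
    try:
        return float(raw)
    except ValueError:
        return np.nan


def _mutant_flags_for(kinases, mutant_pattern, mutants):
    if mutants is not None:
        mutants = set(mutants)
        return np.array([k in mutants for k in kinases], dtype=bool)
    if mutant_pattern is None:
        return np.zeros(len(kinases), dtype=bool)
    pat = re.compile(mutant_pattern)
    return np.array([bool(pat.search(k)) for k in kinases], dtype=bool)


def load_matrix(
    path,
    value_kind: str,
    reference_conc: float = DEFAULT_REFERENCE_CONC,
    sep: str | None = None,
    mutant_pattern: str | None = DEFAULT_MUTANT_PATTERN,
    mutants: list[str] | None = None,
) -> PotencyMatrix:
    """Load a wide CSV/TSV matrix (rows = compounds, columns = kinases).

    The delimiter is auto-detected unless ``sep`` is given.  Blank cells
    and the sentinels NA/NaN/N/A/none/null are missing.  Mutant kinases
    are flagged either by an explicit ``mutants`` list or by a regex
    ``mutant_pattern`` matched against column names (default: any name
    containing ``(``, e.g. ``FLT3(D835Y)``).
    """
    df = _read_table(path, sep=sep)
    compounds = [str(c) for c in df.index]
    kinases = [str(k) for k in df.columns]
    values = np.array([[_parse_cell(v) for v in row] for row in df.to_numpy()], dtype=float)
    missing = ~np.isfinite(values)
    return PotencyMatrix(
        compounds=compounds,
        kinases=kinases,
        values=values,
        value_kind=value_kind,
        reference_conc=reference_conc,
        missing=missing,
        mutant_flags=_mutant_flags_for(kinases, mutant_pattern, mutants),
    )


def load_long_matrix(
    path,
    value_kind: str,
    reference_conc: float = DEFAULT_REFERENCE_CONC,
    sep: str | None = None,
    mutant_pattern: str | None = DEFAULT_MUTANT_PATTERN,
    mutants: list[str] | None = None,
) -> PotencyMatrix:
    """Load a long-format triple file ``compound, kinase, value``.

    Pairs absent from the file are missing; duplicate pairs are an
    error.  Produces the same matrix as the wide reader would for the
    equivalent data (rows/columns ordered by first appearance).
    """
    df = pd.read_csv(
        path,
        sep=sep,
        engine="python" if sep is None else "c",
        dtype=str,
        keep_default_na=False,
        encoding="utf-8",
    )
    if df.shape[1] < 3:
        raise ValueError("long format requires columns: compound, kinase, value")
    ccol, kcol, vcol = df.columns[:3]
    if df.duplicated(subset=[ccol, kcol]).any():
        dup = df[df.duplicated(subset=[ccol, kcol])].iloc[0]
        raise ValueError(f"duplicate pair ({dup[ccol]!r}, {dup[kcol]!r})")
    compounds = list(dict.fromkeys(df[ccol]))
    kinases = list(dict.fromkeys(df[kcol]))
    cidx = {c: i for i, c in enumerate(compounds)}
    kidx = {k: i for i, k in enumerate(kinases)}
    values = np.full((len(compounds), len(kinases)), np.nan)
    for c, k, v in zip(df[ccol], df[kcol], df[vcol]):
        values[cidx[c], kidx[k]] = _parse_cell(v)
    return PotencyMatrix(
        compounds=compounds,
        kinases=kinases,
        values=values,
        value_kind=value_kind,
        reference_conc=reference_conc,
        missing=~np.isfinite(values),
        mutant_flags=_mutant_flags_for(kinases, mutant_pattern, mutants),
    )


def write_matrix(matrix: PotencyMatrix, path, sep: str = ",") -> None:
    """Write the wide canonical dialect (UTF-8, '.' decimal, blank = missing).

    Values round-trip bit-stably through :func:`load_matrix` (floats are
    written with ``repr`` precision).
    """
    vals = matrix.values
    rows = []
    for i, comp in enumerate(matrix.compounds):
        cells = [comp]
        for j in range(matrix.n_kinases):
            cells.append("" if matrix.missing[i, j] else repr(float(vals[i, j])))
        rows.append(sep.join(cells))
    header = sep.join(["compound"] + list(matrix.kinases))
    text = "\n".join([header] + rows) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def write_long_matrix(matrix: PotencyMatrix, path, sep: str = ",") -> None:
    """Write the long triple format ``compound, kinase, value``.

    Missing pairs are simply omitted, so sparse matrices stay compact.
    """
    lines = [sep.join(["compound", "kinase", "value"])]
    for i, comp in enumerate(matrix.compounds):
        for j, kin in enumerate(matrix.kinases):
            if not matrix.missing[i, j]:
                lines.append(sep.join([comp, kin, repr(float(matrix.values[i, j]))]))
    text = "\n".join(lines) + "\n"
    if hasattr(path, "write"):
        path.write(text)
    else:
        with open(path, "w", encoding="utf-8") as fh:
            fh.write(text)


def subset_universe(matrix: PotencyMatrix, spec: TargetSpec) -> PotencyMatrix:
    """Restrict a matrix to ``targets U off-target universe``.

    Mutant-flagged kinases are dropped from the off-target side
    automatically (they may remain only as explicit targets).  Column
    order of the original matrix is preserved.
    """
    keep = set(spec.targets) | set(spec.resolve_offtargets(matrix))
    for k in keep:
        matrix.kinase_index(k)
    cols = [j for j, k in enumerate(matrix.kinases) if k in keep]
    return replace(
        matrix,
        kinases=[matrix.kinases[j] for j in cols],
        values=matrix.values[:, cols].copy(),
        missing=matrix.missing[:, cols].copy(),
        mutant_flags=matrix.mutant_flags[cols].copy(),
    )
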