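"""Forward extension of a core to a full signature.

Proteins are added one at a time by stepwise forward selection on the
*residual* of the decision: first the variance explained by the core is
removed (OLS residual of the 0/1 decision on the core proteins), then
the available protein explaining the largest fraction of the remaining
variance (squared Pearson correlation with the residual) is added and
the outcome is re-residualized on all selected proteins.  Addition
stops when the best candidate explains no more than ``min_gain``
(default 1%) of the remaining variance, or the model would exceed
``max_size`` (default 20) proteins.

Candidates are used raw -- only the outcome is residualized -- and the
pool respects the exclusion set of the core's search branch, so
extended signatures stay mutually exclusive.  The practical-panel
filter removes proteins whose assays are hemolysis-sensitive or need a
strong predilution.
"""

from __future__ import annotations

import hashlib
import json
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .cores import Core
from .data import AssayManifest, CohortData, OutcomeCoding, design_matrix


@dataclass
class SignatureModel:
    """An ordered signature: core proteins plus forward additions."""

    core_proteins: tuple[str, ...]
    added_proteins: tuple[str, ...]
    coefficients: dict  # protein -> coefficient on the original log2 scale
    intercept: float
    comparison: str
    includes_age: bool = False
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if set(self.core_proteins) & set(self.added_proteins):
            raise ValueError("core and added proteins overlap")
        if len(self.proteins) > 20:
            raise ValueError("signature exceeds 20 proteins")

    @property
    def proteins(self) -> tuple[str, ...]:
        return self.core_proteins + self.added_proteins

    def to_dict(self) -> dict:
        return {
            "core_proteins": list(self.core_proteins),
            "added_proteins": list(self.added_proteins),
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "comparison": self.comparison,
            "includes_age": self.includes_age,
            "provenance": dict(self.provenance),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SignatureModel":
        return cls(
            core_proteins=tuple(d["core_proteins"]),
            added_proteins=tuple(d["added_proteins"]),
            coefficients=dict(d["coefficients"]),
            intercept=float(d["intercept"]),
            comparison=d["comparison"],
            includes_age=bool(d.get("includes_age", False)),
            provenance=dict(d.get("provenance", {})),
        )


def residualize(y_or_residual: np.ndarray, X_selected: np.ndarray) -> np.ndarray:
    """OLS residual of the current outcome on the selected proteins.

    The fit includes an intercept; the residual is orthogonal to every
    (centered) selected column.  Constant columns are dropped with a
    warning rather than producing a rank-deficient solve.
    """
    y = np.asarray(y_or_residual, dtype=float)
    X = np.asarray(X_selected, dtype=float)
    if X.ndim != 2 or X.shape[1] == 0:
        raise ValueError("X_selected must have at least one column")
    keep = X.std(axis=0) > 0
    if not keep.all():
        warnings.warn("dropping constant column(s) from residualization", stacklevel=2)
        X = X[:, keep]
    A = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    return y - A @ beta


def explained_variance(candidate_values: np.ndarray, residual: np.ndarray) -> float:
    """Fraction of remaining variance a candidate explains (r^2).

    Squared Pearson correlation between the candidate and the current
    residual; a constant candidate explains 0 by convention.
    """
    c = np.asarray(candidate_values, dtype=float)
    r = np.asarray(residual, dtype=float)
    if r.std() == 0:
        raise ValueError("residual has zero variance")
    if c.std() == 0:
        return 0.0
    corr = np.corrcoef(c, r)[0, 1]
    return float(corr**2)


def extend_core(
    core: Core,
    cohort: CohortData,
    coding: OutcomeCoding,
    max_size: int = 20,
    min_gain: float = 0.01,
    candidate_pool: Sequence[str] | None = None,
    force_include: Sequence[str] = (),
) -> SignatureModel:
    """Grow a core into a full signature by greedy forward selection.

    ``candidate_pool`` restricts the additions (e.g. to a
    practical-panel filter); the core's exclusion set is always
    respected.  ``force_include`` proteins are added first regardless
    of gain (the manual-curation route for previously associated
    markers), counting toward ``max_size``.
    """
    max_size = min(max_size, 20)
    pool = set(candidate_pool) if candidate_pool is not None else set(cohort.proteins)
    pool -= set(core.proteins)
    pool -= core.excluded
    pool &= set(cohort.proteins)

    selected = list(core.proteins)
    added: list[str] = []
    for p in force_include:
        if p in selected or p in core.excluded:
            continue
        if len(selected) >= max_size:
            break
        selected.append(p)
        added.append(p)
        pool.discard(p)

    X_all, y, _ = design_matrix(cohort, coding, cohort.proteins)
    col = {p: i for i, p in enumerate(cohort.proteins)}

    def residual_now():
        return residualize(y, X_all[:, [col[p] for p in selected]])

    resid = residual_now()
    # std below ~1e-8 means the outcome is numerically fully explained
    while pool and len(selected) < max_size and resid.std() > 1e-8:
        gains = {p: explained_variance(X_all[:, col[p]], resid) for p in sorted(pool)}
        best = max(sorted(gains), key=lambda p: gains[p])  # ties: lexicographic
        if gains[best] <= min_gain:
            break
        selected.append(best)
        added.append(best)
        pool.discard(best)
        resid = residual_now()

    # final coefficients: one OLS of the decision on all selected
    # proteins, on the original predictor scale
    Xs = X_all[:, [col[p] for p in selected]]
    A = np.column_stack([np.ones(len(y)), Xs])
    beta, *_ = np.linalg.lstsq(A, y, rcond=None)
    coefficients = {p: float(b) for p, b in zip(selected, beta[1:])}
    return SignatureModel(
        core_proteins=tuple(core.proteins),
        added_proteins=tuple(added),
        coefficients=coefficients,
        intercept=float(beta[0]),
        comparison=coding.comparison,
        includes_age=False,
        provenance={
            "excluded": sorted(core.excluded),
            "min_gain": min_gain,
            "max_size": max_size,
            "config_hash": _config_hash(core, min_gain, max_size),
        },
    )


def filter_candidates(
    manifest: AssayManifest,
    hemolysate_min: float = 7.5,
    dilution_max: float = 2025.0,
) -> list[str]:
    """Proteins practical for a custom multiplex panel.

    Removes assays that show interference below ``hemolysate_min``
    mg/ml of hemolysate (tolerance < 7.5 mg/ml) or that require a
    predilution of 1:``dilution_max`` or stronger (proteins far more
    abundant than the intended panel).  Proteins with missing
    annotation are excluded conservatively, with a warning.
    """
    tab = manifest.table
    tol = pd.to_numeric(tab["hemolysate_tolerance"], errors="coerce")
    dil = pd.to_numeric(tab["dilution_factor"], errors="coerce")
    missing = tab.index[tol.isna() | dil.isna()]
    if len(missing):
        warnings.warn(
            f"excluding {len(missing)} protein(s) with missing annotation: "
            f"{list(missing[:5])}",
            stacklevel=2,
        )
    keep = (tol >= hemolysate_min) & (dil < dilution_max)
    return [p for p in tab.index if bool(keep.get(p, False))]


def _config_hash(core: Core, min_gain: float, max_size: int) -> str:
    payload = json.dumps(
        {
            "core": list(core.proteins),
            "excluded": sorted(core.excluded),
            "min_gain": min_gain,
            "max_size": max_size,
        },
        sort_keys=True,
    )
    return hashlib.sha256(payload.encode()).hexdigest()[:12]
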