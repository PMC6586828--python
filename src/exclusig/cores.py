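"""Discovery of mutually exclusive protein cores.

A *core* is a small protein set that is robustly selected across
repeated 50/50 splits of a discovery cohort: on each split an
elastic-net linear model of the 0/1 decision is fitted on the training
half, and the proteins with nonzero coefficients at the
cross-validation-selected penalty are recorded.  Proteins present in at
least an inclusion fraction (default 70%) of the split models form the
core.

Mutually exclusive cores arise from a recursive exclusion search: each
accepted core of size N spawns N branches, each withholding one more
core protein from the candidate pool.  All previously excluded proteins
stay unavailable down a branch, so any two cores from different
branches differ in at least one protein.  Branches stop on an empty or
out-of-size core, on a core failing its sensitivity/specificity
constraint, or once the exclusion set exceeds a budget (default 20).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import FrozenSet, Sequence

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, ElasticNetCV
from sklearn.model_selection import KFold

from .data import CohortData, OutcomeCoding, design_matrix
from .evaluate import best_point, ols_refit_scores, roc_curve, stratified_half_split


def candidate_panel_count(n_proteins: int, panel_size: int) -> int:
    """Number of distinct panels of ``panel_size`` out of ``n_proteins``.

    The size of the exhaustive search space the recursive exclusion
    strategy avoids -- e.g. choosing 4 from 1000 proteins can be done in
    over 40 billion ways.
    """
    return math.comb(n_proteins, panel_size)


@dataclass
class StageConfig:
    """Search constraints for one comparison (stage) of the analysis.

    A core is accepted when its size lies in ``core_size_range`` and it
    reaches ``sens_only_threshold`` sensitivity, or both sensitivity
    and specificity reach ``joint_sens_spec_threshold`` (at the
    best-point operating point on held-out halves).
    """

    comparison: str
    core_size_range: tuple[int, int] = (2, 6)
    sens_only_threshold: float = 0.8
    joint_sens_spec_threshold: float = 0.7
    n_splits: int = 50
    inclusion_threshold: float = 0.70
    enet_mixing: float = 0.9
    cv_folds: int = 10
    max_exclusions: int = 20
    penalty_rule: str = "one_se"

    def __post_init__(self) -> None:
        lo, hi = self.core_size_range
        if not (1 <= lo <= hi <= 6):
            raise ValueError("core_size_range must lie within [1, 6]")
        for name in ("sens_only_threshold", "joint_sens_spec_threshold",
                     "inclusion_threshold", "enet_mixing"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must be in [0, 1]")

    @classmethod
    def for_comparison(cls, comparison: str, **overrides) -> "StageConfig":
        """Stage-specific constraint presets.

        Benign vs I-II: size 2-6, sens >= 0.8 or sens & spec > 0.6
        (early stages are hardest to separate); benign vs III-IV: size
        2-5, sens >= 0.8 or sens & spec > 0.7; benign vs I-IV: size
        2-6, sens >= 0.8 or sens & spec > 0.7.
        """
        presets = {
            "benign_vs_I_II": dict(core_size_range=(2, 6), joint_sens_spec_threshold=0.6),
            "benign_vs_III_IV": dict(core_size_range=(2, 5), joint_sens_spec_threshold=0.7),
            "benign_vs_I_IV": dict(core_size_range=(2, 6), joint_sens_spec_threshold=0.7),
            "I_II_vs_III_IV": dict(core_size_range=(2, 6), joint_sens_spec_threshold=0.7),
        }
        if comparison not in presets:
            raise ValueError(f"no preset for comparison {comparison!r}")
        kwargs = presets[comparison] | overrides
        return cls(comparison=comparison, **kwargs)

    def accepts(self, core: "Core") -> bool:
        lo, hi = self.core_size_range
        if not lo <= len(core.proteins) <= hi:
            return False
        sens, spec = core.performance
        return sens >= self.sens_only_threshold or (
            sens >= self.joint_sens_spec_threshold
            and spec >= self.joint_sens_spec_threshold
        )


@dataclass(frozen=True)
class Core:
    """A candidate core: proteins, exclusion history, and performance."""

    proteins: tuple[str, ...]
    excluded: FrozenSet[str]
    selection_frequencies: dict = field(compare=False)
    performance: tuple[float, float]  # (sens, spec) at BP on held-out halves
    branch_path: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if set(self.proteins) & self.excluded:
            raise ValueError("core proteins overlap the exclusion set")

    def to_dict(self) -> dict:
        return {
            "proteins": list(self.proteins),
            "excluded": sorted(self.excluded),
            "frequencies": {p: self.selection_frequencies.get(p) for p in self.proteins},
            "performance": {"sens": self.performance[0], "spec": self.performance[1]},
            "path": list(self.branch_path),
        }


def fit_penalized_model(
    X: np.ndarray,
    y: np.ndarray,
    mixing: float = 0.9,
    cv_folds: int = 10,
    seed: int | None = None,
    penalty: float | None = None,
    penalty_rule: str = "one_se",
) -> tuple[np.ndarray, float]:
    """Elastic-net linear regression of the 0/1 decision on proteins.

    Predictors are standardized internally; the returned coefficients
    are on the standardized scale (only the sparsity pattern matters to
    core selection).  The penalty is chosen by ``cv_folds``-fold
    cross-validation unless ``penalty`` pins it: at the largest value
    within one standard error of the CV minimum (``penalty_rule=
    "one_se"``, the glmnet coefficient-extraction default the method
    was built around, and markedly more specific in stability
    selection) or at the CV minimum itself (``"cv_min"``).

    Returns (coefficients, intercept).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("constant outcome")
    if penalty is None and len(y) < 2 * cv_folds:
        raise ValueError(f"need >= {2 * cv_folds} samples for {cv_folds}-fold CV")
    if penalty_rule not in ("one_se", "cv_min"):
        raise ValueError("penalty_rule must be 'one_se' or 'cv_min'")
    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        if penalty is None:
            cv = KFold(n_splits=cv_folds, shuffle=True, random_state=_u32(seed))
            cv_model = ElasticNetCV(
                l1_ratio=mixing, cv=cv, alphas=100, tol=1e-7, max_iter=50_000
            )
            cv_model.fit(Z, y)
            if penalty_rule == "cv_min":
                return cv_model.coef_.copy(), float(cv_model.intercept_)
            mse = cv_model.mse_path_  # (n_alphas, n_folds)
            mean_err = mse.mean(axis=1)
            se = mse.std(axis=1, ddof=1) / np.sqrt(mse.shape[1])
            i_min = int(np.argmin(mean_err))
            bound = mean_err[i_min] + se[i_min]
            penalty = float(cv_model.alphas_[mean_err <= bound].max())
        model = ElasticNet(alpha=penalty, l1_ratio=mixing, tol=1e-7, max_iter=50_000)
        model.fit(Z, y)
    return model.coef_.copy(), float(model.intercept_)


def discover_core(
    cohort: CohortData,
    coding: OutcomeCoding,
    config: StageConfig,
    excluded: FrozenSet[str] = frozenset(),
    seed: int | None = None,
    branch_path: tuple[str, ...] = (),
) -> Core | None:
    """One round of stability selection over repeated 50/50 splits.

    Returns the core (proteins selected in >= ``inclusion_threshold``
    of the split models, with its held-out best-point performance), or
    None ("no-core") when the core is empty or violates the size
    bounds.  ``excluded`` proteins are removed from the candidate pool
    before any fitting.
    """
    pool = [p for p in cohort.proteins if p not in excluded]
    if not pool:
        raise ValueError("candidate pool is empty")
    X, y, _ = design_matrix(cohort, coding, pool)
    ss = np.random.SeedSequence(_u32(seed))
    children = ss.spawn(config.n_splits + 1)
    split_rng = np.random.default_rng(children[0])
    counts = np.zeros(len(pool))
    splits = []
    for k in range(config.n_splits):
        tr, te = stratified_half_split(y, split_rng)
        while len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            tr, te = stratified_half_split(y, split_rng)
        splits.append((tr, te))
        coef, _ = fit_penalized_model(
            X[tr], y[tr],
            mixing=config.enet_mixing,
            cv_folds=config.cv_folds,
            seed=int(children[k + 1].generate_state(1)[0] % (2**31)),
            penalty_rule=config.penalty_rule,
        )
        counts += coef != 0
    freqs = dict(zip(pool, counts / config.n_splits))
    members = sorted(p for p, f in freqs.items() if f >= config.inclusion_threshold)
    lo, hi = config.core_size_range
    if not members or not lo <= len(members) <= hi:
        return None
    perf = _performance_over_splits(cohort, coding, members, splits)
    return Core(
        proteins=tuple(members),
        excluded=frozenset(excluded),
        selection_frequencies=freqs,
        performance=perf,
        branch_path=branch_path,
    )


def core_performance(
    proteins: Sequence[str],
    cohort: CohortData,
    coding: OutcomeCoding,
    n_splits: int = 50,
    seed: int | None = None,
) -> tuple[float, float]:
    """Held-out best-point (sens, spec) of an unpenalized refit.

    On each of ``n_splits`` stratified 50/50 splits the protein set is
    refitted by OLS on the training half and scored on the test half;
    sensitivity and specificity at the closest-to-perfect ROC point are
    averaged over splits.  Degenerate (single-class) halves are
    resampled.
    """
    if not proteins:
        raise ValueError("empty core")
    rng = np.random.default_rng(_u32(seed))
    _, y, _ = design_matrix(cohort, coding, proteins)
    splits = []
    for _ in range(n_splits):
        tr, te = stratified_half_split(y, rng)
        while len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            tr, te = stratified_half_split(y, rng)
        splits.append((tr, te))
    return _performance_over_splits(cohort, coding, proteins, splits)


def _performance_over_splits(cohort, coding, proteins, splits):
    X, y, _ = design_matrix(cohort, coding, proteins)
    sens, spec = [], []
    for tr, te in splits:
        s = ols_refit_scores(X[tr], y[tr], X[te])
        bp = best_point(roc_curve(s, y[te]))
        sens.append(bp.sens)
        spec.append(bp.spec)
    return float(np.mean(sens)), float(np.mean(spec))


def search_exclusive_cores(
    cohort: CohortData,
    coding: OutcomeCoding,
    config: StageConfig,
    seed: int | None = None,
) -> list[Core]:
    """Depth-first recursive exclusion search for mutually exclusive cores.

    Every accepted core of size N spawns N child searches, each adding
    one of its proteins to the branch's exclusion set; previously
    excluded proteins stay unavailable.  A branch terminates on
    "no-core", on a constraint violation (size or sens/spec per the
    StageConfig) or when more than ``max_exclusions`` proteins have
    been excluded.  Duplicate (proteins, excluded) states reached via
    different paths are visited once.

    The per-node randomness depends only on the exclusion set, never on
    traversal order, so a fixed seed yields an identical search tree.
    """
    master = _u32(seed)
    protein_index = {p: i for i, p in enumerate(cohort.proteins)}

    accepted: list[Core] = []
    seen_states: set[tuple] = set()
    visited_exclusions: set[FrozenSet[str]] = set()
    stack: list[tuple[FrozenSet[str], tuple[str, ...]]] = [(frozenset(), ())]

    while stack:
        excluded, path = stack.pop()
        if len(excluded) > config.max_exclusions:
            continue
        if excluded in visited_exclusions:
            continue
        visited_exclusions.add(excluded)
        if len(excluded) >= len(cohort.proteins):
            continue
        node_seed = _node_seed(master, excluded, protein_index)
        core = discover_core(
            cohort, coding, config, excluded=excluded, seed=node_seed, branch_path=path
        )
        if core is None or not config.accepts(core):
            continue
        state = (core.proteins, core.excluded)
        if state not in seen_states:
            seen_states.add(state)
            accepted.append(core)
        # children ordered by descending selection frequency of the
        # protein being excluded, ties lexicographic; pushed in reverse
        # so the stack pops them in that order.
        children = sorted(
            core.proteins,
            key=lambda p: (-core.selection_frequencies.get(p, 0.0), p),
        )
        for prot in reversed(children):
            stack.append((excluded | {prot}, path + (prot,)))
    return accepted


def _node_seed(master: int, excluded: FrozenSet[str], protein_index: dict) -> int:
    entropy = [master] + sorted(protein_index[p] for p in excluded)
    return int(np.random.SeedSequence(entropy).generate_state(1)[0] % (2**31))


def _u32(seed: int | None) -> int | None:
    return None if seed is None else int(seed) % (2**31)
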