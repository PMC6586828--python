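"""ROC machinery and replication-style model evaluation.

Operating-point conventions
---------------------------
A sample is called positive when its score is >= the threshold.  Three
clinically motivated points on the ROC curve are used throughout:

* BP  -- "best point": closest (Euclidean) point to perfect
  classification (sens = spec = 1).
* FSE -- focus on sensitivity: among points with sensitivity >= a
  minimum level, the one with highest specificity.
* FSP -- focus on specificity: the mirror image.

Replication-style evaluation refits a fixed protein set with ordinary
least squares on repeated stratified 50/50 splits (the relative NPX
scale makes coefficients non-transferable across laboratory runs) and
summarises AUC, PPV/NPV and the three operating points over repeats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .data import CohortData, OutcomeCoding, design_matrix

METRICS = ("AUC", "PPV", "NPV", "BPse", "BPsp", "FSEse", "FSEsp", "FSPse", "FSPsp")


class RocPoint(NamedTuple):
    threshold: float
    sens: float
    spec: float
    attained: bool = True


def roc_curve(scores, labels) -> pd.DataFrame:
    """All distinct operating points of the score, as (threshold, sens, spec).

    Includes a +inf sentinel (nothing called positive) and a point at
    every distinct score value; sensitivity is non-increasing in the
    threshold.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # group tied scores: cumulative counts at each distinct threshold
    distinct = np.r_[True, s[1:] != s[:-1]]
    idx = np.flatnonzero(distinct)
    tp = np.cumsum(y)
    last = np.r_[idx[1:] - 1, len(s) - 1]
    thresholds = np.r_[np.inf, s[idx]]
    tps = np.r_[0, tp[last]]
    fps = np.r_[0, (last + 1) - tp[last]]
    return pd.DataFrame(
        {
            "threshold": thresholds,
            "sens": tps / n_pos,
            "spec": (n_neg - fps) / n_neg,
        }
    )


def auc(scores, labels) -> float:
    """Area under the ROC curve = Mann-Whitney probability, ties 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels)
    ranks = stats.rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = len(labels) - n_pos
    u = ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def best_point(roc: pd.DataFrame) -> RocPoint:
    """Point minimising the distance to perfect classification.

    Ties break toward higher sensitivity, then higher threshold.
    """
    if len(roc) == 0:
        raise ValueError("empty ROC curve")
    d2 = (1 - roc["sens"]) ** 2 + (1 - roc["spec"]) ** 2
    best = d2.min()
    cand = roc[np.isclose(d2, best)]
    cand = cand.sort_values(["sens", "threshold"], ascending=False)
    row = cand.iloc[0]
    return RocPoint(float(row["threshold"]), float(row["sens"]), float(row["spec"]))


def point_at_min(roc: pd.DataFrame, which: str, level: float) -> RocPoint:
    """Best point subject to a floor on sensitivity or specificity.

    Among points with the constrained metric >= ``level``, returns the
    one maximising the other metric.  If no point attains the level the
    point with the maximal constrained metric is returned with
    ``attained=False`` (reported as "NA" downstream).
    """
    if which not in ("sensitivity", "specificity"):
        raise ValueError("which must be 'sensitivity' or 'specificity'")
    if not 0 < level <= 1:
        raise ValueError("level must be in (0, 1]")
    fixed = "sens" if which == "sensitivity" else "spec"
    other = "spec" if which == "sensitivity" else "sens"
    ok = roc[roc[fixed] >= level]
    if len(ok):
        cand = ok.sort_values([other, fixed, "threshold"], ascending=False)
        row = cand.iloc[0]
        return RocPoint(float(row["threshold"]), float(row["sens"]), float(row["spec"]))
    cand = roc.sort_values([fixed, other, "threshold"], ascending=False)
    row = cand.iloc[0]
    return RocPoint(
        float(row["threshold"]), float(row["sens"]), float(row["spec"]), attained=False
    )


def ppv_npv(tp: int, fp: int, tn: int, fn: int) -> tuple[float, float]:
    """Positive and negative predictive values; NaN on empty denominator."""
    if min(tp, fp, tn, fn) < 0:
        raise ValueError("counts must be nonnegative")
    ppv = tp / (tp + fp) if tp + fp else math.nan
    npv = tn / (tn + fn) if tn + fn else math.nan
    return ppv, npv


def confusion_at(scores, labels, threshold: float) -> tuple[int, int, int, int]:
    """(tp, fp, tn, fn) calling positive at score >= threshold."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores >= threshold
    tp = int(np.sum(pos & (labels == 1)))
    fp = int(np.sum(pos & (labels == 0)))
    tn = int(np.sum(~pos & (labels == 0)))
    fn = int(np.sum(~pos & (labels == 1)))
    return tp, fp, tn, fn


# ---------------------------------------------------------------------------
# splitting and OLS refit helpers shared with the core search


def stratified_half_split(y: np.ndarray, rng: np.random.Generator):
    """Indices of a stratified 50/50 split (train, test)."""
    train, test = [], []
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        idx = rng.permutation(idx)
        half = len(idx) // 2
        train.extend(idx[:half])
        test.extend(idx[half:])
    return np.sort(np.array(train)), np.sort(np.array(test))


def ols_refit_scores(X_train, y_train, X_test):
    """OLS refit on the training half; linear scores on the test half.

    Predictors are standardized with training-half statistics only (no
    leakage); constant columns stay at zero weight.
    """
    mean = X_train.mean(axis=0)
    sd = X_train.std(axis=0)
    sd[sd == 0] = 1.0
    Zt = (X_train - mean) / sd
    Zs = (X_test - mean) / sd
    A = np.column_stack([np.ones(len(Zt)), Zt])
    beta, *_ = np.linalg.lstsq(A, y_train, rcond=None)
    return np.column_stack([np.ones(len(Zs)), Zs]) @ beta


@dataclass
class EvaluationSummary:
    """Mean and SD of each metric over repeated split-refit evaluations."""

    comparison: str
    n_repeats: int
    min_level: float
    means: Mapping[str, float]
    sds: Mapping[str, float]
    model_size: int | None = None
    model_id: str | None = None

    def mean_sens_spec(self) -> float:
        return (self.means["BPse"] + self.means["BPsp"]) / 2.0


def evaluate_model_replication(
    proteins: Sequence[str],
    cohort: CohortData,
    coding: OutcomeCoding,
    n_repeats: int = 50,
    seed: int | None = None,
    min_level: float = 0.93,
    include_age: bool = False,
    model_id: str | None = None,
) -> EvaluationSummary:
    """Repeat-split refit evaluation of a fixed protein set.

    Per repeat: stratified 50/50 split, OLS refit of the fixed set on
    the training half, scores on the test half, then AUC, PPV/NPV and
    sens/spec at the BP and the minimum-sensitivity / -specificity
    points.  FSE/FSP metrics at repeats where the level is unattainable
    are dropped from the summary (NaN-aware means/SDs).
    """
    X, y, _ = design_matrix(cohort, coding, proteins, include_age=include_age)
    rng = np.random.default_rng(seed)
    rows = {m: [] for m in METRICS}
    for _ in range(n_repeats):
        tr, te = stratified_half_split(y, rng)
        while len(np.unique(y[te])) < 2 or len(np.unique(y[tr])) < 2:
            tr, te = stratified_half_split(y, rng)
        s = ols_refit_scores(X[tr], y[tr], X[te])
        roc = roc_curve(s, y[te])
        rows["AUC"].append(auc(s, y[te]))
        bp = best_point(roc)
        rows["BPse"].append(bp.sens)
        rows["BPsp"].append(bp.spec)
        ppv, npv = ppv_npv(*confusion_at(s, y[te], bp.threshold))
        rows["PPV"].append(ppv)
        rows["NPV"].append(npv)
        fse = point_at_min(roc, "sensitivity", min_level)
        fsp = point_at_min(roc, "specificity", min_level)
        rows["FSEse"].append(fse.sens if fse.attained else math.nan)
        rows["FSEsp"].append(fse.spec if fse.attained else math.nan)
        rows["FSPse"].append(fsp.sens if fsp.attained else math.nan)
        rows["FSPsp"].append(fsp.spec if fsp.attained else math.nan)
    means = {m: float(np.nanmean(v)) if not np.all(np.isnan(v)) else math.nan
             for m, v in rows.items()}
    sds = {m: float(np.nanstd(v)) if not np.all(np.isnan(v)) else math.nan
           for m, v in rows.items()}
    return EvaluationSummary(
        comparison=coding.comparison,
        n_repeats=n_repeats,
        min_level=min_level,
        means=means,
        sds=sds,
        model_size=len(proteins),
        model_id=model_id,
    )


def rank_models(summaries: Sequence[EvaluationSummary]) -> list[EvaluationSummary]:
    """Order models by average best-point sensitivity and specificity.

    Descending by mean(BPse, BPsp); ties break by higher AUC, then by
    smaller model size.  Input order never matters.
    """
    comparisons = {s.comparison for s in summaries}
    if len(comparisons) > 1:
        raise ValueError(f"summaries mix comparisons: {sorted(comparisons)}")

    def key(s: EvaluationSummary):
        size = s.model_size if s.model_size is not None else 0
        return (-s.mean_sens_spec(), -s.means["AUC"], size, s.model_id or "")

    return sorted(summaries, key=key)


def compare_score_groups(
    scores_by_group: Mapping[str, Sequence[float]],
    pairs: Sequence[tuple[str, str]] | None = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Pairwise two-sample rank-sum tests with a Bonferroni cut-off.

    The significance threshold is alpha / (number of comparisons),
    e.g. 0.05/6 = 8.3e-3 for six pairwise contrasts.
    """
    groups = list(scores_by_group)
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in scores_by_group.items():
        if len(v) < 2:
            raise ValueError(f"group {g!r} has < 2 samples")
    if pairs is None:
        pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    n_comparisons = len(pairs)
    threshold = alpha / n_comparisons
    rows = []
    for a, b in pairs:
        xa = np.asarray(scores_by_group[a], dtype=float)
        xb = np.asarray(scores_by_group[b], dtype=float)
        pooled = np.concatenate([xa, xb])
        # exact null distribution where feasible (small, tie-free groups)
        method = (
            "exact"
            if max(len(xa), len(xb)) <= 25 and len(np.unique(pooled)) == len(pooled)
            else "asymptotic"
        )
        res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method)
        rows.append((a, b, float(res.statistic), float(res.pvalue), res.pvalue < threshold))
    out = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic", "p", "significant"])
    out.attrs["bonferroni_threshold"] = threshold
    return out


def _check_two_classes(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
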