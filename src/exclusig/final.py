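"""Fixation of a signature into a deployable absolute-concentration classifier.

The chosen panel (e.g. an 11-plex plus age) is re-trained on log2
absolute concentrations: the cohort is split into equal training and
validation halves stratified by outcome, a ridge-penalized linear model
is fitted with k-fold cross-validation and the penalty chosen by the
one-standard-error rule, train and validation AUCs are compared with a
DeLong test, and -- when they do not differ -- a final model is refitted
on all samples.  Raw linear predictions are mapped to (0, 1) scores by
the logistic link f(x) = e^x / (e^x + 1), and three clinical cut-offs
are recorded on the score scale: the best point (BP) and the points
focusing on sensitivity (FSE) or specificity (FSP) at a 0.98 floor.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import expit

from .data import CohortData, OutcomeCoding, design_matrix
from .evaluate import auc, best_point, point_at_min, roc_curve

LINK_NAME = "logistic"


def link(x):
    """The logistic link f(x) = e^x / (e^x + 1), mapping scores to (0, 1)."""
    return expit(np.asarray(x, dtype=float))


# ---------------------------------------------------------------------------
# splitting


def stratified_split(
    labels: pd.Series | Mapping[str, object],
    fraction: float = 0.5,
    seed: int | None = None,
) -> tuple[list, list]:
    """Split sample ids into two disjoint halves, stratified by label.

    Per stratum the two halves differ by at most one sample.  Returns
    (train ids, validation ids); seed-deterministic.
    """
    labels = pd.Series(labels)
    rng = np.random.default_rng(seed)
    train, val = [], []
    for _, idx in labels.groupby(labels, sort=True).groups.items():
        ids = list(idx)
        if len(ids) < 2:
            raise ValueError("every stratum needs >= 2 samples")
        ids = [ids[i] for i in rng.permutation(len(ids))]
        n_train = int(round(len(ids) * fraction))
        n_train = min(max(n_train, 1), len(ids) - 1)
        train.extend(ids[:n_train])
        val.extend(ids[n_train:])
    return train, val


# ---------------------------------------------------------------------------
# ridge fit with the one-SE rule


@dataclass
class RidgeFitResult:
    coefficients: dict
    intercept: float
    penalty: float
    penalty_min: float
    cv_alphas: np.ndarray
    cv_mean_error: np.ndarray
    cv_se: np.ndarray


def one_se_penalty(alphas, mean_errors, ses) -> float:
    """Largest penalty whose CV error is within one SE of the minimum."""
    alphas = np.asarray(alphas, dtype=float)
    mean_errors = np.asarray(mean_errors, dtype=float)
    i_min = int(np.argmin(mean_errors))
    bound = mean_errors[i_min] + np.asarray(ses, dtype=float)[i_min]
    ok = alphas[mean_errors <= bound]
    return float(ok.max())


def _ridge_path(Z: np.ndarray, y: np.ndarray, alphas: np.ndarray) -> np.ndarray:
    """Ridge coefficients for every penalty at once, via SVD.

    Solves min ||y - b0 - Z b||^2 + alpha ||b||^2 on centered data;
    returns an (n_alphas, p) array (intercepts recovered separately).
    """
    yc = y - y.mean()
    Zc = Z - Z.mean(axis=0)
    U, s, Vt = np.linalg.svd(Zc, full_matrices=False)
    Uty = U.T @ yc
    d = s[None, :] / (s[None, :] ** 2 + alphas[:, None])  # (n_alphas, r)
    return (d * Uty[None, :]) @ Vt


def fit_final_model(
    X: np.ndarray,
    y: np.ndarray,
    folds: int = 5,
    seed: int | None = None,
    alphas: np.ndarray | None = None,
) -> RidgeFitResult:
    """Cross-validated ridge regression with the one-SE penalty rule.

    Predictors are standardized (training statistics); the CV error
    curve (mean squared error per penalty, SE over folds) is computed
    with stratified ``folds``-fold assignment, the penalty is the
    largest one within one SE of the CV minimum, and the returned
    coefficients (refit on all supplied samples at that penalty) are
    back-transformed to the original predictor scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(np.unique(y)) < 2:
        raise ValueError("constant outcome")
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < folds:
        raise ValueError(f"need >= {folds} samples per class for {folds}-fold CV")
    if alphas is None:
        alphas = np.logspace(-4, 4, 100)
    alphas = np.sort(np.asarray(alphas, dtype=float))

    mean = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mean) / sd

    # stratified fold assignment
    rng = np.random.default_rng(seed)
    fold_of = np.empty(len(y), dtype=int)
    for cls in classes:
        idx = rng.permutation(np.flatnonzero(y == cls))
        fold_of[idx] = np.arange(len(idx)) % folds
    fold_err = np.empty((folds, len(alphas)))
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        B = _ridge_path(Z[tr], y[tr], alphas)
        pred = Z[te] @ B.T + (y[tr].mean() - Z[tr].mean(axis=0) @ B.T)
        fold_err[f] = ((y[te][:, None] - pred) ** 2).mean(axis=0)
    cv_mean = fold_err.mean(axis=0)
    cv_se = fold_err.std(axis=0, ddof=1) / np.sqrt(folds)
    chosen = one_se_penalty(alphas, cv_mean, cv_se)

    B = _ridge_path(Z, y, np.array([chosen]))[0]
    beta = B / sd
    intercept = float(y.mean() - mean @ beta)
    return RidgeFitResult(
        coefficients={f"x{i}": float(b) for i, b in enumerate(beta)},
        intercept=intercept,
        penalty=float(chosen),
        penalty_min=float(alphas[int(np.argmin(cv_mean))]),
        cv_alphas=alphas,
        cv_mean_error=cv_mean,
        cv_se=cv_se,
    )


# ---------------------------------------------------------------------------
# DeLong test


def delong_auc_variance(scores, labels) -> tuple[float, float]:
    """AUC and its DeLong variance from placement values."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = scores[labels == 1], scores[labels == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("labels contain a single class")
    v10, v01 = _placements(pos, neg)
    a = float(v10.mean())
    var = 0.0
    if len(pos) > 1:
        var += v10.var(ddof=1) / len(pos)
    if len(neg) > 1:
        var += v01.var(ddof=1) / len(neg)
    return a, float(var)


def _placements(pos: np.ndarray, neg: np.ndarray):
    # midrank formulation: psi = 1 if pos > neg, 1/2 if tied
    all_s = np.concatenate([pos, neg])
    ranks = stats.rankdata(all_s)
    rp = stats.rankdata(pos)
    rn = stats.rankdata(neg)
    m, n = len(pos), len(neg)
    v10 = (ranks[:m] - rp) / n
    v01 = 1.0 - (ranks[m:] - rn) / m
    return v10, v01


def delong_test(
    scores_a,
    labels_a,
    scores_b,
    labels_b=None,
) -> tuple[float, float, float]:
    """Two-sided DeLong comparison of two AUCs.

    With ``labels_b`` omitted the scores are paired (two scores for the
    same samples) and the covariance of the placements is used; with
    ``labels_b`` given the comparison is unpaired (e.g. training vs
    validation halves) and the two variances add independently.

    Returns (auc_a, auc_b, p).
    """
    scores_a = np.asarray(scores_a, dtype=float)
    labels_a = np.asarray(labels_a, dtype=int)
    if labels_b is None:
        pos_mask, neg_mask = labels_a == 1, labels_a == 0
        if not pos_mask.any() or not neg_mask.any():
            raise ValueError("labels contain a single class")
        scores_b = np.asarray(scores_b, dtype=float)
        if len(scores_b) != len(scores_a):
            raise ValueError("paired comparison needs equal-length scores")
        v10a, v01a = _placements(scores_a[pos_mask], scores_a[neg_mask])
        v10b, v01b = _placements(scores_b[pos_mask], scores_b[neg_mask])
        auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
        m, n = int(pos_mask.sum()), int(neg_mask.sum())
        var = 0.0
        if m > 1:
            c10 = np.cov(v10a, v10b, ddof=1)
            var += (c10[0, 0] + c10[1, 1] - 2 * c10[0, 1]) / m
        if n > 1:
            c01 = np.cov(v01a, v01b, ddof=1)
            var += (c01[0, 0] + c01[1, 1] - 2 * c01[0, 1]) / n
        return auc_a, auc_b, _two_sided_p(auc_a - auc_b, var)
    auc_a, var_a = delong_auc_variance(scores_a, labels_a)
    auc_b, var_b = delong_auc_variance(scores_b, np.asarray(labels_b, dtype=int))
    return auc_a, auc_b, _two_sided_p(auc_a - auc_b, var_a + var_b)


def _two_sided_p(diff: float, var: float) -> float:
    if var <= 0:
        return 1.0 if diff == 0 else 0.0
    z = diff / math.sqrt(var)
    return float(2.0 * stats.norm.sf(abs(z)))


# ---------------------------------------------------------------------------
# cut-offs and the final model card


@dataclass
class CutoffSet:
    """The three clinical score thresholds with their defining sens/spec."""

    bp_cut: float
    bp_sens: float
    bp_spec: float
    fse_cut: float
    fse_sens: float
    fse_spec: float
    fse_attained: bool
    fsp_cut: float
    fsp_sens: float
    fsp_spec: float
    fsp_attained: bool

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.__dataclass_fields__}

    @classmethod
    def from_dict(cls, d: dict) -> "CutoffSet":
        return cls(**{k: d[k] for k in cls.__dataclass_fields__})


def determine_cutoffs(
    scores, labels, fse_level: float = 0.98, fsp_level: float = 0.98
) -> CutoffSet:
    """BP/FSE/FSP thresholds on the link-transformed score scale.

    BP is the closest point to perfect classification; FSE maximises
    specificity subject to sensitivity >= ``fse_level``; FSP mirrors it.
    Unattainable levels are flagged (``*_attained = False``).
    """
    roc = roc_curve(scores, labels)
    bp = best_point(roc)
    fse = point_at_min(roc, "sensitivity", fse_level)
    fsp = point_at_min(roc, "specificity", fsp_level)
    return CutoffSet(
        bp_cut=bp.threshold, bp_sens=bp.sens, bp_spec=bp.spec,
        fse_cut=fse.threshold, fse_sens=fse.sens, fse_spec=fse.spec,
        fse_attained=fse.attained,
        fsp_cut=fsp.threshold, fsp_sens=fsp.sens, fsp_spec=fsp.spec,
        fsp_attained=fsp.attained,
    )


@dataclass
class FinalModel:
    """A self-contained deployable classifier (model card).

    Coefficients act on log2 concentrations (and age in years); the
    linear predictor is mapped through the logistic link to a (0, 1)
    score and compared to the recorded cut-offs (score >= cut-off is
    positive).
    """

    proteins: tuple[str, ...]
    includes_age: bool
    coefficients: dict
    intercept: float
    cutoffs: CutoffSet
    link_name: str = LINK_NAME
    training_metadata: dict = field(default_factory=dict)

    @property
    def features(self) -> list[str]:
        return list(self.proteins) + (["age"] if self.includes_age else [])

    def score(self, values: pd.DataFrame) -> pd.Series:
        missing = set(self.features) - set(values.columns)
        if missing:
            raise KeyError(f"missing feature value(s): {sorted(missing)}")
        if values[self.features].isna().any().any():
            raise ValueError("missing values; refusing to score without imputation")
        lin = self.intercept + values[self.features].mul(
            pd.Series(self.coefficients)
        ).sum(axis=1)
        return pd.Series(link(lin), index=values.index, name="score")

    def predict(self, values: pd.DataFrame) -> pd.DataFrame:
        """Score samples and classify at each cut-off (boundary -> positive)."""
        s = self.score(values)
        return pd.DataFrame(
            {
                "score": s,
                "class_at_bp": (s >= self.cutoffs.bp_cut).astype(int),
                "class_at_fse": (s >= self.cutoffs.fse_cut).astype(int),
                "class_at_fsp": (s >= self.cutoffs.fsp_cut).astype(int),
            }
        )

    def to_dict(self) -> dict:
        return {
            "proteins": list(self.proteins),
            "includes_age": self.includes_age,
            "coefficients": dict(self.coefficients),
            "intercept": self.intercept,
            "link": self.link_name,
            "cutoffs": self.cutoffs.to_dict(),
            "training_metadata": dict(self.training_metadata),
        }

    def save(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    @classmethod
    def from_dict(cls, d: dict) -> "FinalModel":
        return cls(
            proteins=tuple(d["proteins"]),
            includes_age=bool(d["includes_age"]),
            coefficients=dict(d["coefficients"]),
            intercept=float(d["intercept"]),
            cutoffs=CutoffSet.from_dict(d["cutoffs"]),
            link_name=d.get("link", LINK_NAME),
            training_metadata=dict(d.get("training_metadata", {})),
        )

    @classmethod
    def load(cls, path) -> "FinalModel":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


@dataclass
class FixationReport:
    """Diagnostics of the train/validation fixation workflow."""

    model: FinalModel
    train_auc: float
    validation_auc: float
    delong_p: float
    train_ids: list
    validation_ids: list


def fix_model(
    cohort: CohortData,
    coding: OutcomeCoding,
    proteins: Sequence[str],
    include_age: bool = True,
    folds: int = 5,
    seed: int | None = None,
    fse_level: float = 0.98,
    fsp_level: float = 0.98,
) -> FixationReport:
    """Full fixation workflow for one panel on one cohort.

    Stratified 50/50 split; CV-ridge fit (one-SE penalty) on the
    training half; train vs validation AUC compared by an unpaired
    DeLong test; final refit on all coded samples with the same CV
    scheme; cut-offs determined on the full defining cohort's
    link-transformed scores.  Borderline samples are never involved.
    """
    proteins = list(proteins)
    ids = coding.sample_ids
    y = coding.y
    ss = np.random.SeedSequence(seed)
    s_split, s_train, s_final = (int(c.generate_state(1)[0] % (2**31)) for c in ss.spawn(3))

    train_ids, val_ids = stratified_split(y, 0.5, seed=s_split)
    X, yv, names = design_matrix(cohort, coding, proteins, include_age=include_age)
    pos = {sid: i for i, sid in enumerate(ids)}
    tr = [pos[s] for s in train_ids]
    va = [pos[s] for s in val_ids]

    fit_tr = fit_final_model(X[tr], yv[tr], folds=folds, seed=s_train)
    beta = np.array([fit_tr.coefficients[f"x{i}"] for i in range(len(names))])
    lin_tr = fit_tr.intercept + X[tr] @ beta
    lin_va = fit_tr.intercept + X[va] @ beta
    auc_tr, auc_va, p = delong_test(lin_tr, yv[tr], lin_va, yv[va])

    fit_all = fit_final_model(X, yv, folds=folds, seed=s_final)
    beta_all = np.array([fit_all.coefficients[f"x{i}"] for i in range(len(names))])
    scores_all = link(fit_all.intercept + X @ beta_all)
    cutoffs = determine_cutoffs(scores_all, yv, fse_level, fsp_level)

    model = FinalModel(
        proteins=tuple(proteins),
        includes_age=include_age,
        coefficients={n: float(b) for n, b in zip(names, beta_all)},
        intercept=float(fit_all.intercept),
        cutoffs=cutoffs,
        training_metadata={
            "comparison": coding.comparison,
            "folds": folds,
            "penalty_rule": "one_se",
            "penalty": fit_all.penalty,
            "seed": seed,
            "n_train": len(tr),
            "n_validation": len(va),
        },
    )
    return FixationReport(
        model=model,
        train_auc=auc_tr,
        validation_auc=auc_va,
        delong_p=p,
        train_ids=list(train_ids),
        validation_ids=list(val_ids),
    )
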