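"""Five-fold cross-validation harness and variant comparison.

Folds are stratified for classification (stabilizes small-n folds) and
plain shuffled splits for regression, both seeded. Clustering uses the tree
only and is therefore shared across folds; importance, probabilities, mtry
tuning and training see training-fold rows exclusively — the test fold is
touched only at prediction time.

Metrics: misclassification rate and AUC (from the forest's averaged class
proportions, computed by a Mann-Whitney rank statistic) for classification;
RMSE and MAE for regression.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.model_selection import KFold, StratifiedKFold

from .errors import DataError, ValidationError
from .model import PIRF, PIRFConfig

__all__ = ["CVReport", "run_cv", "compare_variants", "auc_score"]

log = logging.getLogger("pirf")


def auc_score(y_true, scores) -> float:
    """Area under the ROC curve via the Mann-Whitney rank statistic.

    ``y_true`` holds 0/1 (or boolean) indicators of the positive class;
    ties in ``scores`` get midranks, matching the trapezoidal ROC area.
    """
    y = np.asarray(y_true).astype(bool)
    s = np.asarray(scores, dtype=float)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        raise DataError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


@dataclass
class CVReport:
    """Per-fold and aggregate cross-validation metrics."""

    task: str
    n_folds: int
    fold_of: np.ndarray            # test-fold index per sample (post-filter)
    per_fold: pd.DataFrame         # one row per fold
    fold_seeds: tuple
    seed: Optional[int]

    @property
    def mean(self) -> pd.Series:
        return self.per_fold.drop(columns=["fold"]).mean()

    @property
    def sd(self) -> pd.Series:
        return self.per_fold.drop(columns=["fold"]).std(ddof=1)

    def to_frame(self) -> pd.DataFrame:
        out = self.per_fold.copy()
        summary = pd.DataFrame([
            dict(fold="mean", **self.mean.to_dict()),
            dict(fold="sd", **self.sd.to_dict()),
        ])
        return pd.concat([out, summary], ignore_index=True)


def _make_folds(y: np.ndarray, task: str, n_folds: int, seed: Optional[int]):
    n = len(y)
    if n < 10:
        raise ValidationError("cross-validation needs at least 10 samples")
    if task == "classification":
        _, counts = np.unique(y, return_counts=True)
        if counts.min() < n_folds:
            raise ValidationError(
                f"a class has only {counts.min()} samples; stratified "
                f"{n_folds}-fold CV would leave it absent from some training "
                "fold — reduce n_folds or collect more samples")
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True,
                                   random_state=seed)
        splits = list(splitter.split(np.zeros(n), y))
    else:
        splitter = KFold(n_splits=n_folds, shuffle=True, random_state=seed)
        splits = list(splitter.split(np.zeros(n)))
    fold_of = np.empty(n, dtype=int)
    for f, (_, test) in enumerate(splits):
        fold_of[test] = f
    return splits, fold_of


def _score_fold(res, task, X_test, y_test, classes) -> dict:
    if task == "classification":
        pred = res.forest.predict(X_test)
        proba = res.forest.predict_proba(X_test)[:, 1]
        return {
            "error_rate": float(np.mean(pred != y_test)),
            "auc": auc_score(y_test == classes[1], proba),
        }
    pred = res.forest.predict(X_test)
    resid = pred - np.asarray(y_test, dtype=float)
    return {"rmse": float(np.sqrt(np.mean(resid ** 2))),
            "mae": float(np.mean(np.abs(resid)))}


def run_cv(table, tree, y, task: str = "classification",
           config: Optional[PIRFConfig] = None, n_folds: int = 5,
           seed: Optional[int] = 0, model: Optional[PIRF] = None,
           **overrides) -> CVReport:
    """Cross-validate the full pipeline.

    For every fold the entire chain — cluster-local importance,
    probabilities, mtry tuning, final forest — is refit on the training
    rows; the partition into clusters comes from the tree alone and is
    shared. Returns per-fold metrics plus their mean and sd.
    """
    if model is None:
        model = PIRF(y, table, tree, task=task, config=config, **overrides)
    elif overrides:
        raise ValidationError("pass overrides through the model, not both")
    model._prepare()
    y_arr = model._y.values
    classes = np.unique(y_arr) if task == "classification" else None
    splits, fold_of = _make_folds(y_arr, task, n_folds, seed)
    fold_seeds = tuple(int(s.generate_state(1)[0] % 2 ** 31)
                       for s in np.random.SeedSequence(seed).spawn(n_folds))
    rows = []
    for f, (train, test) in enumerate(splits):
        log.info("cv fold=%d n_train=%d n_test=%d seed=%d",
                 f, len(train), len(test), fold_seeds[f])
        res = model._fit_rows(np.asarray(train), seed=fold_seeds[f])
        metrics = _score_fold(res, task, model._X[test], y_arr[test], classes)
        log.info("cv fold=%d k=%s mtry=%d metrics=%s",
                 f, res.k_phylo, res.mtry, metrics)
        rows.append({"fold": f, **metrics})
    return CVReport(task=task, n_folds=n_folds, fold_of=fold_of,
                    per_fold=pd.DataFrame(rows), fold_seeds=fold_seeds,
                    seed=seed)


VARIANT_MODES = {"pirf": "phylo", "uniform": "disjoint",
                 "onecluster": "single"}


def compare_variants(table, tree, y, task: str = "classification",
                     config: Optional[PIRFConfig] = None, n_folds: int = 5,
                     seed: Optional[int] = 0,
                     variants=("pirf", "uniform", "onecluster"),
                     **overrides):
    """Run the three forest variants under shared folds and seeds.

    Variants: ``pirf`` (phylogenetic clusters), ``uniform`` (fully disjoint
    clusters, k = p, the standard RF), ``onecluster`` (k = 1, globalized
    feature weighting). Returns ``(table, reports)`` where ``table`` has one
    row per (variant, fold) including the variance of that fold's
    probability vector w, and ``reports`` maps variant -> CVReport.
    """
    for v in variants:
        if v not in VARIANT_MODES:
            raise ValidationError(f"unknown variant {v!r}")
    rows = []
    reports = {}
    shared_fold_of = None
    for v in variants:
        cfg = PIRFConfig(**{**(config.__dict__ if config else {}),
                            **overrides, "cluster_mode": VARIANT_MODES[v]})
        model = PIRF(y, table, tree, task=task, config=cfg)
        model._prepare()
        y_arr = model._y.values
        classes = np.unique(y_arr) if task == "classification" else None
        splits, fold_of = _make_folds(y_arr, task, n_folds, seed)
        if shared_fold_of is None:
            shared_fold_of = fold_of
        elif not np.array_equal(shared_fold_of, fold_of):
            raise DataError("fold assignments differ across variants")
        fold_seeds = tuple(int(s.generate_state(1)[0] % 2 ** 31)
                           for s in np.random.SeedSequence(seed).spawn(n_folds))
        fold_rows = []
        for f, (train, test) in enumerate(splits):
            res = model._fit_rows(np.asarray(train), seed=fold_seeds[f])
            metrics = _score_fold(res, task, model._X[test], y_arr[test],
                                  classes)
            # shift-invariant variance; subtracting first keeps a constant
            # vector (the k=p uniform case) at exactly zero
            w_var = float(np.var(res.w - res.w[0]))
            rows.append({"variant": v, "fold": f, "w_variance": w_var,
                         **metrics})
            fold_rows.append({"fold": f, **metrics})
        reports[v] = CVReport(task=task, n_folds=n_folds,
                              fold_of=fold_of,
                              per_fold=pd.DataFrame(fold_rows),
                              fold_seeds=fold_seeds, seed=seed)
    return pd.DataFrame(rows), reports
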