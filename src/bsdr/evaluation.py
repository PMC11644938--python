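"""Downstream evaluation of selected band sets with an RBF-kernel SVM.

Protocol per fold: the selector is trained on 90% of the samples; the held
out 10% is halved into an SVM train and an SVM test split.  The SVM uses the
published hyperparameters — ``C = 1e5`` (classification) or ``C = 100``
(regression) with ``gamma = 1`` — and only the selected band columns.
Classification is scored by overall accuracy and Cohen's kappa, regression
by R² and RMSE.  A brute-force subset search over tiny band universes serves
as the optimality oracle in tests.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.svm import SVC, SVR

from .data import CLASSIFICATION, REGRESSION, SpectralDataset, SplitPlan, make_split_plan
from .exceptions import (
    CombinatorialGuardError,
    ConfigurationError,
    DataValidationError,
    StratificationError,
)

SVM_C_CLASSIFICATION = 1e5
SVM_C_REGRESSION = 100.0
SVM_GAMMA = 1.0


def confusion_from_labels(y_true, y_pred, n_classes: int) -> np.ndarray:
    """K x K count matrix, rows = true class, columns = predicted class."""
    conf = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(conf, (np.asarray(y_true), np.asarray(y_pred)), 1)
    return conf


def overall_accuracy(confusion: np.ndarray) -> float:
    """Proportion of correctly classified instances: trace / total."""
    conf = np.asarray(confusion, dtype=np.float64)
    if conf.size == 0:
        raise DataValidationError("empty confusion matrix")
    if (conf < 0).any():
        raise DataValidationError("confusion counts must be non-negative")
    total = conf.sum()
    if total <= 0:
        raise DataValidationError("confusion matrix has zero total count")
    return float(np.trace(conf) / total)


def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement ``(p_o - p_e) / (1 - p_e)``.

    ``p_o`` is the observed agreement (trace / total) and ``p_e`` the
    product-of-marginals chance agreement.  Undefined when ``p_e = 1``
    (a single-cell degenerate matrix).
    """
    conf = np.asarray(confusion, dtype=np.float64)
    p_o = overall_accuracy(conf)
    total = conf.sum()
    p_e = float((conf.sum(axis=1) * conf.sum(axis=0)).sum() / total**2)
    if p_e >= 1.0 - 1e-15:
        raise DataValidationError("kappa undefined: chance agreement equals 1")
    return (p_o - p_e) / (1.0 - p_e)


def regression_metrics(y_true, y_pred) -> tuple[float, float]:
    """``(R², RMSE)``; R² is NaN (undefined) for constant ``y_true``."""
    y_true = np.asarray(y_true, dtype=np.float64)
    y_pred = np.asarray(y_pred, dtype=np.float64)
    if y_true.shape != y_pred.shape or y_true.size < 2:
        raise DataValidationError("y_true and y_pred must be equal-length with n >= 2")
    ss_res = float(np.sum((y_true - y_pred) ** 2))
    rmse = float(np.sqrt(ss_res / y_true.size))
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else float("nan")
    return r2, rmse


@dataclass
class EvaluationReport:
    """Downstream SVM performance of one band set on one fold."""

    task: str
    fold_id: int
    target_size: int
    bands_used: np.ndarray
    oa: float | None = None
    kappa: float | None = None
    r2: float | None = None
    rmse: float | None = None
    mse: float | None = None

    @property
    def primary_metric(self) -> float:
        return self.oa if self.task == CLASSIFICATION else self.r2


def evaluate_bands_svm(
    dataset: SpectralDataset,
    bands,
    plan: SplitPlan,
) -> EvaluationReport:
    """Train an RBF-SVM on the selected band columns and score the test half.

    Bands are 1-based indices.  Hyperparameters are fixed at the published
    values (C, gamma); multiclass uses a one-vs-rest decision function.
    """
    band_arr = np.asarray(list(bands), dtype=np.int64)
    if band_arr.size == 0:
        raise ConfigurationError("band set is empty")
    if band_arr.min() < 1 or band_arr.max() > dataset.n_bands:
        raise ConfigurationError(f"band indices must lie in 1..{dataset.n_bands}")
    cols = band_arr - 1  # 1-based -> 0-based
    X, y = dataset.reflectance[:, cols], dataset.targets
    tr, te = plan.svm_train_indices, plan.svm_test_indices
    if tr.size == 0 or te.size == 0:
        raise DataValidationError("SVM train/test splits must be non-empty")
    report = EvaluationReport(
        task=dataset.task, fold_id=plan.fold_id,
        target_size=band_arr.size, bands_used=np.sort(band_arr),
    )
    if dataset.task == CLASSIFICATION:
        if np.unique(y[tr]).size != dataset.n_classes:
            raise StratificationError("a class is absent from the SVM training split")
        clf = SVC(kernel="rbf", C=SVM_C_CLASSIFICATION, gamma=SVM_GAMMA,
                  decision_function_shape="ovr")
        clf.fit(X[tr], y[tr])
        pred = clf.predict(X[te])
        conf = confusion_from_labels(y[te], pred, dataset.n_classes)
        report.oa = overall_accuracy(conf)
        report.kappa = cohens_kappa(conf)
    else:
        reg = SVR(kernel="rbf", C=SVM_C_REGRESSION, gamma=SVM_GAMMA)
        reg.fit(X[tr], y[tr])
        pred = reg.predict(X[te])
        report.r2, report.rmse = regression_metrics(y[te], pred)
        report.mse = report.rmse**2
    return report


def _report_rows(report: EvaluationReport, selector_name: str):
    metrics = (
        {"oa": report.oa, "kappa": report.kappa}
        if report.task == CLASSIFICATION
        else {"r2": report.r2, "rmse": report.rmse}
    )
    return [
        {
            "selector": selector_name,
            "target_size": report.target_size,
            "fold": report.fold_id,
            "metric": name,
            "value": value,
        }
        for name, value in metrics.items()
    ]


def cross_validate(
    dataset: SpectralDataset,
    selector,
    target_sizes,
    seed: int,
    n_folds: int = 10,
    selector_name: str = "bsdr",
    include_baseline: bool = True,
) -> pd.DataFrame:
    """Run the full fold protocol for each fold and target size.

    ``selector`` is a callable ``(dataset, plan, target_size, seed) -> band
    set`` run on each fold's training portion; every set is scored with
    ``evaluate_bands_svm``.  The all-bands baseline is computed once per fold
    and attached to every target size.  Returns a long-format table with
    columns ``selector, target_size, fold, metric, value``.
    """
    labels = dataset.targets if dataset.task == CLASSIFICATION else None
    rows = []
    for fold_id in range(1, n_folds + 1):
        plan = make_split_plan(dataset.n_samples, fold_id, seed, labels=labels, n_folds=n_folds)
        if include_baseline:
            all_bands = np.arange(1, dataset.n_bands + 1)
            base = evaluate_bands_svm(dataset, all_bands, plan)
            for t in target_sizes:
                base_t = EvaluationReport(**{**base.__dict__, "target_size": int(t)})
                rows.extend(_report_rows(base_t, "all_bands"))
        for t in target_sizes:
            bands = selector(dataset, plan, int(t), seed)
            report = evaluate_bands_svm(dataset, bands, plan)
            report.target_size = int(t)
            rows.extend(_report_rows(report, selector_name))
    return pd.DataFrame(rows)


def summarize_results(results: pd.DataFrame) -> pd.DataFrame:
    """Aggregate a ``cross_validate`` table to mean ± sample std per cell."""
    grouped = results.groupby(["selector", "target_size", "metric"])["value"]
    summary = grouped.agg(mean="mean", std=lambda s: s.std(ddof=1)).reset_index()
    summary["display"] = summary.apply(lambda r: f"{r['mean']:.2f} ± {r['std']:.2f}", axis=1)
    return summary


def brute_force_subset_search(
    dataset: SpectralDataset,
    t: int,
    plan: SplitPlan,
    max_subsets: int = 100_000,
):
    """Exhaustively score every t-subset of bands; the optimality oracle.

    Only feasible for tiny band universes — refuses when ``C(L, t)`` exceeds
    ``max_subsets``.  Returns ``(best_bands, best_metric)`` where the metric
    is overall accuracy (classification, maximized) or test MSE (regression,
    minimized).
    """
    from math import comb

    L = dataset.n_bands
    n_subsets = comb(L, t)
    if n_subsets > max_subsets:
        raise CombinatorialGuardError(
            f"C({L}, {t}) = {n_subsets} exceeds the guard of {max_subsets}"
        )
    best_bands, best_metric = None, None
    for subset in itertools.combinations(range(1, L + 1), t):
        report = evaluate_bands_svm(dataset, subset, plan)
        if dataset.task == CLASSIFICATION:
            metric, better = report.oa, (lambda m, b: m > b)
        else:
            metric, better = report.mse, (lambda m, b: m < b)
        if best_metric is None or better(metric, best_metric):
            best_bands, best_metric = np.asarray(subset, dtype=np.int64), metric
    return best_bands, best_metric
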