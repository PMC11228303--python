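"""Deep + radiomics feature fusion and multi-kernel SVM classification.

The fusion classifier concatenates the CNN's penultimate-FC features with
the hand-crafted radiomics vector, standardizes per feature (parameters
fitted on training data only), and classifies with a support vector
machine whose kernel (linear, polynomial, RBF) and hyperparameters are
chosen by inner stratified cross-validation on the training split.  The
outer protocol is stratified 5-fold cross-validation reporting
sensitivity, specificity, precision, accuracy, F1, AP and ROC-AUC per
fold and in aggregate.

The SVM dual optimization is delegated to scikit-learn's SVC; the kernel
functions, the selection loop and the evaluation protocol live here.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedKFold
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from . import metrics as fmetrics

__all__ = ["FusionError", "fuse_features", "kernel_eval", "MultiKernelSVC",
           "CVPlan", "cross_validate", "FusedClassifier"]


class FusionError(ValueError):
    pass


def fuse_features(deep_table: pd.DataFrame, radiomics_table: pd.DataFrame) -> pd.DataFrame:
    """Join two feature tables on ``sample_id`` and concatenate columns.

    Both tables need a ``sample_id`` column and a ``label`` column; the
    labels must agree.  Raises :class:`FusionError` naming offending ids
    on any mismatch.  Row order follows ``deep_table``.
    """
    for name, t in (("deep", deep_table), ("radiomics", radiomics_table)):
        if "sample_id" not in t.columns or "label" not in t.columns:
            raise FusionError(f"{name} table must have sample_id and label columns")
    left = deep_table.set_index("sample_id")
    right = radiomics_table.set_index("sample_id")
    missing = sorted(set(left.index).symmetric_difference(right.index))
    if missing:
        raise FusionError(f"sample_id mismatch between tables: {missing}")
    if left.index.has_duplicates or right.index.has_duplicates:
        raise FusionError("duplicate sample_id entries")
    right = right.loc[left.index]
    if not (left["label"].values == right["label"].values).all():
        bad = left.index[left["label"].values != right["label"].values].tolist()
        raise FusionError(f"label disagreement for sample_ids: {bad}")
    fused = pd.concat(
        [left.drop(columns="label").add_prefix("deep_"),
         right.drop(columns="label").add_prefix("rad_")],
        axis=1,
    )
    fused["label"] = left["label"].values
    return fused.reset_index()


def kernel_eval(kind: str, x, y, gamma: float = 1.0, coef0: float = 1.0,
                degree: int = 3) -> float:
    """Evaluate one kernel value k(x, y).

    linear: <x, y>; poly: (gamma <x, y> + coef0)^degree;
    rbf: exp(-gamma ||x - y||^2).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if kind == "linear":
        return float(x @ y)
    if kind in ("poly", "polynomial"):
        return float((gamma * (x @ y) + coef0) ** degree)
    if kind == "rbf":
        return float(np.exp(-gamma * np.sum((x - y) ** 2)))
    raise ValueError(f"unknown kernel kind {kind!r}")


def _candidate_grid(n_features: int, kernels, C_grid, gamma_grid, degree_grid,
                    coef0: float):
    """Ordered candidate list; the order encodes the tie-break (linear
    before polynomial before rbf, then smallest C first)."""
    gammas = [1.0 / n_features if g == "auto" else float(g) for g in gamma_grid]
    out = []
    for kernel in kernels:
        if kernel == "linear":
            for C in C_grid:
                out.append({"kernel": "linear", "C": C})
        elif kernel in ("poly", "polynomial"):
            for C in C_grid:
                for g in gammas:
                    for d in degree_grid:
                        out.append({"kernel": "poly", "C": C, "gamma": g,
                                    "degree": d, "coef0": coef0})
        elif kernel == "rbf":
            for C in C_grid:
                for g in gammas:
                    out.append({"kernel": "rbf", "C": C, "gamma": g})
        else:
            raise ValueError(f"unknown kernel {kernel!r}")
    return out


def _make_svc(params: dict) -> SVC:
    return SVC(**params)


class MultiKernelSVC:
    """SVM with kernel selection by inner stratified cross-validation.

    Every candidate (kernel, hyperparameters) is scored by ``inner_cv``-fold
    stratified CV accuracy on the training data only; the best candidate
    (ties broken by kernel order linear < polynomial < rbf, then smaller C)
    is refit on all training data.  ``selection_report_`` records every
    candidate's inner score; ``best_params_`` the winner.

    Standardize features upstream (see :class:`FusedClassifier`); this
    class does not scale.
    """

    def __init__(self, kernels=("linear", "poly", "rbf"), C_grid=(0.1, 1.0, 10.0),
                 gamma_grid=("auto", 0.01, 0.1), degree_grid=(2, 3), coef0=1.0,
                 inner_cv=3, seed=0):
        self.kernels = kernels
        self.C_grid = C_grid
        self.gamma_grid = gamma_grid
        self.degree_grid = degree_grid
        self.coef0 = coef0
        self.inner_cv = inner_cv
        self.seed = seed

    _param_names = ("kernels", "C_grid", "gamma_grid", "degree_grid", "coef0",
                    "inner_cv", "seed")

    def get_params(self, deep=True):
        return {k: getattr(self, k) for k in self._param_names}

    def set_params(self, **params):
        for k, v in params.items():
            if k not in self._param_names:
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        classes, counts = np.unique(y, return_counts=True)
        if classes.size < 2:
            raise ValueError("training data must contain both classes")
        if counts.min() < 2:
            raise ValueError("need >= 2 samples per class")
        candidates = _candidate_grid(X.shape[1], self.kernels, self.C_grid,
                                     self.gamma_grid, self.degree_grid, self.coef0)
        n_splits = min(self.inner_cv, int(counts.min()))
        skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=self.seed)
        splits = list(skf.split(X, y))
        report = []
        best_score, best_params = -np.inf, None
        for params in candidates:
            accs = []
            for tr, te in splits:
                clf = _make_svc(params).fit(X[tr], y[tr])
                accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
            score = float(np.mean(accs))
            report.append({**params, "inner_cv_accuracy": score})
            if score > best_score:  # strict: first best wins ties
                best_score, best_params = score, params
        self.selection_report_ = report
        self.best_params_ = best_params
        self.best_inner_score_ = best_score
        self.svc_ = _make_svc(best_params).fit(X, y)
        self.classes_ = self.svc_.classes_
        return self

    def decision_function(self, X):
        return self.svc_.decision_function(np.asarray(X, dtype=float))

    def predict(self, X):
        return self.svc_.predict(np.asarray(X, dtype=float))

    def score(self, X, y):
        return float(np.mean(self.predict(X) == np.asarray(y, dtype=int)))

    def decision_function_via_kernels(self, X) -> np.ndarray:
        """Recompute f(x) = sum_i alpha_i n_i k(m_i, x) + b from the dual
        coefficients through :func:`kernel_eval` (consistency check path,
        independent of SVC.decision_function)."""
        svc = self.svc_
        p = self.best_params_
        kind = p["kernel"]
        kw = {"gamma": p.get("gamma", 1.0), "coef0": p.get("coef0", 0.0),
              "degree": p.get("degree", 3)}
        X = np.atleast_2d(np.asarray(X, dtype=float))
        sv = svc.support_vectors_
        dual = svc.dual_coef_[0]  # alpha_i * n_i
        out = np.array([
            sum(dual[i] * kernel_eval(kind, sv[i], x, **kw) for i in range(len(sv)))
            + svc.intercept_[0]
            for x in X
        ])
        return out


class FusedClassifier:
    """Standardization + multi-kernel SVM, the per-fold training unit.

    Scaling parameters are fitted on the training data passed to ``fit``
    only, so using one instance per outer fold is leakage-free.
    """

    def __init__(self, **svc_params):
        self.svc_params = svc_params

    def fit(self, X, y):
        self.scaler_ = StandardScaler().fit(X)
        self.svm_ = MultiKernelSVC(**self.svc_params).fit(self.scaler_.transform(X), y)
        return self

    def decision_function(self, X):
        return self.svm_.decision_function(self.scaler_.transform(X))

    def predict(self, X):
        return self.svm_.predict(self.scaler_.transform(X))


@dataclass
class CVPlan:
    """Stratified k-fold plan; fold assignments are recorded on use."""

    n_folds: int = 5
    stratified: bool = True
    seed: int = 0
    assignments: np.ndarray | None = field(default=None, repr=False)

    def folds(self, labels: np.ndarray):
        labels = np.asarray(labels, dtype=int)
        if not self.stratified:
            raise NotImplementedError("only stratified folding is supported")
        counts = np.bincount(labels)
        if counts.min() < self.n_folds:
            raise ValueError("each class needs >= n_folds samples for stratification")
        skf = StratifiedKFold(n_splits=self.n_folds, shuffle=True,
                              random_state=self.seed)
        self.assignments = np.empty(len(labels), dtype=int)
        splits = []
        for k, (tr, te) in enumerate(skf.split(np.zeros(len(labels)), labels)):
            self.assignments[te] = k
            splits.append((tr, te))
        return splits


def cross_validate(features, labels, plan: CVPlan | None = None,
                   **svc_params) -> dict:
    """Outer stratified CV of the standardize + multi-kernel-SVM pipeline.

    Returns a report dict: ``folds`` (per-fold metric dicts incl. the
    selected kernel), ``aggregate`` (mean and sd of each metric) and
    ``oof_scores`` (out-of-fold decision values aligned with the input).
    """
    X = np.asarray(features, dtype=float)
    y = np.asarray(labels, dtype=int)
    plan = plan or CVPlan()
    fold_reports = []
    oof = np.full(len(y), np.nan)
    for k, (tr, te) in enumerate(plan.folds(y)):
        clf = FusedClassifier(**svc_params).fit(X[tr], y[tr])
        scores = clf.decision_function(X[te])
        oof[te] = scores
        rep = fmetrics.evaluate_scores(y[te], scores)
        d = rep.as_dict()
        d["fold"] = k
        d["selected_kernel"] = clf.svm_.best_params_["kernel"]
        d["selected_params"] = clf.svm_.best_params_
        fold_reports.append(d)
    metric_keys = ("sensitivity", "specificity", "precision", "accuracy",
                   "f1", "auc", "ap")
    aggregate = {}
    for key in metric_keys:
        vals = np.array([f[key] for f in fold_reports], dtype=float)
        aggregate[key] = {"mean": float(vals.mean()), "sd": float(vals.std(ddof=1))}
    return {"folds": fold_reports, "aggregate": aggregate, "oof_scores": oof,
            "fold_assignments": plan.assignments}
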