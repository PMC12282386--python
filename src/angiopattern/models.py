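"""Pattern classifiers: elastic-net penalized logistic regression and
random forest.

The penalized logistic model minimizes the average negative log-likelihood
plus the elastic-net penalty λ·(α‖β‖₁ + (1−α)‖β‖₂²/2) over a decreasing
λ grid anchored at λ_max (the smallest λ zeroing every slope), with λ
chosen by stratified cross-validated deviance.  Features are standardized
internally; reported coefficients are mapped back to the original scale.
Three-class problems use the symmetric multinomial likelihood.

The random forest is bagged CART with √p candidate features per split and
out-of-bag probability estimates, at the conventional 500 trees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import log_loss
from sklearn.model_selection import StratifiedKFold


@dataclass
class FitResult:
    """A fitted classifier plus the artefacts needed for reporting."""

    algorithm: str                        # "penalized_logistic" | "random_forest"
    classes: np.ndarray
    feature_names: list[str]
    estimator: object
    scaler_mean: Optional[np.ndarray] = None
    scaler_scale: Optional[np.ndarray] = None
    lambdas: Optional[np.ndarray] = None
    coef_path: Optional[np.ndarray] = None        # (n_lambda, n_classes_eff, p) standardized scale
    cv_deviance: Optional[np.ndarray] = None      # mean CV deviance per lambda
    selected_lambda: Optional[float] = None
    alpha: Optional[float] = None
    coefficients: Optional[np.ndarray] = None     # original-scale slopes
    intercept: Optional[np.ndarray] = None        # original-scale intercept
    dropped_features: list[str] = field(default_factory=list)
    oob_score: Optional[float] = None


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(float), list(X.columns)
    X = np.asarray(X, float)
    return X, [f"x{i}" for i in range(X.shape[1])]


def lambda_grid(
    X: np.ndarray,
    y_codes: np.ndarray,
    n_classes: int,
    alpha: float,
    n_lambda: int,
    lambda_min_ratio: float,
) -> np.ndarray:
    """Log-spaced λ grid from λ_max down by ``lambda_min_ratio``.

    λ_max is the smallest penalty at which all slopes are zero:
    max_j,k |x_jᵀ(1{y=k} − p̄_k)| / (n·α) on standardized features.  For
    near-ridge mixing the α in the denominator is floored to keep the
    grid finite.
    """
    n = X.shape[0]
    a = max(alpha, 1e-3)
    lam_max = 0.0
    for k in range(n_classes if n_classes > 2 else 1):
        yk = (y_codes == (k if n_classes > 2 else 1)).astype(float)
        lam_max = max(lam_max, float(np.max(np.abs(X.T @ (yk - yk.mean())))) / (n * a))
    lam_max = max(lam_max, 1e-6)
    return np.geomspace(lam_max, lam_max * lambda_min_ratio, n_lambda)


def _null_intercept(y_codes: np.ndarray, n_classes: int) -> np.ndarray:
    """Exact intercept of the slope-free (null) model: class log-odds.

    At λ ≥ λ_max every slope is zero and the likelihood is maximized by
    the class prevalences; the solver's tiny effective step keeps it from
    reaching that point, so the closed form is substituted."""
    counts = np.bincount(y_codes, minlength=n_classes).astype(float)
    p = counts / counts.sum()
    p = np.clip(p, 1e-12, 1 - 1e-12)
    if n_classes == 2:
        return np.array([np.log(p[1] / p[0])])
    logp = np.log(p)
    return logp - logp.mean()


def _fix_null_model(clf, y_codes, n_classes):
    if np.all(clf.coef_ == 0.0):
        clf.intercept_ = _null_intercept(y_codes, n_classes)


def _path_fit(X, y_codes, lambdas, alpha, tol, max_iter, seed):
    """Warm-started elastic-net path, largest λ first.

    Returns (coef path, intercept path, fitted estimators' final clone).
    """
    n = X.shape[0]
    clf = LogisticRegression(
        penalty="elasticnet",
        l1_ratio=alpha,
        solver="saga",
        warm_start=True,
        max_iter=max_iter,
        tol=tol,
        random_state=seed,
    )
    coefs, intercepts = [], []
    for lam in lambdas:
        clf.C = 1.0 / (n * lam)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", FutureWarning)
            clf.fit(X, y_codes)
        _fix_null_model(clf, y_codes, int(np.max(y_codes)) + 1)
        coefs.append(clf.coef_.copy())
        intercepts.append(clf.intercept_.copy())
    return np.array(coefs), np.array(intercepts), clf


def fit_penalized_logistic(
    X,
    y,
    alpha: float = 0.5,
    n_folds: int = 10,
    rng_seed: int = 0,
    n_lambda: int = 100,
    lambda_min_ratio: float = 1e-4,
    lambdas: Optional[np.ndarray] = None,
    selection: str = "min",
    tol: float = 1e-4,
    max_iter: int = 5000,
) -> FitResult:
    """Elastic-net logistic regression with λ chosen by cross-validation.

    ``selection`` is 'min' (λ minimizing mean CV deviance, the default) or
    '1se' (largest λ within one standard error of the minimum).  Constant
    feature columns are dropped with a warning; a single-class ``y`` is an
    error.
    """
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    classes, y_codes = np.unique(y, return_inverse=True)
    if classes.size < 2:
        raise ValueError("y must contain at least 2 classes")
    if Xm.shape[0] < n_folds:
        raise ValueError("need at least n_folds samples")

    keep = Xm.std(axis=0) > 0
    dropped = [nm for nm, k in zip(names, keep) if not k]
    if dropped:
        warnings.warn(f"dropping constant feature columns: {dropped}", stacklevel=2)
        Xm = Xm[:, keep]
        names = [nm for nm, k in zip(names, keep) if k]

    mean = Xm.mean(axis=0)
    scale = Xm.std(axis=0)
    Xs = (Xm - mean) / scale

    if lambdas is None:
        lambdas = lambda_grid(Xs, y_codes, classes.size, alpha, n_lambda, lambda_min_ratio)
    lambdas = np.asarray(lambdas, float)

    # cross-validated deviance per lambda
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=rng_seed)
    dev = np.zeros((n_folds, lambdas.size))
    for f, (tr, va) in enumerate(skf.split(Xs, y_codes)):
        n_tr = tr.size
        clf = LogisticRegression(
            penalty="elasticnet",
            l1_ratio=alpha,
            solver="saga",
            warm_start=True,
            max_iter=max_iter,
            tol=tol,
            random_state=rng_seed,
        )
        for j, lam in enumerate(lambdas):
            clf.C = 1.0 / (n_tr * lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", FutureWarning)
                clf.fit(Xs[tr], y_codes[tr])
            _fix_null_model(clf, y_codes[tr], classes.size)
            proba = clf.predict_proba(Xs[va])
            dev[f, j] = 2.0 * log_loss(y_codes[va], proba, labels=np.arange(classes.size))
    mean_dev = dev.mean(axis=0)
    if selection == "min":
        j_star = int(np.argmin(mean_dev))
    elif selection == "1se":
        se = dev.std(axis=0, ddof=1) / np.sqrt(n_folds)
        j_min = int(np.argmin(mean_dev))
        within = np.nonzero(mean_dev <= mean_dev[j_min] + se[j_min])[0]
        j_star = int(within[0])  # grid is decreasing: first index = largest lambda
    else:
        raise ValueError("selection must be 'min' or '1se'")

    coef_path, icpt_path, clf = _path_fit(Xs, y_codes, lambdas, alpha, tol, max_iter, rng_seed)
    # refit at the selected lambda (warm from the path end)
    clf.C = 1.0 / (Xs.shape[0] * lambdas[j_star])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", FutureWarning)
        clf.fit(Xs, y_codes)
    _fix_null_model(clf, y_codes, classes.size)

    coef_orig = clf.coef_ / scale
    icpt_orig = clf.intercept_ - coef_orig @ mean
    return FitResult(
        algorithm="penalized_logistic",
        classes=classes,
        feature_names=names,
        estimator=clf,
        scaler_mean=mean,
        scaler_scale=scale,
        lambdas=lambdas,
        coef_path=coef_path,
        cv_deviance=mean_dev,
        selected_lambda=float(lambdas[j_star]),
        alpha=alpha,
        coefficients=coef_orig,
        intercept=icpt_orig,
        dropped_features=dropped,
    )


def fit_random_forest(
    X,
    y,
    n_trees: int = 500,
    rng_seed: int = 0,
) -> FitResult:
    """Seeded bagged-tree ensemble with out-of-bag probability estimates."""
    Xm, names = _as_matrix(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("y must contain at least 2 classes")
    rf = RandomForestClassifier(
        n_estimators=n_trees,
        max_features="sqrt",
        oob_score=True,
        random_state=rng_seed,
        n_jobs=1,
    )
    rf.fit(Xm, y)
    return FitResult(
        algorithm="random_forest",
        classes=rf.classes_,
        feature_names=names,
        estimator=rf,
        oob_score=float(rf.oob_score_),
    )


def predict_proba(fit: FitResult, X) -> np.ndarray:
    """Class-probability matrix with columns in ``fit.classes`` order."""
    Xm, names = _as_matrix(X)
    if fit.dropped_features:
        keep = [i for i, nm in enumerate(names) if nm not in fit.dropped_features]
        Xm = Xm[:, keep]
        names = [names[i] for i in keep]
    if names != fit.feature_names and len(names) != len(fit.feature_names):
        raise ValueError("feature columns do not match the fitted model")
    if isinstance(X, pd.DataFrame) and names != fit.feature_names:
        raise ValueError("feature columns do not match the fitted model")
    if fit.algorithm == "penalized_logistic":
        Xm = (Xm - fit.scaler_mean) / fit.scaler_scale
    return fit.estimator.predict_proba(Xm)


def predict(fit: FitResult, X) -> np.ndarray:
    """Predicted labels: argmax of :func:`predict_proba` (0.5 threshold
    in the binary case)."""
    proba = predict_proba(fit, X)
    return fit.classes[np.argmax(proba, axis=1)]
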