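"""Confusion metrics, ROC/AUC and the repeated-split evaluation harness.

Three classification tasks mirror the clinical reading workflow: *focal vs. diffuse*
uses only vessels with those two labels; *focal vs. non-focal* pools
diffuse, mixed and serial into the negative class; *three-class* pools
mixed and serial into "others".  Each evaluation iteration draws a
stratified 75/25 split, refits MFPCA and the classifier on the training
vessels only, and scores the held-out test set; summaries over iterations
report the mean and a 95% percentile interval per metric.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .cohort import Cohort
from .curves import VesselRecord
from .features import ENCODED_COLUMNS_MUFR, ENCODED_COLUMNS_PPGI
from .fpca import fit_mfpca, register_curves, transform
from .indices import PPGI_CUTOFF, compute_ppgi, max_local_gradient, vessel_flags
from .models import FitResult, fit_penalized_logistic, fit_random_forest, predict, predict_proba

logger = logging.getLogger(__name__)

TASKS = ("focal_vs_diffuse", "focal_vs_nonfocal", "three_class")

#: evaluation methods: classification rule x feature set
METHODS = ("ppgi_cutoff", "plr_mufr", "plr_ppgi", "rf_mufr", "rf_ppgi")

#: elastic-net settings used inside the repeated-split harness: a 30-point
#: λ grid to 1e-3·λ_max with 5-fold CV is ample for model selection at
#: n ≈ 200–350 and keeps a 500-iteration run tractable on one CPU
HARNESS_PLR_OPTS = {"n_lambda": 30, "lambda_min_ratio": 1e-3, "n_folds": 5}


def round_pct(x: float) -> int:
    """Percentage rounding, half away from zero (0.525 -> 53%)."""
    return int(math.floor(100.0 * x + 0.5)) if x >= 0 else -round_pct(-x)


@dataclass(frozen=True)
class ConfusionMatrix:
    """k x k counts; rows are truth, columns are prediction."""

    counts: np.ndarray
    class_order: tuple[str, ...]

    def __post_init__(self):
        c = np.asarray(self.counts, int)
        object.__setattr__(self, "counts", c)
        k = len(self.class_order)
        if c.shape != (k, k) or np.any(c < 0):
            raise ValueError("counts must be a k x k non-negative matrix")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


def confusion_from_predictions(y_true, y_pred, class_order: Sequence[str]) -> ConfusionMatrix:
    order = list(class_order)
    idx = {c: i for i, c in enumerate(order)}
    counts = np.zeros((len(order), len(order)), int)
    for t, p in zip(y_true, y_pred):
        counts[idx[t], idx[p]] += 1
    return ConfusionMatrix(counts=counts, class_order=tuple(order))


def confusion_metrics(cm: ConfusionMatrix, positive_class: str) -> dict[str, float]:
    """Binary accuracy, sensitivity, specificity, PPV and NPV.

    Ratios with zero denominators are reported as NaN, never as 0.
    """
    if cm.counts.shape != (2, 2):
        raise ValueError("confusion_metrics requires a 2x2 matrix")
    if positive_class not in cm.class_order:
        raise ValueError(f"{positive_class!r} not in {cm.class_order}")
    p = cm.class_order.index(positive_class)
    n = 1 - p
    tp, fn = cm.counts[p, p], cm.counts[p, n]
    fp, tn = cm.counts[n, p], cm.counts[n, n]

    def ratio(num, den):
        return float(num) / den if den > 0 else float("nan")

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def roc_auc(scores, labels) -> float:
    """AUC via the tie-corrected Mann–Whitney rank formula.

    Equals the trapezoid area under the empirical ROC curve; ``labels``
    are binary truth (1 = positive).
    """
    scores = np.asarray(scores, float)
    labels = np.asarray(labels).astype(bool)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute an AUC")
    ranks = rankdata(scores)
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def one_vs_rest_auc(
    prob_matrix: np.ndarray, labels, class_order: Sequence[str]
) -> dict[str, float]:
    """Per-class AUC of each class's probability column against the rest."""
    labels = np.asarray(labels)
    out = {}
    for j, cls in enumerate(class_order):
        y = labels == cls
        if y.all() or not y.any():
            raise ValueError(f"class {cls!r} missing from labels")
        out[cls] = roc_auc(prob_matrix[:, j], y)
    return out


def _round_half_away(x: float) -> int:
    return int(math.floor(x + 0.5))


def split_labels(
    labels: Sequence[str],
    train_fraction: float = 0.75,
    stratify: bool = True,
    rng_seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Index split reproducible by seed; per-stratum train size is
    round(train_fraction * n_stratum), half away from zero."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(rng_seed)
    if not stratify:
        idx = rng.permutation(labels.size)
        n_train = _round_half_away(train_fraction * labels.size)
        return np.sort(idx[:n_train]), np.sort(idx[n_train:])
    train, test = [], []
    for cls in np.unique(labels):
        members = np.nonzero(labels == cls)[0]
        if members.size < 2:
            raise ValueError(f"stratum {cls!r} has fewer than 2 members")
        perm = rng.permutation(members)
        n_train = _round_half_away(train_fraction * members.size)
        train.extend(perm[:n_train])
        test.extend(perm[n_train:])
    return np.sort(np.array(train, int)), np.sort(np.array(test, int))


def split_data(
    records: Sequence[VesselRecord],
    train_fraction: float = 0.75,
    stratify: bool = True,
    rng_seed: int = 0,
) -> tuple[list[VesselRecord], list[VesselRecord]]:
    """Split vessel records 75/25, stratified by pattern label by default."""
    if not records:
        raise ValueError("dataset must be non-empty")
    labels = [r.label for r in records]
    tr, te = split_labels(labels, train_fraction, stratify, rng_seed)
    recs = list(records)
    return [recs[i] for i in tr], [recs[i] for i in te]


# ---------------------------------------------------------------------------
# task plumbing

def task_label(label: str, task: str) -> Optional[str]:
    """Map a four-class pattern label to the task's label space.

    Returns None for vessels excluded from the task (mixed/serial in
    focal vs. diffuse).
    """
    if task == "focal_vs_diffuse":
        return label if label in ("focal", "diffuse") else None
    if task == "focal_vs_nonfocal":
        return "focal" if label == "focal" else "nonfocal"
    if task == "three_class":
        return label if label in ("focal", "diffuse") else "others"
    raise ValueError(f"unknown task {task!r}")


def task_classes(task: str) -> tuple[str, ...]:
    return {
        "focal_vs_diffuse": ("focal", "diffuse"),
        "focal_vs_nonfocal": ("focal", "nonfocal"),
        "three_class": ("focal", "diffuse", "others"),
    }[task]


@dataclass
class EvaluationReport:
    """Per-iteration metrics with mean and 95% CI summaries."""

    task: str
    method: str
    per_iteration: pd.DataFrame
    summary: pd.DataFrame  # index: metric; columns: mean, ci_low, ci_high
    n_iterations: int
    seeds: list[int]
    n_redraws: int = 0


def _summarize(per_iter: pd.DataFrame, ci: str = "percentile") -> pd.DataFrame:
    rows = {}
    for col in per_iter.columns:
        vals = per_iter[col].dropna().to_numpy()
        if vals.size == 0:
            rows[col] = (float("nan"),) * 3
            continue
        mean = float(vals.mean())
        if ci == "percentile":
            lo, hi = np.percentile(vals, [2.5, 97.5])
        else:  # normal approximation
            half = 1.96 * vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            lo, hi = mean - half, mean + half
        rows[col] = (mean, float(lo), float(hi))
    return pd.DataFrame(rows, index=["mean", "ci_low", "ci_high"]).T


@dataclass
class _Prepared:
    """Task-filtered cohort with cached per-vessel scalar features."""

    records: list[VesselRecord]
    labels: np.ndarray          # task label space
    strata: np.ndarray          # original pattern labels (stratification)
    ppgi: np.ndarray
    scalar_block: np.ndarray    # encoded non-score, non-ppgi feature columns
    covariates: dict


def prepare_task(cohort: Cohort, task: str) -> _Prepared:
    """Drop excluded vessels, map labels and precompute scalar features."""
    records, labels, strata, ppgi, block = [], [], [], [], []
    for rec in cohort.records:
        if vessel_flags(rec)["no_functional_disease"]:
            continue
        t = task_label(rec.label, task)
        if t is None:
            continue
        cov = cohort.covariates[rec.patient_id]
        records.append(rec)
        labels.append(t)
        strata.append(rec.label)
        ppgi.append(compute_ppgi(rec.curve).ppgi)
        block.append(
            [
                cov.age,
                int(cov.sex == "male"),
                int(cov.smoking == "current"),
                int(cov.smoking == "previous"),
                int(cov.diabetes),
                int(cov.dyslipidaemia),
                int(cov.hypertension),
                rec.reference_diameter,
                rec.distal_mufr,
                max_local_gradient(rec.curve),
            ]
        )
    return _Prepared(
        records=records,
        labels=np.array(labels),
        strata=np.array(strata),
        ppgi=np.array(ppgi),
        scalar_block=np.array(block).reshape(len(records), 10),
        covariates=cohort.covariates,
    )


def _feature_frame(prep: _Prepared, idx: np.ndarray, scores: np.ndarray, include_ppgi: bool) -> pd.DataFrame:
    """Assemble the encoded design matrix from cached scalars plus scores."""
    blk = prep.scalar_block[idx]
    cols = {
        "age": blk[:, 0],
        "sex_male": blk[:, 1],
        "smoking_current": blk[:, 2],
        "smoking_previous": blk[:, 3],
        "diabetes": blk[:, 4],
        "dyslipidaemia": blk[:, 5],
        "hypertension": blk[:, 6],
        "score1": scores[:, 0],
        "score2": scores[:, 1],
        "score3": scores[:, 2],
        "reference_diameter": blk[:, 7],
        "distal_mufr": blk[:, 8],
        "d_mufr_ds": blk[:, 9],
    }
    if include_ppgi:
        cols["ppgi"] = prep.ppgi[idx]
    order = ENCODED_COLUMNS_PPGI if include_ppgi else ENCODED_COLUMNS_MUFR
    return pd.DataFrame(cols)[list(order)]


def _fit_method(method: str, Xtr, ytr, seed: int, plr_opts: dict, rf_opts: dict) -> FitResult:
    if method.startswith("plr"):
        return fit_penalized_logistic(Xtr, ytr, rng_seed=seed, **plr_opts)
    return fit_random_forest(Xtr, ytr, rng_seed=seed, **rf_opts)


def evaluate_split(
    prep: _Prepared,
    task: str,
    methods: Sequence[str],
    rng_seed: int,
    n_grid: int = 101,
    plr_opts: Optional[dict] = None,
    rf_opts: Optional[dict] = None,
) -> Optional[dict[str, dict]]:
    """One stratified split, fit and test; None if the test set is degenerate.

    MFPCA and feature standardization are fitted on the training vessels
    only and applied to the held-out set, so test labels and curves never
    influence the fitted models.
    """
    plr_opts = dict(HARNESS_PLR_OPTS if plr_opts is None else plr_opts)
    rf_opts = dict(rf_opts or {})
    tr, te = split_labels(prep.strata, 0.75, True, rng_seed)
    ytr, yte = prep.labels[tr], prep.labels[te]
    classes = task_classes(task)
    if set(classes) - set(ytr) or set(classes) - set(yte):
        return None

    rec_tr = [prep.records[i] for i in tr]
    rec_te = [prep.records[i] for i in te]
    sample_tr = register_curves(rec_tr, n_grid=n_grid)
    model = fit_mfpca(sample_tr, n_components=3)
    scores_tr = transform(model, sample_tr)
    scores_te = transform(model, register_curves(rec_te, n_grid=n_grid))

    out = {}
    frames = {}
    for method in methods:
        if method == "ppgi_cutoff":
            if task == "three_class":
                raise ValueError("the PPGi cut-off rule is binary only")
            neg = "diffuse" if task == "focal_vs_diffuse" else "nonfocal"
            y_pred = np.where(prep.ppgi[te] >= PPGI_CUTOFF, "focal", neg)
            proba = None
        else:
            include_ppgi = method.endswith("_ppgi")
            if include_ppgi not in frames:
                frames[include_ppgi] = (
                    _feature_frame(prep, tr, scores_tr, include_ppgi),
                    _feature_frame(prep, te, scores_te, include_ppgi),
                )
            Xtr, Xte = frames[include_ppgi]
            fit = _fit_method(method, Xtr, ytr, rng_seed, plr_opts, rf_opts)
            proba = predict_proba(fit, Xte)
            y_pred = fit.classes[np.argmax(proba, axis=1)]
        cm = confusion_from_predictions(yte, y_pred, classes)
        entry: dict = {"confusion": cm, "y_true": yte, "y_pred": y_pred}
        if len(classes) == 2:
            entry["metrics"] = confusion_metrics(cm, positive_class="focal")
            if proba is not None:
                j = list(
                    fit.classes
                ).index("focal")
                entry["metrics"]["auc"] = roc_auc(proba[:, j], yte == "focal")
                entry["proba_focal"] = proba[:, j]
        else:
            acc = float(np.mean(yte == y_pred))
            entry["metrics"] = {"accuracy": acc}
            if proba is not None:
                cols = [list(fit.classes).index(c) for c in classes]
                aucs = one_vs_rest_auc(proba[:, cols], yte, classes)
                for c in classes:
                    p_idx = classes.index(c)
                    y_bin = yte == c
                    pred_bin = y_pred == c
                    tp = int(np.sum(y_bin & pred_bin))
                    fn = int(np.sum(y_bin & ~pred_bin))
                    fp = int(np.sum(~y_bin & pred_bin))
                    tn = int(np.sum(~y_bin & ~pred_bin))
                    entry["metrics"][f"sensitivity_{c}"] = tp / (tp + fn) if tp + fn else float("nan")
                    entry["metrics"][f"specificity_{c}"] = tn / (tn + fp) if tn + fp else float("nan")
                    entry["metrics"][f"auc_{c}"] = aucs[c]
                entry["proba"] = proba[:, cols]
        out[method] = entry
    return out


def repeat_evaluate(
    cohort: Cohort,
    task: str,
    methods: Sequence[str] = ("ppgi_cutoff", "plr_mufr", "plr_ppgi"),
    n_iterations: int = 500,
    base_seed: int = 0,
    ci: str = "percentile",
    n_grid: int = 101,
    plr_opts: Optional[dict] = None,
    rf_opts: Optional[dict] = None,
) -> dict[str, EvaluationReport]:
    """Repeated 75/25 split evaluation.

    Iteration i uses seed ``base_seed + i``; test sets missing a class are
    re-drawn with a logged count so ``n_iterations`` stays fixed.  Returns
    one report per method (methods share the splits and MFPCA fits).
    """
    prep = prepare_task(cohort, task)
    rows: dict[str, list] = {m: [] for m in methods}
    seeds, n_redraws = [], 0
    for i in range(n_iterations):
        seed = (base_seed + i) % (2**31)
        result = evaluate_split(prep, task, methods, seed, n_grid, plr_opts, rf_opts)
        attempt = 0
        while result is None:
            n_redraws += 1
            attempt += 1
            seed = (base_seed + i + attempt * 1_000_003) % (2**31)
            result = evaluate_split(prep, task, methods, seed, n_grid, plr_opts, rf_opts)
        seeds.append(seed)
        for m in methods:
            rows[m].append(result[m]["metrics"])
    if n_redraws:
        logger.info("re-drew %d degenerate test sets", n_redraws)
    reports = {}
    for m in methods:
        per_iter = pd.DataFrame(rows[m])
        reports[m] = EvaluationReport(
            task=task,
            method=m,
            per_iteration=per_iter,
            summary=_summarize(per_iter, ci=ci),
            n_iterations=n_iterations,
            seeds=seeds,
            n_redraws=n_redraws,
        )
    return reports
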