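"""Repeated stratified 5-fold cross-validation and result aggregation.

One *iteration* shuffles the cohort into k stratified folds and performs k
*runs*: each run fits the full Bayesian ensemble on the training folds (the
cost grid is recomputed from scratch for that training set) and predicts the
held-out fold, so every subject is predicted exactly once per iteration.
Iteration metrics are computed on these pooled out-of-fold predictions.

Per-voxel coefficients are pooled bottom-up: beta_R per run (posterior-
weighted within the ensemble), beta_I = mean of the k beta_R per iteration,
and across iterations the mean beta_mu, the population standard deviation
beta_sigma (divide by N, not N-1), and the strict sign counts beta_plus /
beta_minus (exact zeros belong to neither count). Negative coefficients mark
voxels where controls have higher intensities than patients.

Iteration t of an experiment uses seed base_seed + t; running two feature
tables ("measures") of the same subjects with the same base seed therefore
pairs their fold allocations, which is what makes per-iteration win counts
between measures meaningful.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ensemble import SubjectPrediction, ensemble_predict, fit_ensemble
from .volumes import CohortFeatureTable, PATIENT

__all__ = [
    "FoldPlan",
    "ClassificationMetrics",
    "IterationResult",
    "ExperimentResult",
    "stratified_folds",
    "compute_metrics",
    "run_iteration",
    "run_experiment",
    "compare_measures",
]


@dataclass
class FoldPlan:
    k: int
    assignment: np.ndarray  # per-subject fold index in 0..k-1
    seed: int


@dataclass
class ClassificationMetrics:
    """Confusion-matrix summaries with patient as the positive class."""

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    f1: float
    sensitivity: float
    specificity: float

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "f1": self.f1,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "tp": self.tp,
            "fp": self.fp,
            "tn": self.tn,
            "fn": self.fn,
        }


@dataclass
class IterationResult:
    metrics: ClassificationMetrics
    correct: np.ndarray  # per-subject bool, aligned with the table's row order
    beta_iteration: np.ndarray  # mean of the k per-run beta_R
    seed: int


@dataclass
class ExperimentResult:
    """Aggregates of a repeated stratified-CV experiment on one feature table."""

    measure_tag: str
    subject_ids: list[str]
    labels: np.ndarray
    n_iterations: int
    k: int
    base_seed: int
    seeds: np.ndarray
    metrics: pd.DataFrame  # one row per iteration
    misclassification_counts: np.ndarray  # per subject, over iterations
    beta_mean: np.ndarray
    beta_sd: np.ndarray  # population SD (divide by N)
    beta_pos_count: np.ndarray  # iterations with beta_I > 0, per voxel
    beta_neg_count: np.ndarray  # iterations with beta_I < 0, per voxel
    voxel_index_map: np.ndarray

    def coefficient_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "voxel_index": self.voxel_index_map,
                "beta_mean": self.beta_mean,
                "beta_sd": self.beta_sd,
                "beta_pos_count": self.beta_pos_count,
                "beta_neg_count": self.beta_neg_count,
            }
        )


def stratified_folds(labels: np.ndarray, k: int, seed: int) -> FoldPlan:
    """Shuffle each class and deal round-robin into k folds.

    Per-class fold sizes differ by at most one, preserving the
    patient-to-control ratio across folds.
    """
    labels = np.asarray(labels)
    rng = np.random.default_rng(seed)
    assignment = np.full(len(labels), -1, dtype=int)
    for cls in np.unique(labels):
        members = np.flatnonzero(labels == cls)
        if len(members) < k:
            raise ValueError(
                f"class {cls} has {len(members)} members, fewer than k={k} folds"
            )
        shuffled = rng.permutation(members)
        for fold in range(k):
            assignment[shuffled[fold::k]] = fold
    return FoldPlan(k, assignment, seed)


def compute_metrics(predictions: list[SubjectPrediction]) -> ClassificationMetrics:
    """Accuracy, F1, sensitivity, specificity from pooled predictions."""
    if not predictions:
        raise ValueError("no predictions to score")
    y_true = np.array([p.true_label for p in predictions])
    y_pred = np.array([p.predicted_label for p in predictions])
    tp = int(np.sum((y_true == PATIENT) & (y_pred == PATIENT)))
    fn = int(np.sum((y_true == PATIENT) & (y_pred != PATIENT)))
    tn = int(np.sum((y_true != PATIENT) & (y_pred != PATIENT)))
    fp = int(np.sum((y_true != PATIENT) & (y_pred == PATIENT)))
    accuracy = (tp + tn) / len(predictions)
    if tp + fn == 0:
        warnings.warn("no patients present: sensitivity undefined", stacklevel=2)
        sensitivity = float("nan")
    else:
        sensitivity = tp / (tp + fn)
    if tn + fp == 0:
        warnings.warn("no controls present: specificity undefined", stacklevel=2)
        specificity = float("nan")
    else:
        specificity = tn / (tn + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) > 0 else float("nan")
    return ClassificationMetrics(tp, fp, tn, fn, accuracy, f1, sensitivity, specificity)


def run_iteration(
    table: CohortFeatureTable, k: int, seed: int, standardize: bool = False
) -> IterationResult:
    """One stratified k-fold pass: k ensembles, pooled out-of-fold predictions."""
    plan = stratified_folds(table.labels, k, seed)
    correct = np.zeros(table.n_subjects, dtype=bool)
    predictions: list[SubjectPrediction] = []
    betas = []
    for fold in range(k):
        test_rows = np.flatnonzero(plan.assignment == fold)
        train_rows = np.flatnonzero(plan.assignment != fold)
        try:
            ens = fit_ensemble(table.subset(train_rows), standardize=standardize)
        except Exception as exc:  # annotate with the failing fold
            raise RuntimeError(f"ensemble fit failed on fold {fold}: {exc}") from exc
        preds = ensemble_predict(ens, table.subset(test_rows))
        for row, pred in zip(test_rows, preds):
            correct[row] = pred.correct
        predictions.extend(preds)
        betas.append(ens.run_coefficients)
    beta_iteration = np.mean(betas, axis=0)
    return IterationResult(compute_metrics(predictions), correct, beta_iteration, seed)


def run_experiment(
    table: CohortFeatureTable,
    n_iterations: int = 1000,
    base_seed: int = 0,
    k: int = 5,
    standardize: bool = False,
) -> ExperimentResult:
    """Repeat the stratified-CV pipeline and aggregate metrics and coefficients."""
    if n_iterations < 1:
        raise ValueError("n_iterations must be >= 1")
    seeds = base_seed + np.arange(n_iterations)
    rows = []
    miscls = np.zeros(table.n_subjects, dtype=int)
    p = table.n_voxels
    beta_sum = np.zeros(p)
    beta_sq_sum = np.zeros(p)
    pos = np.zeros(p, dtype=int)
    neg = np.zeros(p, dtype=int)
    for t, seed in enumerate(seeds):
        it = run_iteration(table, k, int(seed), standardize=standardize)
        rows.append({"iteration": t, "seed": int(seed), **it.metrics.as_dict()})
        miscls += ~it.correct
        beta_sum += it.beta_iteration
        beta_sq_sum += it.beta_iteration**2
        pos += it.beta_iteration > 0
        neg += it.beta_iteration < 0
    beta_mean = beta_sum / n_iterations
    # population variance; clamp tiny negative rounding residue
    var = np.maximum(beta_sq_sum / n_iterations - beta_mean**2, 0.0)
    return ExperimentResult(
        table.measure_tag,
        table.subject_ids,
        table.labels,
        n_iterations,
        k,
        base_seed,
        seeds,
        pd.DataFrame(rows),
        miscls,
        beta_mean,
        np.sqrt(var),
        pos,
        neg,
        table.voxel_index_map,
    )


def compare_measures(results: dict[str, ExperimentResult]) -> pd.DataFrame:
    """Per-iteration wins between measures run on paired fold allocations.

    Requires identical subjects and identical iteration seeds across the
    measures (the comparison is meaningless otherwise). Returns one row per
    iteration with each measure's accuracy and F1 plus the strict winner of
    each metric ('tie' when equal); win totals live in ``df.attrs['wins']``.
    """
    if len(results) < 2:
        raise ValueError("need at least two measures to compare")
    names = list(results)
    first = results[names[0]]
    for name in names[1:]:
        r = results[name]
        if r.subject_ids != first.subject_ids:
            raise ValueError(f"measure {name}: subject lists differ; comparison must be paired")
        if not np.array_equal(r.seeds, first.seeds):
            raise ValueError(f"measure {name}: iteration seeds differ; comparison must be paired")
    out = pd.DataFrame({"iteration": np.arange(first.n_iterations)})
    for metric in ("accuracy", "f1"):
        vals = np.column_stack([results[n].metrics[metric].to_numpy() for n in names])
        for j, n in enumerate(names):
            out[f"{metric}_{n}"] = vals[:, j]
        best = vals.argmax(axis=1)
        strict = vals.max(axis=1) > np.partition(vals, -2, axis=1)[:, -2]
        out[f"{metric}_winner"] = np.where(strict, np.array(names)[best], "tie")
    out.attrs["wins"] = {
        metric: {
            n: int((out[f"{metric}_winner"] == n).sum()) for n in names + ["tie"]
        }
        for metric in ("accuracy", "f1")
    }
    return out
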