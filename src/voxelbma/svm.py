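"""Probabilistic linear SVMs: soft-margin fit, logistic link, training fit score.

Each ensemble member is an ordinary soft-margin linear SVM at cost C whose
real-valued decision score s(x) = w·x + b (patients on the positive side) is
mapped to a patient probability through a logistic link p = 1/(1 + e^(-s)).
The quality of the fit on the training set is the Bernoulli log-likelihood
of the training labels under those probabilities, which downstream becomes
the model evidence in the Bayesian weighting.

The link is deliberately parameter-free: the log-likelihood must be a pure
function of the SVM fit so that models at different costs are comparable.
A Platt-style calibrated link (a, b fitted on training scores) is available
via ``link="platt"`` for sensitivity analysis, not as the default.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.svm import SVC

from .volumes import CohortFeatureTable, PATIENT

__all__ = [
    "ProbabilisticSVMModel",
    "fit_linear_svm",
    "predict_probability",
    "training_log_likelihood",
    "training_error_count",
]

PROB_EPS = 1e-12  # clip probabilities to keep the log-likelihood finite
SOLVER_TOL = 1e-6
SOLVER_MAX_ITER = 10_000_000

LinkKind = Literal["logistic", "platt"]


@dataclass
class ProbabilisticSVMModel:
    """A fitted linear SVM at one cost value with a score-to-probability link."""

    cost: float
    coefficients: np.ndarray  # per-voxel weight vector
    intercept: float
    link: LinkKind = "logistic"
    # Platt parameters p = 1/(1+exp(-(a*s + b))); identity (1, 0) for the plain link.
    link_a: float = 1.0
    link_b: float = 0.0

    def score(self, X: np.ndarray) -> np.ndarray:
        """Decision score w·x + b for each row of X."""
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.coefficients.shape[0]:
            raise ValueError(
                f"feature length {X.shape[1]} does not match model's "
                f"{self.coefficients.shape[0]} voxels"
            )
        return X @ self.coefficients + self.intercept


def _fit_svc_precomputed(
    gram: np.ndarray, X: np.ndarray, y: np.ndarray, cost: float
) -> tuple[np.ndarray, float]:
    """Solve the soft-margin dual on a precomputed linear Gram matrix.

    The Gram matrix is shared across the many cost values evaluated on one
    training set; the recovered primal (w, b) is identical to a direct
    linear-kernel fit.
    """
    clf = SVC(kernel="precomputed", C=cost, tol=SOLVER_TOL, max_iter=SOLVER_MAX_ITER)
    clf.fit(gram, y)
    if clf.fit_status_ != 0:
        raise RuntimeError(f"SVM solver did not converge at cost {cost}")
    w = clf.dual_coef_[0] @ X[clf.support_]
    return w, float(clf.intercept_[0])


def fit_linear_svm(
    train: CohortFeatureTable,
    cost: float,
    link: LinkKind = "logistic",
    standardize: bool = False,
    _gram: np.ndarray | None = None,
) -> ProbabilisticSVMModel:
    """Fit a soft-margin linear SVM at the given cost.

    Deterministic for fixed input: the convex dual is solved to tolerance
    1e-6 with an iteration cap that raises on non-convergence. With
    ``standardize`` the features are z-scored using training-row statistics
    and the model is folded back to the original scale. ``_gram`` lets a
    caller reuse X @ X.T across cost values.
    """
    if cost <= 0:
        raise ValueError(f"cost must be positive, got {cost}")
    y = train.labels
    if len(np.unique(y)) < 2:
        raise ValueError("training set must contain both classes")
    X = train.matrix
    mu = sigma = None
    if standardize:
        mu = X.mean(axis=0)
        sigma = X.std(axis=0)
        sigma[sigma == 0] = 1.0
        X = (X - mu) / sigma
        _gram = None
    if _gram is None:
        _gram = X @ X.T
    w, b = _fit_svc_precomputed(_gram, X, y, cost)
    if standardize:
        w = w / sigma
        b = b - float(w @ mu)
    model = ProbabilisticSVMModel(float(cost), w, b, link)
    if link == "platt":
        s = model.score(train.matrix).reshape(-1, 1)
        lr = LogisticRegression(C=1e6, tol=1e-8).fit(s, y)
        model.link_a = float(lr.coef_[0, 0])
        model.link_b = float(lr.intercept_[0])
    return model


def predict_probability(model: ProbabilisticSVMModel, X: np.ndarray) -> np.ndarray:
    """Patient probability via the logistic link; strictly inside (0, 1)."""
    s = model.score(X)
    if model.link == "platt":
        s = model.link_a * s + model.link_b
    with np.errstate(over="ignore"):
        p = 1.0 / (1.0 + np.exp(-s))
    return np.clip(p, PROB_EPS, 1.0 - PROB_EPS)


def training_log_likelihood(
    model: ProbabilisticSVMModel, train: CohortFeatureTable
) -> float:
    """Bernoulli log-likelihood of the training labels, LL <= 0."""
    p = predict_probability(model, train.matrix)
    y = train.labels
    return float(np.sum(y * np.log(p) + (1 - y) * np.log(1.0 - p)))


def training_error_count(model: ProbabilisticSVMModel, train: CohortFeatureTable) -> int:
    """Training subjects on the wrong side of the boundary.

    A score of exactly 0 predicts control, mirroring the strict ``> 0.5``
    rule used for the ensemble's probability threshold.
    """
    pred = (model.score(train.matrix) > 0).astype(int)
    return int(np.sum(pred != (train.labels == PATIENT)))


def model_to_dict(model: ProbabilisticSVMModel) -> dict:
    """JSON-serializable export of one fitted model."""
    return {
        "cost": model.cost,
        "intercept": model.intercept,
        "coefficients": model.coefficients.tolist(),
        "link": {"kind": model.link, "a": model.link_a, "b": model.link_b},
    }
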