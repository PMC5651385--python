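"""Bayesian model averaging over the cost grid.

Nineteen linear SVMs, one per grid cost, are combined by posterior model
weights p(C|D) = L(D|C) p(C) / p(D):

* the prior p(C) is a Gaussian centered at C_mu with standard deviation
  Delta/2, evaluated at the unclipped grid positions C_mu + Delta*i/9 and
  normalized — equivalently w(i) ∝ exp(-2 (i/9)^2), a fixed shape that
  down-weights the strongly-fitting high-cost models to guard against
  overfitting on small cohorts;
* the likelihood L(D|C) = exp(LL(D|C)) comes from each model's training
  log-likelihood; with ~50 training subjects exp(LL) underflows, so the
  posterior is computed in log space and the evidence p(D) is reported on a
  shifted scale (the posterior is shift-invariant);
* a test subject's decision statistic is the posterior-weighted average of
  the member probabilities, H = sum_c p(C=c|D) p(patient|C=c, D, x), with
  "patient" predicted iff H > 0.5 (exactly 0.5 predicts control);
* per-voxel coefficients are pooled the same way: beta_R = sum_c
  p(C=c|D) beta_{C=c}.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .costgrid import (
    GRID_OFFSETS,
    CostFitter,
    CostGrid,
    build_cost_grid,
    find_c_max,
    find_c_mu,
)
from .svm import ProbabilisticSVMModel, predict_probability, training_log_likelihood
from .volumes import CohortFeatureTable

__all__ = [
    "EnsembleModel",
    "SubjectPrediction",
    "prior_weights",
    "posterior_weights",
    "fit_ensemble",
    "ensemble_predict",
    "aggregate_run_coefficients",
]

NORMALIZATION_ATOL = 1e-12


@dataclass
class SubjectPrediction:
    subject_id: str
    ensemble_probability: float
    predicted_label: int  # patient iff ensemble_probability > 0.5
    true_label: int

    @property
    def correct(self) -> bool:
        return self.predicted_label == self.true_label


@dataclass
class EnsembleModel:
    """The 19 fitted members with prior, likelihoods, posterior and evidence."""

    grid: CostGrid
    models: list[ProbabilisticSVMModel]
    prior: np.ndarray
    log_likelihoods: np.ndarray
    likelihood: np.ndarray  # exp(LL - log_shift)
    posterior: np.ndarray
    evidence: float  # p(D) on the shifted scale: sum(likelihood * prior)
    log_shift: float  # max LL; true log p(D) = log(evidence) + log_shift
    run_coefficients: np.ndarray  # posterior-weighted beta vector

    def to_dict(self) -> dict:
        return {
            "grid": self.grid.to_dict(),
            "prior": self.prior.tolist(),
            "log_likelihoods": self.log_likelihoods.tolist(),
            "posterior": self.posterior.tolist(),
            "evidence_shifted": self.evidence,
            "log_shift": self.log_shift,
        }


def prior_weights(grid: CostGrid) -> np.ndarray:
    """Normalized Gaussian prior over the 19 grid points.

    Evaluated at the unclipped formula positions, where the exponent
    -(Delta*i/9)^2 / (2 (Delta/2)^2) collapses to -2 (i/9)^2: the weight
    pattern is the same for every grid and clipping never distorts it. A
    degenerate grid (Delta = 0, all members identical) gets uniform weights
    with a warning.
    """
    if grid.delta == 0:
        warnings.warn(
            "degenerate cost grid (delta = 0): all 19 models are identical; "
            "using uniform prior weights",
            stacklevel=2,
        )
        return np.full(len(GRID_OFFSETS), 1.0 / len(GRID_OFFSETS))
    w = np.exp(-2.0 * (GRID_OFFSETS / 9.0) ** 2)
    return w / w.sum()


def posterior_weights(
    prior: np.ndarray, log_likelihoods: np.ndarray
) -> tuple[np.ndarray, float, float]:
    """Posterior model weights L(D|C) p(C) / p(D), computed in log space.

    Returns ``(posterior, evidence, log_shift)`` where ``evidence`` is
    p(D) on the scale shifted by ``log_shift = max(LL)``; the posterior is
    exact and invariant to uniform LL shifts.
    """
    prior = np.asarray(prior, dtype=float)
    ll = np.asarray(log_likelihoods, dtype=float)
    if not np.isclose(prior.sum(), 1.0, atol=1e-9):
        raise ValueError("prior must sum to 1")
    if np.all(np.isneginf(ll)):
        raise ValueError("all model likelihoods are zero; posterior undefined")
    log_shift = float(np.max(ll))
    likelihood = np.exp(ll - log_shift)
    unnorm = likelihood * prior
    evidence = float(unnorm.sum())
    if evidence == 0.0:
        raise ValueError(
            "evidence underflowed to zero: prior mass sits entirely on models "
            "whose likelihood is negligible relative to the best fit"
        )
    return unnorm / evidence, evidence, log_shift


def fit_ensemble(
    train: CohortFeatureTable,
    prior: np.ndarray | None = None,
    standardize: bool = False,
) -> EnsembleModel:
    """Full per-run pipeline: anchors, grid, 19 fits, Bayesian weights.

    Deterministic given the training table. ``prior`` overrides the Gaussian
    prior (e.g. a point mass for single-model comparisons); it must sum to 1.
    """
    fitter = CostFitter(train, standardize=standardize)
    c_mu = find_c_mu(train, fitter=fitter)
    c_max, cands, raw, filt = find_c_max(train, c_mu, fitter=fitter, return_profile=True)
    grid = build_cost_grid(c_mu, c_max, cands, raw, filt)
    models = [fitter.fit(c) for c in grid.values]
    ll = np.array([training_log_likelihood(m, train) for m in models])
    if prior is None:
        prior = prior_weights(grid)
    else:
        prior = np.asarray(prior, dtype=float)
        if prior.shape != grid.values.shape:
            raise ValueError("prior must have one weight per grid value")
    posterior, evidence, log_shift = posterior_weights(prior, ll)
    likelihood = np.exp(ll - log_shift)
    betas = np.stack([m.coefficients for m in models])
    run_coefficients = posterior @ betas
    return EnsembleModel(
        grid, models, prior, ll, likelihood, posterior, evidence, log_shift,
        run_coefficients,
    )


def ensemble_predict(
    ensemble: EnsembleModel, test: CohortFeatureTable
) -> list[SubjectPrediction]:
    """Posterior-weighted average probability per test subject, thresholded at 0.5."""
    n_model_voxels = ensemble.models[0].coefficients.shape[0]
    if test.n_voxels != n_model_voxels:
        raise ValueError(
            f"test table has {test.n_voxels} voxel columns, ensemble expects "
            f"{n_model_voxels}"
        )
    probs = np.stack([predict_probability(m, test.matrix) for m in ensemble.models])
    H = ensemble.posterior @ probs  # (n_test,)
    return [
        SubjectPrediction(
            test.subject_ids[i],
            float(H[i]),
            int(H[i] > 0.5),
            int(test.labels[i]),
        )
        for i in range(test.n_subjects)
    ]


def aggregate_run_coefficients(ensemble: EnsembleModel) -> np.ndarray:
    """Posterior-weighted per-voxel coefficient vector (beta_R)."""
    betas = np.stack([m.coefficients for m in ensemble.models])
    return ensemble.posterior @ betas


def with_point_mass_prior(ensemble: EnsembleModel, index: int) -> EnsembleModel:
    """Refocus an ensemble on a single grid member (prior mass 1 at ``index``)."""
    prior = np.zeros(len(ensemble.models))
    prior[index] = 1.0
    posterior, evidence, log_shift = posterior_weights(prior, ensemble.log_likelihoods)
    betas = np.stack([m.coefficients for m in ensemble.models])
    return replace(
        ensemble,
        prior=prior,
        posterior=posterior,
        evidence=evidence,
        log_shift=log_shift,
        run_coefficients=posterior @ betas,
    )
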