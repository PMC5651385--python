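"""Data-driven cost grid: C_mu, C_max, and the 19-value cost vector.

The ensemble's 19 cost values are anchored to the training set D:

* C_mu  — the minimum cost at which the fitted SVM makes zero training
          classification errors (found by a doubling/halving bracket from
          C = 1 followed by bisection in log10 space to 1% relative
          tolerance);
* C_max — the minimum cost at which the training log-likelihood reaches its
          plateau: the LL profile over a log-spaced candidate scan is
          smoothed with a length-3 median filter and the first candidate
          within a flatness tolerance of the smoothed maximum is taken;
* the grid is then C_mu + Delta * i/9 for i in -9..9 with Delta =
  C_max - C_mu, so C_mu sits at the center and C_max at the top.

Values the linear formula drives to zero or below (possible whenever
Delta >= C_mu) are clipped to a small positive epsilon and flagged; the
formula itself stays linear.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .svm import ProbabilisticSVMModel, fit_linear_svm, training_error_count, training_log_likelihood
from .volumes import CohortFeatureTable

__all__ = [
    "CostGrid",
    "CostFitter",
    "find_c_mu",
    "ll_profile",
    "median_filter3",
    "find_c_max",
    "build_cost_grid",
]

GRID_OFFSETS = np.arange(-9, 10)  # i = -9 .. 9, 19 values
COST_FLOOR = 1e-4
COST_CAP = 1e8
C_MU_LOG_RTOL = 0.01  # bisection stop: hi/lo <= 1 + 1%
CMAX_N_CANDIDATES = 40
CMAX_SPAN = 1e4  # scan [c_mu, c_mu * span]
CLIP_FACTOR = 1e-6  # clipped grid values become CLIP_FACTOR * c_mu


class CostFitter:
    """Caches SVM fits on one training set across repeated cost evaluations.

    The linear Gram matrix is computed once; every helper in this module and
    in the ensemble fits through the same cache, so a cost value probed
    during the C_mu search is never refitted for the LL scan or the grid.
    """

    def __init__(self, train: CohortFeatureTable, standardize: bool = False):
        self.train = train
        self.standardize = standardize
        self._gram = None if standardize else train.matrix @ train.matrix.T
        self._models: dict[float, ProbabilisticSVMModel] = {}

    def fit(self, cost: float) -> ProbabilisticSVMModel:
        cost = float(cost)
        if cost not in self._models:
            self._models[cost] = fit_linear_svm(
                self.train, cost, standardize=self.standardize, _gram=self._gram
            )
        return self._models[cost]

    def error_count(self, cost: float) -> int:
        return training_error_count(self.fit(cost), self.train)

    def log_likelihood(self, cost: float) -> float:
        return training_log_likelihood(self.fit(cost), self.train)


@dataclass
class CostGrid:
    """The 19-value cost vector with its anchors and the LL scan audit trail."""

    c_mu: float
    c_max: float
    values: np.ndarray  # 19 positive costs, non-decreasing in i
    clipped: np.ndarray  # boolean per value: True where positivity clipping applied
    ll_candidates: np.ndarray | None = None
    ll_raw: np.ndarray | None = None
    ll_filtered: np.ndarray | None = None

    @property
    def delta(self) -> float:
        return self.c_max - self.c_mu

    def to_dict(self) -> dict:
        d = {
            "c_mu": self.c_mu,
            "c_max": self.c_max,
            "delta": self.delta,
            "values": self.values.tolist(),
            "clipped": self.clipped.tolist(),
        }
        if self.ll_candidates is not None:
            d["ll_profile"] = {
                "candidates": self.ll_candidates.tolist(),
                "raw": self.ll_raw.tolist(),
                "filtered": self.ll_filtered.tolist(),
            }
        return d


def find_c_mu(
    train: CohortFeatureTable,
    fitter: CostFitter | None = None,
    floor: float = COST_FLOOR,
    cap: float = COST_CAP,
) -> float:
    """Minimum cost achieving zero training classification errors.

    Brackets the zero-error boundary by doubling (or halving) from C = 1,
    then bisects in log space until the bracket ratio is within 1%. The
    zero-error set need not be contiguous from below (isolated low-cost
    pockets occur), so the result is verified at a few probed larger costs
    and the search resumes above any that still errs. When even the smallest
    probed cost is error-free the floor itself is returned: below it the
    solution is numerically meaningless. Raises if no error-free cost exists
    up to ``cap`` (not linearly separable).
    """
    f = fitter or CostFitter(train)

    def bisect(lo: float, hi: float) -> float:
        # invariant: errors at lo (or lo is the floor), zero errors at hi
        while hi / lo > 1.0 + C_MU_LOG_RTOL:
            mid = float(np.sqrt(lo * hi))
            if f.error_count(mid) == 0:
                hi = mid
            else:
                lo = mid
        return hi

    def double_up(lo: float) -> float:
        hi = lo * 2
        while f.error_count(hi) != 0:
            lo = hi
            hi *= 2
            if hi > cap:
                raise ValueError(
                    f"no zero-error cost found up to {cap:g}: "
                    "training set is not linearly separable"
                )
        return bisect(lo, hi)

    c = 1.0
    if f.error_count(c) == 0:
        # search downward for where errors first appear
        hi = c
        lo = c / 2
        while lo >= floor and f.error_count(lo) == 0:
            hi = lo
            lo /= 2
        if lo < floor and f.error_count(floor) == 0:
            c = floor
        else:
            c = bisect(max(lo, floor), hi)
    else:
        c = double_up(c)
    while True:
        bad = next(
            (p for p in (2 * c, 10 * c, 100 * c) if p <= cap and f.error_count(p) != 0),
            None,
        )
        if bad is None:
            return c
        c = double_up(bad)


def ll_profile(
    train: CohortFeatureTable,
    candidates: np.ndarray,
    fitter: CostFitter | None = None,
) -> np.ndarray:
    """Training log-likelihood of the fitted model at each candidate cost."""
    f = fitter or CostFitter(train)
    candidates = np.asarray(candidates, dtype=float)
    if np.any(np.diff(candidates) < 0):
        raise ValueError("candidates must be sorted ascending")
    return np.array([f.log_likelihood(c) for c in candidates])


def median_filter3(values: np.ndarray) -> np.ndarray:
    """Length-3 median filter; endpoints pass through unchanged."""
    v = np.asarray(values, dtype=float)
    if v.ndim != 1 or len(v) == 0:
        raise ValueError("expected a non-empty 1-D sequence")
    if len(v) < 3:
        return v.copy()
    out = v.copy()
    windows = np.column_stack([v[:-2], v[1:-1], v[2:]])
    out[1:-1] = np.median(windows, axis=1)
    return out


def find_c_max(
    train: CohortFeatureTable,
    c_mu: float,
    fitter: CostFitter | None = None,
    n_candidates: int = CMAX_N_CANDIDATES,
    span: float = CMAX_SPAN,
    candidates: np.ndarray | None = None,
    return_profile: bool = False,
):
    """Minimum cost at which the (smoothed) training log-likelihood plateaus.

    Scans log-spaced candidates from ``c_mu`` to ``c_mu * span``, median-
    filters the LL profile, and returns the smallest candidate whose
    filtered LL is within a flatness tolerance of the filtered maximum.
    When the profile is still rising at the top, the default scan extends
    itself (same log density) up to the absolute cost cap before raising;
    an explicit ``candidates`` array is never extended.
    """
    f = fitter or CostFitter(train)
    explicit = candidates is not None
    if not explicit:
        candidates = np.logspace(np.log10(c_mu), np.log10(c_mu * span), n_candidates)
    candidates = np.asarray(candidates, dtype=float)
    while True:
        raw = ll_profile(train, candidates, fitter=f)
        filtered = median_filter3(raw)
        tol_flat = 1e-6 * max(1.0, abs(filtered.max()))
        at_plateau = filtered >= filtered.max() - tol_flat
        first = int(np.argmax(at_plateau))
        rising_at_top = first == len(candidates) - 1 and not at_plateau[:-1].any()
        if not rising_at_top:
            break
        top = candidates[-1]
        if explicit or top >= COST_CAP:
            raise RuntimeError(
                "log-likelihood still rising at the top of the cost scan "
                f"(cap {top:g}); rerun with a larger span"
            )
        ext = np.logspace(
            np.log10(top), np.log10(min(top * span, COST_CAP)), n_candidates
        )[1:]
        candidates = np.concatenate([candidates, ext])
    c_max = float(candidates[first])
    if return_profile:
        return c_max, candidates, raw, filtered
    return c_max


def build_cost_grid(
    c_mu: float,
    c_max: float,
    ll_candidates: np.ndarray | None = None,
    ll_raw: np.ndarray | None = None,
    ll_filtered: np.ndarray | None = None,
) -> CostGrid:
    """Assemble the 19-value vector C_mu + Delta*i/9, i = -9..9, with clipping."""
    if c_mu <= 0:
        raise ValueError(f"c_mu must be positive, got {c_mu}")
    if c_max < c_mu:
        raise ValueError(f"c_max ({c_max}) must be >= c_mu ({c_mu})")
    delta = c_max - c_mu
    values = c_mu + delta * GRID_OFFSETS / 9.0
    clipped = values <= 0
    if clipped.any():
        values = values.copy()
        values[clipped] = CLIP_FACTOR * c_mu
        warnings.warn(
            f"{int(clipped.sum())} grid value(s) at or below zero clipped to "
            f"{CLIP_FACTOR * c_mu:g}",
            stacklevel=2,
        )
    return CostGrid(
        float(c_mu), float(c_max), values, clipped, ll_candidates, ll_raw, ll_filtered
    )
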