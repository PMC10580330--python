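"""Evaluation and significance of CPM predictions.

Predictive performance is the Spearman rank correlation between observed
and LOOCV-predicted severity (symptom scores are skewed integers, so rank
correlation is the appropriate metric).  Because held-out folds are not
independent, parametric p-values for that correlation are anticonservative;
significance is instead assessed by permutation: the score vector is
shuffled against the connectomes, the full LOOCV CPM is rerun per shuffle,
and the one-sided exceedance p is computed with the plus-one rule
``p = (1 + #{null rho >= observed rho}) / (1 + n_perm)``, which is never
zero and exchangeable-valid.

By default only the scores are permuted while covariates stay aligned with
the connectomes, isolating the score-connectome link; joint score+covariate
shuffling is available via ``shuffle_covariates=True``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np
from scipy import stats

from .cpm import loocv_predict_batch

if TYPE_CHECKING:  # pragma: no cover
    from .cpm import CPM

logger = logging.getLogger(__name__)

N_PERMUTATIONS = 1000  # study default


def spearman_eval(observed, predicted, allow_constant: bool = False) -> float:
    """Spearman rho between observed and predicted values (average ranks on ties).

    A constant input vector leaves rho undefined; by default this raises,
    with ``allow_constant=True`` it is logged and reported as 0.0 (the
    convention used inside the permutation machinery so that observed and
    null statistics are computed identically).
    """
    a = np.asarray(observed, dtype=float)
    b = np.asarray(predicted, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 3:
        raise ValueError("observed and predicted must be equal-length 1-D, n >= 3")
    if np.ptp(a) == 0 or np.ptp(b) == 0:
        if allow_constant:
            logger.warning("constant vector: Spearman rho undefined, reporting 0.0")
            return 0.0
        raise ValueError("Spearman rho undefined for a constant vector")
    return float(stats.spearmanr(a, b).statistic)


def _spearman_columns(y: np.ndarray, predicted: np.ndarray) -> np.ndarray:
    """Spearman rho of y against each column of predicted; undefined -> 0."""
    ry = stats.rankdata(y)
    rp = stats.rankdata(predicted, axis=0)
    ry_c = ry - ry.mean()
    rp_c = rp - rp.mean(axis=0)
    denom = np.sqrt((ry_c**2).sum()) * np.sqrt((rp_c**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (ry_c @ rp_c) / denom
    return np.where(np.isfinite(rho), rho, 0.0)


def permutation_indices(n: int, n_perm: int, seed: int) -> np.ndarray:
    """(n_perm, n) permutation index matrix, a function of (n, n_perm, seed) only."""
    rng = np.random.default_rng(seed)
    return np.array([rng.permutation(n) for _ in range(n_perm)])


@dataclass(frozen=True)
class PermutationResult:
    """Observed rho, permutation null distribution, and exceedance p."""

    r_observed: float
    null_distribution: np.ndarray
    n_perm: int
    seed: int

    @property
    def p_permu(self) -> float:
        return float(
            (1 + np.sum(self.null_distribution >= self.r_observed))
            / (1 + self.n_perm)
        )

    def summary(self) -> str:
        return (
            f"permutation test: rho = {self.r_observed:.4f}, "
            f"p_permu = {self.p_permu:.4g} ({self.n_perm} permutations, "
            f"seed {self.seed})"
        )


def permutation_test(
    model: "CPM",
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    shuffle_covariates: bool = False,
    results=None,
    batch_size: int = 64,
) -> PermutationResult:
    """Permutation significance of a CPM's LOOCV predictability.

    The observed statistic is the Spearman rho of the model's LOOCV
    predictions (computed here if ``results`` is not supplied).  Each
    permutation shuffles the score vector against the connectomes and
    reruns the full LOOCV CPM.  Score-only shuffles share the covariate
    projections across permutations and run batched; joint shuffles fall
    back to a per-permutation loop.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    if results is None:
        results = model.fit()
    y = model.scores
    r_observed = spearman_eval(y, results.predicted, allow_constant=True)
    n = y.shape[0]
    perms = permutation_indices(n, n_perm, seed)
    e = model._edge_view()
    null = np.empty(n_perm)
    if shuffle_covariates and model.covariates is not None:
        for i, perm in enumerate(perms):
            pred, _ = loocv_predict_batch(
                e, y[perm], model.covariates[perm], model.threshold_p
            )
            null[i] = _spearman_columns(y[perm], pred)[0]
    else:
        for start in range(0, n_perm, batch_size):
            block = perms[start:start + batch_size]
            y_block = y[block.T]  # (n, P)
            pred, _ = loocv_predict_batch(
                e, y_block, model.covariates, model.threshold_p
            )
            for c in range(block.shape[0]):
                null[start + c] = _spearman_columns(y_block[:, c], pred[:, c:c + 1])[0]
    return PermutationResult(
        r_observed=r_observed, null_distribution=null, n_perm=n_perm, seed=seed
    )


@dataclass(frozen=True)
class MotionCheck:
    """Rank correlations of head motion with observed and predicted scores."""

    r_observed_fd: float
    p_observed_fd: float
    r_predicted_fd: float
    p_predicted_fd: float
    defined: bool = True


def motion_confound_check(scores, predicted, mean_fd) -> MotionCheck:
    """Spearman correlation of mean FD with observed and predicted scores.

    A constant FD vector leaves the correlations undefined; the result is
    flagged (``defined=False``) with NaN statistics.
    """
    y = np.asarray(scores, float)
    yhat = np.asarray(predicted, float)
    fd = np.asarray(mean_fd, float)
    if not (y.shape == yhat.shape == fd.shape):
        raise ValueError("scores, predicted and mean_fd must have equal length")
    if np.ptp(fd) == 0:
        logger.warning("constant FD vector: motion correlations undefined")
        return MotionCheck(np.nan, np.nan, np.nan, np.nan, defined=False)
    r1 = stats.spearmanr(fd, y)
    r2 = stats.spearmanr(fd, yhat)
    return MotionCheck(
        r_observed_fd=float(r1.statistic), p_observed_fd=float(r1.pvalue),
        r_predicted_fd=float(r2.statistic), p_predicted_fd=float(r2.pvalue),
    )
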