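"""Connectome-based predictive modeling: edge selection, network strengths,
linear model, leave-one-out cross-validation, and final-model export.

The CPM protocol relates a subject's connectome to a continuous severity
score in three steps.  In a training set, every edge's Fisher-z strength is
partially correlated with the score, controlling for covariates (age,
gender, disease duration by default); edges with two-sided p strictly below
a threshold (default 0.01) form the positive network (r > 0) and negative
network (r < 0).  Each subject's positive/negative network strength is the
sum of their connectivity over the corresponding edge set, and severity is
regressed on the two strengths by ordinary least squares.  Under
leave-one-out cross-validation (LOOCV) the held-out subject is predicted
from their own strengths under the fold's mask; the reported connectome is
the consensus of edges selected with the same sign in every fold.

Partial-correlation p-values use the t approximation with
``df = n - 2 - k`` for k covariates.  Folds whose mask is empty predict the
fold-training mean and are logged as degenerate.

The internal engine is vectorized over many score vectors at once, which is
what makes full-pipeline permutation tests affordable; the batched path is
exactly equivalent to the per-fold loop (asserted in the test suite).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
import numpy as np
import pandas as pd
from scipy import stats

from .edges import EdgeMask, edge_pairs, n_edges, vectorize_matrix

logger = logging.getLogger(__name__)

#: Default two-sided p threshold for edge selection.
THRESHOLD_P = 0.01


# ---------------------------------------------------------------------------
# Low-level pieces
# ---------------------------------------------------------------------------

def _as_edge_matrix(connectivity) -> tuple[np.ndarray, int]:
    """Coerce (n, N, N) matrix stack or (n, M) edge matrix to (n, M), N."""
    arr = np.asarray(connectivity, dtype=float)
    if arr.ndim == 3:
        if arr.shape[1] != arr.shape[2]:
            raise ValueError("matrix stack must be (n_subjects, N, N)")
        n_nodes = arr.shape[1]
        iu = edge_pairs(n_nodes)
        return arr[:, iu[0], iu[1]], n_nodes
    if arr.ndim == 2:
        m = arr.shape[1]
        # invert M = N(N-1)/2
        n_nodes = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
        if n_edges(n_nodes) != m:
            raise ValueError(f"{m} columns is not N(N-1)/2 for integer N")
        return arr, n_nodes
    raise ValueError("connectivity must be 2-D (n, M) or 3-D (n, N, N)")


def _residualizer(covariates: np.ndarray | None, n: int) -> np.ndarray:
    """Orthonormal basis Q of the span of [1, covariates] (n x (k+1))."""
    if covariates is None or covariates.size == 0:
        x = np.ones((n, 1))
    else:
        x = np.column_stack([np.ones(n), covariates])
    q, _ = np.linalg.qr(x)
    return q


def _partial_corr_columns(e: np.ndarray, y: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Column-wise correlation of residualized e (n, M) with residualized y (n, P).

    Residualization projects out span(q) (intercept + covariates).  Edges
    with zero residual variance get r = 0.
    """
    e_res = e - q @ (q.T @ e)
    y_res = y - q @ (q.T @ y)
    e_norm = np.sqrt(np.einsum("ij,ij->j", e_res, e_res))
    y_norm = np.sqrt(np.einsum("ij,ij->j", y_res, y_res))
    # an edge constant (or spanned by the covariates) has no residual
    # variance beyond rounding noise; call it zero-variance
    e_scale = np.linalg.norm(e, axis=0)
    dead = e_norm <= 1e-10 * np.maximum(e_scale, 1.0)
    if np.any(y_norm <= 1e-10 * np.maximum(np.linalg.norm(y, axis=0), 1.0)):
        raise ValueError("score vector is constant after residualization")
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (e_res.T @ y_res) / np.outer(e_norm, y_norm)
    r[dead, :] = 0.0
    return np.clip(r, -1.0, 1.0)


def _critical_r(threshold_p: float, df: int) -> float:
    """|r| above which the two-sided partial-correlation p is strictly < threshold."""
    t_crit = stats.t.isf(threshold_p / 2.0, df)
    return t_crit / np.sqrt(df + t_crit**2)


@dataclass(frozen=True)
class EdgeStats:
    """Per-edge partial correlation and two-sided p over all M edges."""

    r_partial: np.ndarray
    p_value: np.ndarray
    df: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"r_partial": self.r_partial, "p_value": self.p_value})


def edge_select(
    connectivity,
    scores: np.ndarray,
    covariates: np.ndarray | None = None,
    threshold_p: float = THRESHOLD_P,
) -> tuple[EdgeStats, EdgeMask]:
    """Covariate-controlled edge selection on a full sample.

    Both each edge's strength and the score are residualized on the
    covariates (plus intercept) and the residuals correlated; p comes from
    the t approximation with ``df = n - 2 - k``.  The mask holds edges with
    p strictly below ``threshold_p``, signed by the correlation.  An edge
    with p exactly equal to the threshold is not selected.
    """
    if not 0 < threshold_p < 1:
        raise ValueError("threshold_p must be in (0, 1)")
    e, n_nodes = _as_edge_matrix(connectivity)
    y = np.asarray(scores, dtype=float).reshape(-1, 1)
    n = e.shape[0]
    if y.shape[0] != n:
        raise ValueError("scores length does not match number of subjects")
    cov = None if covariates is None else np.atleast_2d(np.asarray(covariates, float))
    if cov is not None and cov.shape[0] != n:
        cov = cov.T
    k = 0 if cov is None else cov.shape[1]
    if n < k + 3:
        raise ValueError(f"need at least {k + 3} subjects for {k} covariates")
    if np.ptp(y) == 0:
        raise ValueError("score vector is constant")
    q = _residualizer(cov, n)
    r = _partial_corr_columns(e, y, q)[:, 0]
    df = n - 2 - k
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[r == 0] = 1.0
    p = np.clip(p, np.finfo(float).tiny, 1.0)
    mask = EdgeMask(
        n_nodes=n_nodes,
        pos_edges=np.flatnonzero((p < threshold_p) & (r > 0)),
        neg_edges=np.flatnonzero((p < threshold_p) & (r < 0)),
    )
    return EdgeStats(r_partial=r, p_value=p, df=df), mask


def network_strengths(matrix, mask: EdgeMask) -> tuple[float, float]:
    """(sum over positive edges, sum over negative edges) of one connectome."""
    z = np.asarray(matrix, dtype=float)
    edges = vectorize_matrix(z) if z.ndim == 2 else z
    if edges.shape[-1] != n_edges(mask.n_nodes):
        raise ValueError("matrix dimensions do not match mask atlas")
    return float(edges[mask.pos_edges].sum()), float(edges[mask.neg_edges].sum())


@dataclass(frozen=True)
class LinearCoefficients:
    """OLS coefficients of severity on network strengths.

    A slope is None when that sign's edge set was empty and the predictor
    was dropped.
    """

    intercept: float
    slope_pos: float | None
    slope_neg: float | None

    def predict(self, sum_pos, sum_neg) -> np.ndarray:
        yhat = np.full(np.shape(np.asarray(sum_pos, float)), self.intercept, dtype=float)
        if self.slope_pos is not None:
            yhat = yhat + self.slope_pos * np.asarray(sum_pos, float)
        if self.slope_neg is not None:
            yhat = yhat + self.slope_neg * np.asarray(sum_neg, float)
        return yhat


def fit_linear(
    sum_pos: np.ndarray | None,
    sum_neg: np.ndarray | None,
    scores: np.ndarray,
) -> LinearCoefficients:
    """OLS of score on (1, sum_pos, sum_neg); pass None to drop a predictor.

    Raises
    ------
    ValueError
        If n < 4 or the design is rank deficient (collinear predictors).
    """
    y = np.asarray(scores, dtype=float)
    n = y.shape[0]
    if n < 4:
        raise ValueError("need at least 4 subjects to fit the linear model")
    cols: list[np.ndarray] = [np.ones(n)]
    used: list[str] = []
    for name, v in (("pos", sum_pos), ("neg", sum_neg)):
        if v is not None:
            v = np.asarray(v, dtype=float)
            if v.shape[0] != n:
                raise ValueError("strength vector length does not match scores")
            cols.append(v)
            used.append(name)
    x = np.column_stack(cols)
    rank = np.linalg.matrix_rank(x)
    if rank < x.shape[1]:
        raise ValueError(
            "rank-deficient design: network-strength predictors are collinear "
            "(or constant); consider dropping one"
        )
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    it = iter(beta[1:])
    return LinearCoefficients(
        intercept=float(beta[0]),
        slope_pos=float(next(it)) if "pos" in used else None,
        slope_neg=float(next(it)) if "neg" in used else None,
    )


# ---------------------------------------------------------------------------
# Batched LOOCV engine
# ---------------------------------------------------------------------------

def _batched_ols_predict(
    sp: np.ndarray, sn: np.ndarray, y: np.ndarray,
    sp0: np.ndarray, sn0: np.ndarray,
) -> np.ndarray:
    """Held-out predictions of per-column OLS fits of y on (1, sp, sn).

    All arrays have P columns (one per score vector); sp/sn/y are training
    values (n_t, P), sp0/sn0 the held-out subject's strengths (P,).  Fits
    use centered predictors with a pseudoinverse solve, so a column with an
    empty network (strength identically zero) degrades gracefully to the
    remaining predictor, or to the training mean when both are empty.
    """
    mp = sp.mean(axis=0)
    mn = sn.mean(axis=0)
    my = y.mean(axis=0)
    spc = sp - mp
    snc = sn - mn
    yc = y - my
    a = np.empty((sp.shape[1], 2, 2))
    a[:, 0, 0] = np.einsum("ij,ij->j", spc, spc)
    a[:, 1, 1] = np.einsum("ij,ij->j", snc, snc)
    a[:, 0, 1] = a[:, 1, 0] = np.einsum("ij,ij->j", spc, snc)
    b = np.empty((sp.shape[1], 2, 1))
    b[:, 0, 0] = np.einsum("ij,ij->j", spc, yc)
    b[:, 1, 0] = np.einsum("ij,ij->j", snc, yc)
    coef = np.linalg.pinv(a, rcond=1e-12) @ b  # (P, 2, 1)
    b1 = coef[:, 0, 0]
    b2 = coef[:, 1, 0]
    return my + b1 * (sp0 - mp) + b2 * (sn0 - mn)


def loocv_predict_batch(
    e: np.ndarray,
    scores: np.ndarray,
    covariates: np.ndarray | None,
    threshold_p: float,
    record_signs: bool = False,
) -> tuple[np.ndarray, np.ndarray | None]:
    """LOOCV-CPM predictions for P score vectors sharing connectomes/covariates.

    Parameters
    ----------
    e
        (n, M) edge-strength matrix.
    scores
        (n, P) score matrix; each column is analyzed independently.
    covariates
        (n, k) covariate matrix kept aligned with the connectomes, or None.
    threshold_p
        Edge-selection threshold (p strictly below).
    record_signs
        When True also return per-fold selection signs (n_folds, M, P), int8.

    Returns
    -------
    predicted : (n, P) array of held-out predictions.
    fold_signs : (n, M, P) int8 array or None.
    """
    n, m = e.shape
    scores = np.asarray(scores, dtype=float)
    if scores.ndim == 1:
        scores = scores[:, None]
    p_cols = scores.shape[1]
    k = 0 if covariates is None else covariates.shape[1]
    if n < k + 4:
        raise ValueError("too few subjects for LOOCV with these covariates")
    df = (n - 1) - 2 - k
    if df < 1:
        raise ValueError("nonpositive degrees of freedom in folds")
    r_crit = _critical_r(threshold_p, df)
    predicted = np.empty((n, p_cols))
    signs = np.zeros((n, m, p_cols), dtype=np.int8) if record_signs else None
    idx = np.arange(n)
    for j in range(n):
        train = idx != j
        e_t = e[train]
        y_t = scores[train]
        if np.any(np.ptp(y_t, axis=0) == 0):
            raise ValueError(f"score vector constant within fold {j}")
        cov_t = None if covariates is None else covariates[train]
        q = _residualizer(cov_t, n - 1)
        r = _partial_corr_columns(e_t, y_t, q)  # (M, P)
        pos = r > r_crit
        neg = r < -r_crit
        if record_signs:
            signs[j][pos] = 1
            signs[j][neg] = -1
        sp = e_t @ pos
        sn = e_t @ neg
        sp0 = e[j] @ pos
        sn0 = e[j] @ neg
        predicted[j] = _batched_ols_predict(sp, sn, y_t, sp0, sn0)
    return predicted, signs


# ---------------------------------------------------------------------------
# Model / results objects
# ---------------------------------------------------------------------------

class CPM:
    """Connectome-based predictive model of a severity score.

    Parameters
    ----------
    connectivity
        Per-subject Fisher-z connectomes: (n, N, N) stack of symmetric
        matrices or (n, M) upper-triangle edge matrix.
    scores
        Severity score per subject (length n).
    covariates
        Optional (n, k) numeric covariate matrix (e.g. age, gender as 0/1,
        disease duration in years) controlled for during edge selection.
    threshold_p
        Two-sided p threshold for edge selection (default 0.01; strict).
    edge_subset
        Optional array of canonical edge indices restricting the edge
        universe (used by region-based and lesioned variants).

    Examples
    --------
    >>> model = CPM(matrices, scores, covariates=covs)
    >>> res = model.fit()          # LOOCV; consensus connectome + rho
    >>> final = model.fit_final()  # exportable model for external data
    >>> final.predict(new_matrices)
    """

    def __init__(
        self,
        connectivity,
        scores,
        covariates=None,
        threshold_p: float = THRESHOLD_P,
        edge_subset: np.ndarray | None = None,
    ) -> None:
        self.edges_full, self.n_nodes = _as_edge_matrix(connectivity)
        self.scores = np.asarray(scores, dtype=float)
        if self.scores.ndim != 1 or self.scores.shape[0] != self.edges_full.shape[0]:
            raise ValueError("scores must be 1-D with one entry per subject")
        if covariates is None:
            self.covariates = None
        else:
            cov = np.asarray(covariates, dtype=float)
            if cov.ndim == 1:
                cov = cov[:, None]
            if cov.shape[0] != self.scores.shape[0]:
                raise ValueError("covariates must have one row per subject")
            self.covariates = cov
        if not 0 < threshold_p < 1:
            raise ValueError("threshold_p must be in (0, 1)")
        self.threshold_p = float(threshold_p)
        if edge_subset is None:
            self.edge_subset = None
        else:
            self.edge_subset = np.unique(np.asarray(edge_subset, dtype=np.int64))
            if self.edge_subset.size and self.edge_subset.max() >= n_edges(self.n_nodes):
                raise ValueError("edge_subset indices exceed the edge universe")

    # -- helpers ----------------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return int(self.edges_full.shape[0])

    @property
    def n_covariates(self) -> int:
        return 0 if self.covariates is None else int(self.covariates.shape[1])

    def _edge_view(self) -> np.ndarray:
        if self.edge_subset is None:
            return self.edges_full
        return self.edges_full[:, self.edge_subset]

    def _to_full_indices(self, local: np.ndarray) -> np.ndarray:
        if self.edge_subset is None:
            return local
        return self.edge_subset[local]

    # -- estimation -------------------------------------------------------

    def fit(self) -> "CPMResults":
        """Run LOOCV: per-fold selection, fit, held-out prediction, consensus."""
        if self.n_subjects < 10:
            raise ValueError("LOOCV requires at least 10 subjects")
        e = self._edge_view()
        predicted, signs = loocv_predict_batch(
            e, self.scores, self.covariates, self.threshold_p, record_signs=True
        )
        signs = signs[:, :, 0]  # (n_folds, M_view)
        consensus_pos = np.all(signs == 1, axis=0)
        consensus_neg = np.all(signs == -1, axis=0)
        mask = EdgeMask(
            n_nodes=self.n_nodes,
            pos_edges=self._to_full_indices(np.flatnonzero(consensus_pos)),
            neg_edges=self._to_full_indices(np.flatnonzero(consensus_neg)),
        )
        degenerate = [int(j) for j in np.flatnonzero(~np.any(signs != 0, axis=1))]
        if degenerate:
            logger.info("empty edge mask in %d fold(s): %s (predicted training mean)",
                        len(degenerate), degenerate)
        strengths = np.column_stack([
            self.edges_full[:, mask.pos_edges].sum(axis=1),
            self.edges_full[:, mask.neg_edges].sum(axis=1),
        ])
        return CPMResults(
            model=self,
            predicted=predicted[:, 0],
            consensus_mask=mask,
            fold_signs=signs,
            network_strength=strengths,
            degenerate_folds=degenerate,
        )

    def fit_final(self, restrict_to_consensus: bool = True,
                  results: "CPMResults | None" = None) -> "FittedCPM":
        """Fit the exportable model on the full training sample.

        Edges are selected on all subjects; by default the selection is
        restricted to the LOOCV consensus connectome (the reported one),
        and coefficients are fitted on all training subjects.  With
        ``restrict_to_consensus=False`` the full-sample selection is used
        as-is.
        """
        stats_, full_mask = edge_select(
            self._expanded_view_for_select(), self.scores, self.covariates,
            self.threshold_p,
        )
        if restrict_to_consensus:
            if results is None:
                results = self.fit()
            mask = EdgeMask(
                n_nodes=self.n_nodes,
                pos_edges=np.intersect1d(full_mask.pos_edges, results.consensus_mask.pos_edges),
                neg_edges=np.intersect1d(full_mask.neg_edges, results.consensus_mask.neg_edges),
            )
        else:
            mask = full_mask
        if mask.is_empty:
            raise ValueError(
                "empty consensus connectome: no edge survived selection in every "
                "fold; consider a more liberal threshold_p"
            )
        sp = self.edges_full[:, mask.pos_edges].sum(axis=1) if mask.n_pos else None
        sn = self.edges_full[:, mask.neg_edges].sum(axis=1) if mask.n_neg else None
        coef = fit_linear(sp, sn, self.scores)
        return FittedCPM(mask=mask, coefficients=coef, n_train=self.n_subjects,
                         threshold_p=self.threshold_p, n_covariates=self.n_covariates)

    def _expanded_view_for_select(self) -> np.ndarray:
        """Edge matrix with non-subset columns zeroed so indices stay global."""
        if self.edge_subset is None:
            return self.edges_full
        e = np.zeros_like(self.edges_full)
        e[:, self.edge_subset] = self.edges_full[:, self.edge_subset]
        return e


@dataclass
class CPMResults:
    """LOOCV results: held-out predictions, consensus connectome, diagnostics."""

    model: CPM
    predicted: np.ndarray
    consensus_mask: EdgeMask
    fold_signs: np.ndarray
    network_strength: np.ndarray
    degenerate_folds: list[int] = field(default_factory=list)

    @property
    def rho(self) -> float:
        """Spearman correlation between observed and predicted severity."""
        from .inference import spearman_eval
        return spearman_eval(self.model.scores, self.predicted, allow_constant=True)

    @property
    def informative(self) -> bool:
        """False when every fold had an empty mask (predictions are means)."""
        return len(self.degenerate_folds) < self.model.n_subjects

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "observed": self.model.scores,
            "predicted": self.predicted,
            "sum_pos": self.network_strength[:, 0],
            "sum_neg": self.network_strength[:, 1],
        })

    def summary(self) -> str:
        lines = [
            "Connectome-based predictive model (LOOCV)",
            "=" * 45,
            f"subjects                {self.model.n_subjects}",
            f"nodes / edges           {self.model.n_nodes} / {n_edges(self.model.n_nodes)}",
            f"covariates              {self.model.n_covariates}",
            f"selection threshold p < {self.model.threshold_p}",
            f"consensus edges         {self.consensus_mask.n_pos} positive, "
            f"{self.consensus_mask.n_neg} negative",
            f"Spearman rho (obs, pred) {self.rho:.4f}",
            f"degenerate folds        {len(self.degenerate_folds)}",
        ]
        return "\n".join(lines)


@dataclass(frozen=True)
class FittedCPM:
    """Exportable CPM: consensus edge mask plus linear coefficients.

    Apply to external connectomes with :meth:`predict`; the network
    strengths are computed under the stored mask and fed through the
    training coefficients (no refitting).
    """

    mask: EdgeMask
    coefficients: LinearCoefficients
    n_train: int
    threshold_p: float
    n_covariates: int

    def predict(self, connectivity) -> np.ndarray:
        e, n_nodes = _as_edge_matrix(connectivity)
        if n_nodes != self.mask.n_nodes:
            raise ValueError(
                f"connectomes have {n_nodes} nodes, model expects {self.mask.n_nodes}"
            )
        sp = e[:, self.mask.pos_edges].sum(axis=1)
        sn = e[:, self.mask.neg_edges].sum(axis=1)
        return self.coefficients.predict(sp, sn)

    def to_dict(self) -> dict:
        from .edges import edge_pairs
        iu = edge_pairs(self.mask.n_nodes)
        return {
            "n_nodes": self.mask.n_nodes,
            "n_train": self.n_train,
            "threshold_p": self.threshold_p,
            "n_covariates": self.n_covariates,
            "intercept": self.coefficients.intercept,
            "slope_pos": self.coefficients.slope_pos,
            "slope_neg": self.coefficients.slope_neg,
            "pos_edges": [[int(iu[0][k]), int(iu[1][k])] for k in self.mask.pos_edges],
            "neg_edges": [[int(iu[0][k]), int(iu[1][k])] for k in self.mask.neg_edges],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "FittedCPM":
        mask = EdgeMask.from_pairs(d["n_nodes"], d["pos_edges"], d["neg_edges"])
        coef = LinearCoefficients(
            intercept=float(d["intercept"]),
            slope_pos=None if d["slope_pos"] is None else float(d["slope_pos"]),
            slope_neg=None if d["slope_neg"] is None else float(d["slope_neg"]),
        )
        return cls(mask=mask, coefficients=coef, n_train=int(d["n_train"]),
                   threshold_p=float(d["threshold_p"]),
                   n_covariates=int(d["n_covariates"]))
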