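"""Patient-versus-control network strength and descriptive group statistics.

The strength of a predictive network in any subject - patient or normal
control - is the sum of that subject's Fisher-z connectivity over the
network's edges (the same rule used inside CPM).  Group differences in
strength are assessed with the Mann-Whitney test (strengths inherit the
skew of the underlying scores); descriptive cohort comparisons use the
usual two-sample t-test for normal variables, Mann-Whitney otherwise,
chi-square for categorical tables, and a Lilliefors-type
Kolmogorov-Smirnov check for normality.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.diagnostic import kstest_normal

from .cpm import _as_edge_matrix
from .edges import EdgeMask, n_edges


def strength_in_group(mask: EdgeMask, connectivity) -> np.ndarray:
    """Per-subject (sum_pos, sum_neg) under a fixed connectome mask.

    Applies the identical summation rule as the CPM network strengths to a
    stack of matrices from any group.
    """
    e, n_nodes = _as_edge_matrix(connectivity)
    if n_edges(n_nodes) != n_edges(mask.n_nodes):
        raise ValueError(
            f"matrices have {n_nodes} nodes, mask expects {mask.n_nodes}"
        )
    return np.column_stack([
        e[:, mask.pos_edges].sum(axis=1),
        e[:, mask.neg_edges].sum(axis=1),
    ])


def mann_whitney(a, b) -> tuple[float, float]:
    """Two-sided Mann-Whitney U with tie correction (exact for small n)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)


def chi_square(table, correction: bool = False) -> tuple[float, float]:
    """Chi-square test of independence on a contingency table.

    Continuity correction off by default (so a 2x2 table like
    [[10,0],[0,10]] gives the uncorrected statistic).
    """
    table = np.asarray(table, float)
    if table.size == 0 or np.any(table.sum(axis=1) == 0) or np.any(table.sum(axis=0) == 0):
        raise ValueError("contingency table has an empty row or column")
    res = stats.chi2_contingency(table, correction=correction)
    return float(res.statistic), float(res.pvalue)


def ks_normality(values) -> float:
    """Lilliefors (KS with estimated parameters) normality p-value."""
    values = np.asarray(values, float)
    if values.size < 4:
        raise ValueError("need at least 4 values")
    return float(kstest_normal(values)[1])


def t_test(a, b) -> tuple[float, float]:
    """Two-sided two-sample t-test (pooled variance)."""
    a = np.asarray(a, float)
    b = np.asarray(b, float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.ttest_ind(a, b)
    return float(res.statistic), float(res.pvalue)


@dataclass(frozen=True)
class StrengthComparison:
    """Patient-vs-control medians and Mann-Whitney tests per network sign."""

    median_pos_patients: float
    median_pos_controls: float
    median_neg_patients: float
    median_neg_controls: float
    u_pos: float
    p_pos: float
    u_neg: float
    p_neg: float

    def summary(self) -> str:
        return (
            "network strength, patients vs controls\n"
            f"  positive: median {self.median_pos_patients:.2f} vs "
            f"{self.median_pos_controls:.2f} (U = {self.u_pos:.1f}, p = {self.p_pos:.4g})\n"
            f"  negative: median {self.median_neg_patients:.2f} vs "
            f"{self.median_neg_controls:.2f} (U = {self.u_neg:.1f}, p = {self.p_neg:.4g})"
        )


def compare_network_strength(mask: EdgeMask, patient_matrices,
                             control_matrices) -> StrengthComparison:
    """Compare positive and negative network strength between two groups."""
    sp = strength_in_group(mask, patient_matrices)
    sc = strength_in_group(mask, control_matrices)
    u_pos, p_pos = mann_whitney(sp[:, 0], sc[:, 0])
    u_neg, p_neg = mann_whitney(sp[:, 1], sc[:, 1])
    return StrengthComparison(
        median_pos_patients=float(np.median(sp[:, 0])),
        median_pos_controls=float(np.median(sc[:, 0])),
        median_neg_patients=float(np.median(sp[:, 1])),
        median_neg_controls=float(np.median(sc[:, 1])),
        u_pos=u_pos, p_pos=p_pos, u_neg=u_neg, p_neg=p_neg,
    )
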