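"""Region-based and computational-lesion CPM variants.

A region-based model restricts the edge universe to connections with both
endpoints inside one macroscale region, asking whether severity can be
predicted from that region alone.  A lesioned model removes one region's
nodes and every edge touching them, quantifying the region's importance by
the drop in predictive performance.  Each variant reuses the full LOOCV +
permutation machinery; p-values across the family of regions are adjusted
by Benjamini-Hochberg FDR, and a lesioned model's rho is compared with the
full model's rho by Steiger's z-test for dependent correlations sharing the
observed-score variable.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .atlas import Atlas
from .cpm import CPM, THRESHOLD_P
from .edges import edge_pairs, n_edges
from .inference import N_PERMUTATIONS, permutation_test, spearman_eval


def region_edges(atlas: Atlas, region: str) -> np.ndarray:
    """Edge indices with BOTH endpoints in ``region``."""
    nodes = atlas.nodes_in_region(region)
    member = np.zeros(atlas.n_nodes, dtype=bool)
    member[nodes] = True
    iu, ju = edge_pairs(atlas.n_nodes)
    return np.flatnonzero(member[iu] & member[ju])


def lesioned_edges(atlas: Atlas, region: str) -> np.ndarray:
    """Edge indices with NEITHER endpoint in ``region``."""
    nodes = atlas.nodes_in_region(region)
    member = np.zeros(atlas.n_nodes, dtype=bool)
    member[nodes] = True
    iu, ju = edge_pairs(atlas.n_nodes)
    return np.flatnonzero(~member[iu] & ~member[ju])


def _restricted_cpm(connectivity, scores, covariates, threshold_p, subset) -> CPM:
    return CPM(connectivity, scores, covariates=covariates,
               threshold_p=threshold_p, edge_subset=subset)


def region_based_cpm(
    connectivity, scores, atlas: Atlas, region: str,
    covariates=None, threshold_p: float = THRESHOLD_P,
    n_perm: int = N_PERMUTATIONS, seed: int = 0,
):
    """CPM restricted to within-region edges; returns (rho, p_permu, results)."""
    nodes = atlas.nodes_in_region(region)
    if nodes.size < 2:
        raise ValueError(f"region {region!r} has fewer than 2 nodes")
    model = _restricted_cpm(connectivity, scores, covariates, threshold_p,
                            region_edges(atlas, region))
    results = model.fit()
    perm = permutation_test(model, n_perm=n_perm, seed=seed, results=results)
    return perm.r_observed, perm.p_permu, results


def lesioned_cpm(
    connectivity, scores, atlas: Atlas, region: str,
    covariates=None, threshold_p: float = THRESHOLD_P,
    n_perm: int = N_PERMUTATIONS, seed: int = 0,
):
    """CPM on the complement edge set of one region; returns (rho, p_permu, results)."""
    subset = lesioned_edges(atlas, region)
    if atlas.n_nodes - atlas.nodes_in_region(region).size < 2:
        raise ValueError(f"lesioning {region!r} leaves fewer than 2 nodes")
    model = _restricted_cpm(connectivity, scores, covariates, threshold_p, subset)
    results = model.fit()
    perm = permutation_test(model, n_perm=n_perm, seed=seed, results=results)
    return perm.r_observed, perm.p_permu, results


def fdr_correct(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, capped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def steiger_z(r_full: float, r_lesioned: float, r_between_predictions: float,
              n: int) -> tuple[float, float]:
    """Steiger's z-test for two dependent correlations sharing one variable.

    ``r_full`` and ``r_lesioned`` both correlate predictions with the same
    observed score; ``r_between_predictions`` is the correlation between
    the two prediction vectors.  The Fisher-z difference is scaled by the
    asymptotic SE, which shrinks as the predictions become more dependent.
    Two-sided p from the standard normal.
    """
    for name, r in (("r_full", r_full), ("r_lesioned", r_lesioned),
                    ("r_between_predictions", r_between_predictions)):
        if not -1.0 < r < 1.0:
            raise ValueError(f"{name} must lie strictly inside (-1, 1)")
    if n < 4:
        raise ValueError("n must be >= 4")
    z1 = np.arctanh(r_full)
    z2 = np.arctanh(r_lesioned)
    rbar = (r_full + r_lesioned) / 2.0
    r23 = r_between_predictions
    # covariance of the two dependent correlations (Steiger 1980, pooled r)
    s = (r23 * (1 - 2 * rbar**2) - 0.5 * rbar**2 * (1 - 2 * rbar**2 - r23**2)) \
        / (1 - rbar**2) ** 2
    z = (z1 - z2) * np.sqrt((n - 3) / (2.0 - 2.0 * s))
    p = 2.0 * stats.norm.sf(abs(z))
    return float(z), float(p)


def run_regional_models(
    connectivity, scores, atlas: Atlas,
    covariates=None, threshold_p: float = THRESHOLD_P,
    n_perm: int = N_PERMUTATIONS, seed: int = 0,
    mode: str = "lesioned",
    full_results=None,
) -> pd.DataFrame:
    """Fit one model per region and assemble the region-model table.

    ``mode`` is ``"region_based"`` or ``"lesioned"``.  Each family of
    region models gets its own FDR correction.  For lesioned models the
    table additionally reports Steiger's z and p against the full model
    (the comparison uses the evaluation correlations as computed, i.e.
    rank-based rho entered into the formula, with the between-predictions
    correlation computed the same way).
    """
    if mode not in ("region_based", "lesioned"):
        raise ValueError("mode must be 'region_based' or 'lesioned'")
    runner = region_based_cpm if mode == "region_based" else lesioned_cpm
    if mode == "lesioned" and full_results is None:
        full_results = CPM(connectivity, scores, covariates=covariates,
                           threshold_p=threshold_p).fit()
    rows = []
    per_region_results = {}
    for i, region in enumerate(atlas.region_labels):
        rho, p_permu, results = runner(
            connectivity, scores, atlas, region, covariates=covariates,
            threshold_p=threshold_p, n_perm=n_perm, seed=seed + i,
        )
        per_region_results[region] = results
        rows.append({"region": region, "mode": mode, "rho": rho,
                     "p_permu": p_permu})
    table = pd.DataFrame(rows)
    table["q"] = fdr_correct(table["p_permu"].to_numpy())
    if mode == "lesioned":
        n = len(np.asarray(scores))
        r_full = spearman_eval(scores, full_results.predicted, allow_constant=True)
        table["rho_full"] = r_full
        zs, ps = [], []
        for region in table["region"]:
            res = per_region_results[region]
            r_les = spearman_eval(scores, res.predicted, allow_constant=True)
            if np.ptp(res.predicted) == 0 or np.ptp(full_results.predicted) == 0:
                zs.append(np.nan)
                ps.append(np.nan)
                continue
            r_between = spearman_eval(full_results.predicted, res.predicted,
                                      allow_constant=True)
            z, p = steiger_z(r_full, r_les, r_between, n)
            zs.append(z)
            ps.append(p)
        table["steiger_z"] = zs
        table["steiger_p"] = ps
    return table
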