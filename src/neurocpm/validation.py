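"""Simulation studies and independent oracles validating the pipeline.

Each function here re-derives a quantity the pipeline computes through an
independent route - naive per-edge loops, exact combinatorics, known
planted ground truth - and measures how the pipeline behaves against it.
They are used by the test suite and by ``scripts/acceptance.py``; the
oracle implementations deliberately avoid the vectorized code paths they
check.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import replace
from fractions import Fraction

import numpy as np
from scipy import stats

from .cpm import CPM, edge_select
from .edges import n_edges
from .groups import mann_whitney, strength_in_group
from .inference import permutation_test, spearman_eval
from .patterns import overlap_test
from .regional import lesioned_edges
from .simulate import (
    GeneratorConfig,
    generate_control_group,
    generate_dataset,
    null_config,
)


def _child_seeds(seed: int, n: int) -> np.ndarray:
    """Independent 31-bit seeds derived from one master seed."""
    return np.random.SeedSequence(seed).generate_state(n) % (2**31)


# ---------------------------------------------------------------------------
# Edge-selection oracle
# ---------------------------------------------------------------------------

def naive_partial_corr(edge: np.ndarray, y: np.ndarray,
                       covariates: np.ndarray | None) -> tuple[float, float]:
    """Per-edge partial correlation by explicit residualization (oracle).

    Residualizes the single edge vector and the score on [1, covariates]
    with a lstsq fit, correlates the residuals, and computes the two-sided
    p from the t distribution with df = n - 2 - k.
    """
    n = y.shape[0]
    x = np.ones((n, 1)) if covariates is None else np.column_stack(
        [np.ones(n), covariates])
    k = x.shape[1] - 1

    def resid(v):
        beta, *_ = np.linalg.lstsq(x, v, rcond=None)
        return v - x @ beta

    er, yr = resid(edge.astype(float)), resid(y.astype(float))
    if er.std() == 0:
        return 0.0, 1.0
    r = float(np.corrcoef(er, yr)[0, 1])
    df = n - 2 - k
    t = r * math.sqrt(df / (1.0 - r**2))
    p = float(2.0 * stats.t.sf(abs(t), df))
    return r, p


def edge_selection_oracle_gap(n_datasets: int = 100, n_subjects: int = 20,
                              n_nodes: int = 15, seed: int = 0) -> dict:
    """Max |difference| between vectorized edge selection and the naive oracle.

    Random datasets with one covariate; compares both the partial
    correlations and the p-values over every edge of every dataset.
    """
    rng = np.random.default_rng(seed)
    m = n_edges(n_nodes)
    max_dr = max_dp = 0.0
    for _ in range(n_datasets):
        e = rng.normal(0, 1, (n_subjects, m))
        y = rng.normal(0, 1, n_subjects)
        cov = rng.normal(0, 1, (n_subjects, 1))
        est, _ = edge_select(e, y, cov, threshold_p=0.01)
        for k in range(m):
            r_o, p_o = naive_partial_corr(e[:, k], y, cov)
            max_dr = max(max_dr, abs(r_o - est.r_partial[k]))
            max_dp = max(max_dp, abs(p_o - est.p_value[k]))
    return {"max_abs_diff_r": max_dr, "max_abs_diff_p": max_dp,
            "n_datasets": n_datasets}


# ---------------------------------------------------------------------------
# Hypergeometric overlap oracle
# ---------------------------------------------------------------------------

def hypergeom_tail_exact(x: int, m: int, k: int, n: int) -> Fraction:
    """P(X > x) for a hypergeometric draw, as an exact rational number."""
    total = math.comb(m, n)
    acc = Fraction(0)
    for j in range(x + 1, min(k, n) + 1):
        acc += Fraction(math.comb(k, j) * math.comb(m - k, n - j), total)
    return acc


def hypergeom_tail_bruteforce(x: int, m: int, k: int, n: int) -> Fraction:
    """P(X > x) by enumerating every possible draw of n items from m."""
    members = set(range(k))
    count = sum(1 for draw in itertools.combinations(range(m), n)
                if len(members.intersection(draw)) > x)
    return Fraction(count, math.comb(m, n))


def hypergeom_enumeration_gap(max_m: int = 20, brute_max_m: int = 9) -> dict:
    """Max |p difference| of the overlap test vs exhaustive enumeration.

    Exact rational enumeration for every instance with M <= ``max_m``;
    additionally full draw-by-draw brute force for M <= ``brute_max_m``.
    The overlap test is exercised through real edge sets (first K and first
    n canonical edges of an M-edge universe), matching its implementation
    path end to end.
    """
    max_diff = 0.0
    n_instances = 0
    for m in range(2, max_m + 1):
        dist_cache = {}
        for k in range(0, m + 1):
            for n in range(0, m + 1):
                # x realized by overlapping prefixes is min(k, n); test the
                # scipy tail directly across all x and the set-based
                # overlap_test at the realized x.
                for x in range(0, min(k, n) + 1):
                    exact = float(hypergeom_tail_exact(x, m, k, n))
                    key = (k, n)
                    if key not in dist_cache:
                        dist_cache[key] = stats.hypergeom(m, k, n)
                    impl = float(dist_cache[key].sf(x))
                    max_diff = max(max_diff, abs(impl - exact))
                    if m <= brute_max_m:
                        brute = float(hypergeom_tail_bruteforce(x, m, k, n))
                        max_diff = max(max_diff, abs(impl - brute))
                    n_instances += 1
                res = overlap_test(np.arange(k), np.arange(n), m_total=m,
                                   n_nodes=_nodes_for(m))
                exact_set = float(hypergeom_tail_exact(res.x, m, k, n))
                max_diff = max(max_diff, abs(res.p - exact_set))
    return {"max_abs_diff": max_diff, "n_instances": n_instances}


def _nodes_for(m: int) -> int:
    """Smallest node count whose edge universe holds at least m edges."""
    nn = 2
    while n_edges(nn) < m:
        nn += 1
    return nn


# ---------------------------------------------------------------------------
# Permutation calibration
# ---------------------------------------------------------------------------

def permutation_calibration(n_datasets: int = 200, n_subjects: int = 60,
                            n_nodes: int = 40, n_perm: int = 100,
                            alpha: float = 0.05, seed: int = 0) -> dict:
    """Rejection rate of the permutation test on null (no-signal) cohorts.

    Generates ``n_datasets`` cohorts with no planted edges, runs the full
    LOOCV CPM + permutation test on each, and reports the fraction with
    p_permu < alpha, together with the exact binomial 95% interval around
    alpha for that many trials.
    """
    ds_seeds = _child_seeds(seed, 2 * n_datasets)
    rejections = 0
    for i in range(n_datasets):
        cfg = null_config(n_subjects=n_subjects, n_nodes=n_nodes,
                          seed=int(ds_seeds[i]))
        ds = generate_dataset(cfg)
        model = CPM(ds.matrices, ds.subjects["score_ar"].to_numpy(float),
                    covariates=ds.covariate_matrix())
        p = permutation_test(model, n_perm=n_perm,
                             seed=int(ds_seeds[n_datasets + i])).p_permu
        rejections += p < alpha
    lo = stats.binom.ppf(0.025, n_datasets, alpha) / n_datasets
    hi = stats.binom.ppf(0.975, n_datasets, alpha) / n_datasets
    return {"rejection_rate": rejections / n_datasets, "n_datasets": n_datasets,
            "binomial_ci_low": float(lo), "binomial_ci_high": float(hi)}


# ---------------------------------------------------------------------------
# Planted-edge recovery
# ---------------------------------------------------------------------------

def planted_recovery(seed: int = 0, cfg: GeneratorConfig | None = None) -> dict:
    """Consensus-connectome recovery of planted edges with known truth.

    Default conditions: 80 subjects, 60 nodes, 30 positive + 30 negative
    planted edges at population correlation 0.5.  Reports the sign-correct
    recovery rate, the edge-level false-discovery proportion of the
    consensus, and the LOOCV Spearman rho.
    """
    cfg = replace(cfg or GeneratorConfig(), seed=seed)
    ds = generate_dataset(cfg)
    y = ds.subjects["score_ar"].to_numpy(float)
    res = CPM(ds.matrices, y, covariates=ds.covariate_matrix(),
              ).fit()
    cons = res.consensus_mask
    truth = ds.truth
    hits = (np.intersect1d(cons.pos_edges, truth.pos_edges).size
            + np.intersect1d(cons.neg_edges, truth.neg_edges).size)
    n_planted = truth.pos_edges.size + truth.neg_edges.size
    n_selected = cons.n_pos + cons.n_neg
    false = (np.setdiff1d(cons.pos_edges, truth.pos_edges).size
             + np.setdiff1d(cons.neg_edges, truth.neg_edges).size)
    return {
        "recovery_rate": hits / n_planted if n_planted else float("nan"),
        "false_discovery_proportion": false / n_selected if n_selected else 0.0,
        "spearman_rho": spearman_eval(y, res.predicted, allow_constant=True),
        "n_subjects": cfg.n_subjects,
        "n_selected": n_selected,
    }


# ---------------------------------------------------------------------------
# Lesion sensitivity
# ---------------------------------------------------------------------------

def lesion_config(seed: int = 0) -> GeneratorConfig:
    """Conditions for the lesion study: all planted edges inside one region.

    A 12-node motor-strip region (66 within-region pairs) hosts 10 positive
    + 10 negative planted edges at population correlation 0.5, n = 80.
    """
    return GeneratorConfig(
        n_subjects=80, n_nodes=60, region_sizes={"motor_strip": 12},
        planted_region="motor_strip", n_pos_edges=10, n_neg_edges=10,
        rho_signal=0.5, seed=seed,
    )


def lesion_sensitivity(n_replicates: int = 50, seed: int = 0,
                       uninvolved_region: str = "occipital") -> dict:
    """Lesion study over replicate cohorts with a single signal region.

    Per replicate: full-model LOOCV rho; rho after lesioning the region
    containing every planted edge; rho after lesioning an uninvolved
    region.  Reports the fraction of replicates where the signal lesion
    drops rho below 0.1 while the uninvolved lesion stays within 2
    replicate SDs of the full model, plus the lesion-importance ranking
    rate (signal region's performance drop largest among the two).
    """
    seeds = _child_seeds(seed, n_replicates)
    full_r = np.empty(n_replicates)
    les_signal = np.empty(n_replicates)
    les_other = np.empty(n_replicates)
    for i in range(n_replicates):
        cfg = lesion_config(int(seeds[i]))
        ds = generate_dataset(cfg)
        y = ds.subjects["score_ar"].to_numpy(float)
        cov = ds.covariate_matrix()
        full_r[i] = spearman_eval(
            y, CPM(ds.matrices, y, covariates=cov).fit().predicted,
            allow_constant=True)
        les_signal[i] = spearman_eval(
            y, CPM(ds.matrices, y, covariates=cov,
                   edge_subset=lesioned_edges(ds.atlas, "motor_strip")
                   ).fit().predicted, allow_constant=True)
        les_other[i] = spearman_eval(
            y, CPM(ds.matrices, y, covariates=cov,
                   edge_subset=lesioned_edges(ds.atlas, uninvolved_region)
                   ).fit().predicted, allow_constant=True)
    sd = full_r.std(ddof=1)
    joint = (les_signal < 0.1) & (np.abs(les_other - full_r) < 2 * sd)
    drop_signal = full_r - les_signal
    drop_other = full_r - les_other
    return {
        "joint_criterion_rate": float(joint.mean()),
        "signal_below_0.1_rate": float((les_signal < 0.1).mean()),
        "uninvolved_within_2sd_rate": float((np.abs(les_other - full_r) < 2 * sd).mean()),
        "ranking_rate": float((drop_signal > drop_other).mean()),
        "mean_full_rho": float(full_r.mean()),
        "mean_lesioned_signal_rho": float(les_signal.mean()),
        "replicate_sd": float(sd),
        "n_replicates": n_replicates,
    }


# ---------------------------------------------------------------------------
# Group-comparison power
# ---------------------------------------------------------------------------

def group_strength_power(n_replicates: int = 100, n_patients: int = 40,
                         n_controls: int = 40, shift: float = 0.05,
                         alpha: float = 0.05, seed: int = 0) -> dict:
    """Power of the patient-vs-control negative-network strength comparison.

    Patients are generated with the usual planted coupling; controls share
    the baseline with a ``shift`` (Fisher-z units) added on the planted
    negative-network edges, so patients have reduced negative strength.
    Reports the Mann-Whitney rejection rate in the expected direction for
    the negative network, and the rejection rate for the (unshifted)
    positive network, which should stay near alpha.
    """
    seeds = _child_seeds(seed, n_replicates)
    rej_neg = rej_pos = 0
    for i in range(n_replicates):
        cfg = GeneratorConfig(n_subjects=n_patients, seed=int(seeds[i]))
        ds = generate_dataset(cfg)
        _, control_matrices = generate_control_group(
            cfg, ds.truth, n_controls=n_controls, shift=shift)
        sp = strength_in_group(ds.truth.mask, ds.matrices)
        sc = strength_in_group(ds.truth.mask, control_matrices)
        _, p_neg = mann_whitney(sp[:, 1], sc[:, 1])
        _, p_pos = mann_whitney(sp[:, 0], sc[:, 0])
        rej_neg += (p_neg < alpha) and (np.median(sp[:, 1]) < np.median(sc[:, 1]))
        rej_pos += p_pos < alpha
    return {"negative_power": rej_neg / n_replicates,
            "positive_rejection_rate": rej_pos / n_replicates,
            "shift": shift, "n_replicates": n_replicates}
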