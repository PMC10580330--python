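"""CPM core: edge selection, strengths, linear model, LOOCV, final model."""

import numpy as np
import pytest

from neurocpm.cpm import (
    CPM,
    FittedCPM,
    edge_select,
    fit_linear,
    loocv_predict_batch,
    network_strengths,
)
from neurocpm.edges import EdgeMask, matrix_from_edges, n_edges
from neurocpm.inference import spearman_eval
from neurocpm.simulate import GeneratorConfig, generate_dataset, null_config
from neurocpm.validation import naive_partial_corr


def random_edges(rng, n, nn):
    return rng.normal(size=(n, n_edges(nn)))


class TestEdgeSelect:
    def test_no_covariates_reduces_to_pearson(self, rng):
        e = random_edges(rng, 12, 6)
        y = rng.normal(size=12)
        est, _ = edge_select(e, y, None, 0.05)
        expected = [np.corrcoef(e[:, k], y)[0, 1] for k in range(e.shape[1])]
        np.testing.assert_allclose(est.r_partial, expected, atol=1e-12)

    def test_matches_naive_residualization_oracle(self, rng):
        e = random_edges(rng, 5, 5)
        y = rng.normal(size=5)
        cov = rng.normal(size=(5, 1))
        est, _ = edge_select(e, y, cov, 0.05)
        for k in range(e.shape[1]):
            r_o, p_o = naive_partial_corr(e[:, k], y, cov)
            assert abs(est.r_partial[k] - r_o) < 1e-10
            assert abs(est.p_value[k] - p_o) < 1e-10

    def test_matches_pingouin_partial_corr(self, rng):
        pg = pytest.importorskip("pingouin")
        import pandas as pd
        e = random_edges(rng, 15, 5)
        y = rng.normal(size=15)
        cov = rng.normal(size=(15, 2))
        est, _ = edge_select(e, y, cov, 0.05)
        for k in (0, 3, 7):
            d = pd.DataFrame({"e": e[:, k], "y": y, "c1": cov[:, 0],
                              "c2": cov[:, 1]})
            out = pg.partial_corr(d, x="e", y="y", covar=["c1", "c2"])
            assert est.r_partial[k] == pytest.approx(out["r"].iloc[0], abs=1e-8)
            assert est.p_value[k] == pytest.approx(out["p_val"].iloc[0], abs=1e-8)

    def test_selection_strictly_below_threshold(self, rng):
        """An edge whose p equals the threshold exactly is not selected."""
        e = random_edges(rng, 20, 5)
        y = rng.normal(size=20)
        est, _ = edge_select(e, y, None, 0.05)
        k = int(np.argmin(est.p_value))
        # re-select with the threshold set to that edge's own p-value
        _, mask = edge_select(e, y, None, float(est.p_value[k]))
        assert k not in mask.all_edges()

    def test_constant_edge_gets_r0_p1(self, rng):
        e = random_edges(rng, 10, 5)
        e[:, 3] = 1.7
        est, mask = edge_select(e, rng.normal(size=10), None, 0.05)
        assert est.r_partial[3] == 0.0
        assert est.p_value[3] == 1.0
        assert 3 not in mask.all_edges()

    def test_constant_scores_rejected(self, rng):
        with pytest.raises(ValueError, match="constant"):
            edge_select(random_edges(rng, 10, 5), np.ones(10), None, 0.05)

    def test_threshold_monotonicity(self, rng):
        e = random_edges(rng, 30, 10)
        y = rng.normal(size=30)
        masks = [set(edge_select(e, y, None, p)[1].all_edges().tolist())
                 for p in (0.005, 0.01, 0.05)]
        assert masks[0] <= masks[1] <= masks[2]


class TestNetworkStrengths:
    def test_empty_mask(self):
        z = np.ones((5, 5))
        assert network_strengths(z, EdgeMask(n_nodes=5)) == (0.0, 0.0)

    def test_single_positive_edge(self):
        z = matrix_from_edges(np.zeros(n_edges(5)), 5)
        z[1, 3] = z[3, 1] = 0.7
        mask = EdgeMask.from_pairs(5, pos_pairs=[(1, 3)])
        assert network_strengths(z, mask) == pytest.approx((0.7, 0.0))

    def test_hand_computed_sums(self, rng):
        v = rng.normal(size=n_edges(6))
        z = matrix_from_edges(v, 6)
        mask = EdgeMask(n_nodes=6, pos_edges=[0, 4, 9], neg_edges=[2, 7])
        sp, sn = network_strengths(z, mask)
        assert sp == pytest.approx(v[0] + v[4] + v[9])
        assert sn == pytest.approx(v[2] + v[7])

    def test_mask_linearity(self, rng):
        """Strength under a disjoint union of masks is the sum of strengths."""
        v = rng.normal(size=n_edges(8))
        z = matrix_from_edges(v, 8)
        a = EdgeMask(n_nodes=8, pos_edges=[0, 1], neg_edges=[5])
        b = EdgeMask(n_nodes=8, pos_edges=[10], neg_edges=[12, 20])
        u = EdgeMask(n_nodes=8, pos_edges=[0, 1, 10], neg_edges=[5, 12, 20])
        sa, sb, su = (network_strengths(z, m) for m in (a, b, u))
        assert su[0] == pytest.approx(sa[0] + sb[0])
        assert su[1] == pytest.approx(sa[1] + sb[1])


class TestFitLinear:
    def test_exact_plane_recovered(self, rng):
        sp = rng.normal(size=30)
        sn = rng.normal(size=30)
        y = 2.0 + 1.5 * sp - 0.8 * sn
        coef = fit_linear(sp, sn, y)
        assert coef.intercept == pytest.approx(2.0, abs=1e-10)
        assert coef.slope_pos == pytest.approx(1.5, abs=1e-10)
        assert coef.slope_neg == pytest.approx(-0.8, abs=1e-10)

    def test_single_predictor_exact(self, rng):
        sp = rng.normal(size=20)
        y = 3.0 + 0.5 * sp
        coef = fit_linear(sp, None, y)
        assert coef.slope_neg is None
        np.testing.assert_allclose(coef.predict(sp, np.zeros(20)), y, atol=1e-10)

    def test_negative_only_model(self, rng):
        sn = rng.normal(size=20)
        coef = fit_linear(None, sn, 1.0 - 2.0 * sn)
        assert coef.slope_pos is None
        assert coef.slope_neg == pytest.approx(-2.0, abs=1e-10)

    def test_collinear_design_rejected(self, rng):
        sp = rng.normal(size=20)
        with pytest.raises(ValueError, match="collinear"):
            fit_linear(sp, 2 * sp, rng.normal(size=20))

    def test_too_few_subjects(self):
        with pytest.raises(ValueError, match="at least 4"):
            fit_linear(np.ones(3), None, np.ones(3))


class TestLOOCV:
    def test_each_subject_held_out_once(self, small_dataset):
        ds = small_dataset
        res = CPM(ds.matrices, ds.subjects["score_ar"].to_numpy(float)).fit()
        assert res.predicted.shape == (ds.config.n_subjects,)
        assert res.fold_signs.shape[0] == ds.config.n_subjects

    def test_consensus_subset_of_every_fold(self, small_dataset):
        ds = small_dataset
        res = CPM(ds.matrices, ds.subjects["score_ar"].to_numpy(float)).fit()
        cons = res.consensus_mask
        assert not cons.is_empty
        for j in range(res.fold_signs.shape[0]):
            assert (res.fold_signs[j, cons.pos_edges] == 1).all()
            assert (res.fold_signs[j, cons.neg_edges] == -1).all()

    def test_consensus_invariant_to_subject_order(self, small_dataset):
        ds = small_dataset
        y = ds.subjects["score_ar"].to_numpy(float)
        perm = np.random.default_rng(4).permutation(y.size)
        a = CPM(ds.matrices, y).fit().consensus_mask
        b = CPM(ds.matrices[perm], y[perm]).fit().consensus_mask
        np.testing.assert_array_equal(a.pos_edges, b.pos_edges)
        np.testing.assert_array_equal(a.neg_edges, b.neg_edges)

    def test_planted_signal_recovered(self, planted_dataset):
        ds = planted_dataset
        y = ds.subjects["score_ar"].to_numpy(float)
        res = CPM(ds.matrices, y, covariates=ds.covariate_matrix()).fit()
        cons = res.consensus_mask
        hits = (np.intersect1d(cons.pos_edges, ds.truth.pos_edges).size
                + np.intersect1d(cons.neg_edges, ds.truth.neg_edges).size)
        assert hits / 60 >= 0.8
        assert res.rho > 0.3

    def test_null_data_small_consensus(self):
        sizes, rhos = [], []
        for i in range(5):
            ds = generate_dataset(null_config(n_subjects=60, n_nodes=40,
                                              seed=400 + i))
            y = ds.subjects["score_ar"].to_numpy(float)
            res = CPM(ds.matrices, y).fit()
            sizes.append(res.consensus_mask.n_pos + res.consensus_mask.n_neg)
            rhos.append(res.rho)
        assert np.mean(sizes) < 5
        assert abs(np.mean(rhos)) < 0.4  # centered on 0, wide null spread

    def test_affine_score_equivariance(self, small_dataset):
        """Rescaling scores by a positive affine map rescales predictions."""
        ds = small_dataset
        y = ds.subjects["score_ar"].to_numpy(float)
        a, b = 2.5, 7.0
        r1 = CPM(ds.matrices, y).fit()
        r2 = CPM(ds.matrices, a * y + b).fit()
        np.testing.assert_allclose(r2.predicted, a * r1.predicted + b,
                                   rtol=1e-8, atol=1e-8)
        assert spearman_eval(y, r1.predicted) == pytest.approx(
            spearman_eval(a * y + b, r2.predicted), abs=1e-12)

    def test_batched_engine_matches_per_column_runs(self, rng):
        e = rng.normal(size=(25, n_edges(10)))
        cov = rng.normal(size=(25, 2))
        ys = rng.normal(size=(25, 4))
        batch, _ = loocv_predict_batch(e, ys, cov, 0.05)
        for c in range(4):
            single, _ = loocv_predict_batch(e, ys[:, c:c + 1], cov, 0.05)
            np.testing.assert_allclose(batch[:, c], single[:, 0], atol=1e-10)

    def test_too_few_subjects_rejected(self, rng):
        with pytest.raises(ValueError, match="at least 10"):
            CPM(rng.normal(size=(5, n_edges(6))), rng.normal(size=5)).fit()


class TestFinalModel:
    def test_final_mask_subset_of_full_selection(self, small_dataset):
        ds = small_dataset
        y = ds.subjects["score_ar"].to_numpy(float)
        model = CPM(ds.matrices, y)
        final = model.fit_final()
        _, full_mask = edge_select(ds.edge_matrix, y, None, model.threshold_p)
        assert set(final.mask.pos_edges) <= set(full_mask.pos_edges)
        assert set(final.mask.neg_edges) <= set(full_mask.neg_edges)

    def test_coefficient_signs_on_planted_data(self, planted_dataset):
        ds = planted_dataset
        y = ds.subjects["score_ar"].to_numpy(float)
        final = CPM(ds.matrices, y, covariates=ds.covariate_matrix()).fit_final()
        assert final.coefficients.slope_pos > 0
        assert final.coefficients.slope_neg < 0

    def test_apply_to_training_reproduces_fitted_values(self, small_dataset):
        ds = small_dataset
        y = ds.subjects["score_ar"].to_numpy(float)
        model = CPM(ds.matrices, y)
        final = model.fit_final()
        sp = ds.edge_matrix[:, final.mask.pos_edges].sum(1)
        sn = ds.edge_matrix[:, final.mask.neg_edges].sum(1)
        np.testing.assert_allclose(final.predict(ds.matrices),
                                   final.coefficients.predict(sp, sn))

    def test_external_set_positive_association(self, planted_dataset):
        ds = planted_dataset
        y = ds.subjects["score_ar"].to_numpy(float)
        final = CPM(ds.matrices, y, covariates=ds.covariate_matrix()).fit_final()
        from neurocpm.simulate import generate_external_set
        ext = generate_external_set(ds.config, ds.truth, n_subjects=17,
                                    seed=4242)
        y_ext = ext.subjects["score_ar"].to_numpy(float)
        pred = final.predict(ext.matrices)
        assert spearman_eval(y_ext, pred) > 0

    def test_intercept_only_degenerate_model_constant(self):
        coef_mask = EdgeMask(n_nodes=5)
        from neurocpm.cpm import LinearCoefficients
        model = FittedCPM(mask=coef_mask,
                          coefficients=LinearCoefficients(3.0, None, None),
                          n_train=10, threshold_p=0.01, n_covariates=0)
        pred = model.predict(np.zeros((4, 5, 5)))
        np.testing.assert_array_equal(pred, 3.0)

    def test_dimension_mismatch_rejected(self, small_dataset):
        ds = small_dataset
        final = CPM(ds.matrices,
                    ds.subjects["score_ar"].to_numpy(float)).fit_final()
        with pytest.raises(ValueError, match="nodes"):
            final.predict(np.zeros((2, 7, 7)))

    def test_serialization_round_trip(self, small_dataset):
        ds = small_dataset
        final = CPM(ds.matrices,
                    ds.subjects["score_ar"].to_numpy(float)).fit_final()
        back = FittedCPM.from_dict(final.to_dict())
        np.testing.assert_array_equal(back.mask.pos_edges, final.mask.pos_edges)
        np.testing.assert_allclose(back.predict(ds.matrices),
                                   final.predict(ds.matrices))
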