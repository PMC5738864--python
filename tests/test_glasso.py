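import numpy as np
import pandas as pd
import pytest

from plastinet.glasso import (CovarianceModel, calibrate_rho,
                              condition_number, extract_edges, glasso_fit,
                              penalized_objective, sample_covariance)
from plastinet.io import ExpressionMatrix
from plastinet.synthetic import SyntheticSpec, generate


def random_spd(rng, p=5, n=40):
    return np.cov(rng.standard_normal((n, p)).T, ddof=1)


def cov_model(S, n=40):
    return CovarianceModel(S, [f"g{i}" for i in range(S.shape[0])], n)


class TestSampleCovariance:
    def test_matches_direct_formula(self, small_expr):
        cm = sample_covariance(small_expr)
        x = small_expr.values.to_numpy()
        centered = x - x.mean(axis=1, keepdims=True)
        expected = centered @ centered.T / (x.shape[1] - 1)
        assert np.allclose(cm.S, expected, atol=1e-12)

    def test_perfectly_correlated_pair(self):
        vals = pd.DataFrame([[1.0, 2.0, 3.0, 4.0], [2.0, 4.0, 6.0, 8.0]],
                            index=["a", "b"], columns=list("wxyz"))
        groups = pd.Series(["naive", "naive", "plastic", "plastic"],
                           index=vals.columns)
        cm = sample_covariance(ExpressionMatrix(vals, groups))
        sd = vals.std(axis=1, ddof=1)
        assert cm.S[0, 1] == pytest.approx(sd["a"] * sd["b"])

    def test_single_sample_rejected(self):
        vals = pd.DataFrame([[1.0], [2.0]], index=["a", "b"], columns=["s"])
        groups = pd.Series(["naive"], index=["s"])
        with pytest.raises(ValueError, match="2 samples"):
            sample_covariance(ExpressionMatrix(vals, groups))

    def test_unknown_gene_rejected(self, small_expr):
        with pytest.raises(KeyError, match="nope"):
            sample_covariance(small_expr, ["p1", "nope"])


class TestGlassoAnalyticLimits:
    def test_identity_covariance_gives_identity_precision(self):
        for rho in (0.0, 0.1, 1.0):
            est = glasso_fit(cov_model(np.eye(4)), rho,
                             penalize_diagonal=False)
            assert np.allclose(est.gamma, np.eye(4), atol=1e-8)

    def test_rho_zero_recovers_exact_inverse_2x2(self):
        S = np.array([[2.0, 1.0], [1.0, 2.0]])
        est = glasso_fit(cov_model(S), 0.0, penalize_diagonal=False,
                         tol=1e-8, max_iter=500)
        expected = np.array([[2 / 3, -1 / 3], [-1 / 3, 2 / 3]])
        assert np.allclose(est.gamma, expected, atol=1e-6)

    def test_rho_zero_matches_inverse_on_well_conditioned(self, rng):
        S = random_spd(rng, p=5, n=200)
        est = glasso_fit(cov_model(S, 200), 0.0, penalize_diagonal=False,
                         tol=1e-10, max_iter=1000)
        inv = np.linalg.inv(S)
        assert np.linalg.norm(est.gamma - inv) / np.linalg.norm(inv) < 1e-8

    def test_annihilation_bound_gives_diagonal_estimate(self, rng):
        # with diagonal penalization and rho >= max offdiag |S|,
        # the estimate is exactly diagonal (theorem-backed)
        S = random_spd(rng, p=8, n=30)
        rho = np.abs(S - np.diag(np.diag(S))).max()
        est = glasso_fit(cov_model(S, 30), rho, penalize_diagonal=True)
        off = est.gamma - np.diag(np.diag(est.gamma))
        assert np.abs(off).max() == 0.0
        assert extract_edges(est, 1e-4).n_edges == 0

    def test_single_gene(self):
        est = glasso_fit(cov_model(np.array([[4.0]]), 10), 0.5,
                         penalize_diagonal=True)
        assert est.gamma[0, 0] == pytest.approx(1.0 / 4.5)

    def test_negative_rho_rejected(self):
        with pytest.raises(ValueError, match="rho"):
            glasso_fit(cov_model(np.eye(2)), -0.1)

    def test_asymmetric_covariance_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            CovarianceModel(np.array([[1.0, 0.5], [0.2, 1.0]]), ["a", "b"], 5)


class TestGlassoConvergence:
    @pytest.mark.parametrize("rho", [0.01, 0.1, 0.5])
    @pytest.mark.parametrize("penalize_diagonal", [True, False])
    def test_objective_non_increasing_across_sweeps(self, rng, rho,
                                                    penalize_diagonal):
        S = random_spd(rng, p=6, n=40)
        est = glasso_fit(cov_model(S), rho,
                         penalize_diagonal=penalize_diagonal,
                         track_objective=True)
        path = np.array(est.objective_path)
        assert np.all(np.diff(path) <= 1e-10)

    def test_estimate_is_symmetric_positive_definite(self, rng):
        for _ in range(5):
            S = random_spd(rng)
            est = glasso_fit(cov_model(S), 0.2)
            assert np.allclose(est.gamma, est.gamma.T)
            assert np.linalg.eigvalsh(est.gamma).min() > 0
            assert est.converged

    def test_edge_count_non_increasing_in_rho(self):
        # on the diagonally-dominant synthetic family
        ds = generate(SyntheticSpec(n_genes=40, n_naive=100, n_plastic=100,
                                    regulated_fraction=0.5, effect_size=0.0,
                                    seed=9))
        cov = sample_covariance(ds.expression, ds.planted_gene_ids)
        counts = [extract_edges(glasso_fit(cov, rho), 1e-4).n_edges
                  for rho in (0.01, 0.05, 0.1, 0.3, 0.6, 1.0)]
        assert counts == sorted(counts, reverse=True)

    def test_max_iter_reached_flags_unconverged(self, rng):
        S = random_spd(rng)
        est = glasso_fit(cov_model(S), 0.1, tol=1e-12, max_iter=1)
        assert not est.converged
        assert est.n_iter == 1


class TestEdgeExtraction:
    def make_estimate(self, gamma):
        from plastinet.glasso import PrecisionEstimate
        ids = [f"g{i}" for i in range(gamma.shape[0])]
        return PrecisionEstimate(gamma, ids, 0.1, 0.0, 1, True, True)

    def test_diagonal_precision_gives_empty_network(self):
        net = extract_edges(self.make_estimate(np.diag([1.0, 2.0, 3.0])))
        assert net.n_edges == 0 and net.n_nodes == 0

    def test_threshold_boundary_is_inclusive(self):
        gamma = np.eye(3)
        gamma[0, 1] = gamma[1, 0] = 0.00009
        gamma[0, 2] = gamma[2, 0] = 0.0002
        net = extract_edges(self.make_estimate(gamma), link_threshold=0.0001)
        assert net.edge_pairs() == [("g0", "g2")]
        gamma[0, 1] = gamma[1, 0] = 0.0001  # exactly at the threshold
        net = extract_edges(self.make_estimate(gamma), link_threshold=0.0001)
        assert net.n_edges == 2

    def test_weights_keep_sign(self):
        gamma = np.eye(2)
        gamma[0, 1] = gamma[1, 0] = -0.5
        net = extract_edges(self.make_estimate(gamma))
        assert net.graph.edges["g0", "g1"]["weight"] == pytest.approx(-0.5)


class TestConditionNumber:
    def test_identity_is_one(self):
        rep = condition_number(np.eye(7))
        assert rep.kappa == pytest.approx(1.0)
        assert rep.digits_lost == pytest.approx(0.0)
        assert not rep.singular

    def test_diagonal_closed_form(self):
        rep = condition_number(np.diag([1.0, 10.0]))
        assert rep.kappa == pytest.approx(10.0)
        assert rep.digits_lost == pytest.approx(1.0)

    def test_singular_matrix_flagged(self):
        rep = condition_number(np.array([[1.0, 1.0], [1.0, 1.0]]))
        assert rep.singular
        assert rep.kappa == np.inf or rep.kappa > 1e15

    def test_near_singular_reports_large_kappa(self):
        M = np.eye(3)
        M[0, 0] = 1e-14
        rep = condition_number(M)
        assert rep.kappa > 1e13


class TestCalibrateRho:
    def test_empty_reference_chooses_smallest_annihilating_rho(self, rng):
        S = random_spd(rng, p=5)
        cm = cov_model(S)
        rho_max = np.abs(S - np.diag(np.diag(S))).max()
        grid = [0.1 * rho_max, 0.5 * rho_max, rho_max, 2 * rho_max]
        cal = calibrate_rho(cm, set(), grid)
        assert cal.best_score == 1.0
        # any rho >= max offdiag |S| annihilates all edges and scores 1.0;
        # the chosen rho is the smallest scoring one, never above rho_max
        assert cal.scores[grid.index(rho_max)] == 1.0
        assert cal.chosen_rho <= rho_max + 1e-12

    def test_planted_hub_recovered_exactly_at_high_n(self):
        ds = generate(SyntheticSpec(n_genes=60, n_naive=1500, n_plastic=1500,
                                    regulated_fraction=0.5, effect_size=0.0,
                                    seed=42))
        cov = sample_covariance(ds.expression, ds.planted_gene_ids)
        ref = {frozenset(e) for e in ds.adjacency_edges}
        cal = calibrate_rho(cov, ref, [0.005, 0.01, 0.02, 0.05, 0.1, 0.3])
        assert cal.best_score == 1.0
        assert cal.chosen_rho == pytest.approx(0.05)

    def test_empty_grid_rejected(self, rng):
        with pytest.raises(ValueError, match="grid"):
            calibrate_rho(cov_model(random_spd(rng)), set(), [])
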