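"""Penalized regression correctness: closed-form oracles, CV behavior,
network assembly and the display filter."""

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet

from clpnet import simulate
from clpnet._cd import enet_path_gram
from clpnet.estimate import (
    CLPNetwork,
    estimate_clpn,
    filter_display,
    fit_elastic_net,
    fit_outcome,
    lambda_grid,
    read_network_csv,
    standardize,
    write_network_csv,
    write_network_graphml,
)
from clpnet.panel import PanelDataset

from conftest import FAST


def _standard_design(rng, n=2000, p=15, rho_signal=0.2):
    X = rng.standard_normal((n, p))
    X = (X - X.mean(0)) / X.std(0)
    beta = rng.standard_normal(p) * rho_signal
    y = X @ beta + rng.standard_normal(n)
    y = (y - y.mean()) / y.std()
    return X, y


class TestStandardize:
    def test_columns_mean_zero_sd_one(self, planted_panel):
        X1, X2, scaling = standardize(planted_panel)
        for X in (X1, X2):
            np.testing.assert_allclose(X.mean(0), 0, atol=1e-12)
            np.testing.assert_allclose(X.std(0), 1, atol=1e-12)
        assert list(scaling.index) == planted_panel.node_ids

    def test_idempotent_on_standardized_input(self, rng):
        x = rng.standard_normal(1000)
        z = (x - x.mean()) / x.std()
        z2 = (z - z.mean()) / z.std()
        np.testing.assert_allclose(z, z2, atol=1e-12)

    def test_constant_column_error_names_node(self):
        t1 = np.zeros((100, 15))
        t2 = np.zeros((100, 15))
        with pytest.raises(ValueError, match="De1"):
            standardize(PanelDataset(t1, t2))

    def test_reverse_scoring_flips_standardized_sign(self, planted_panel):
        X1_rev, _, _ = standardize(planted_panel, reverse_score=True)
        X1_raw, _, _ = standardize(planted_panel, reverse_score=False)
        j = planted_panel.node_ids.index("De5")
        np.testing.assert_allclose(X1_rev[:, j], -X1_raw[:, j], atol=1e-12)
        k = planted_panel.node_ids.index("De1")
        np.testing.assert_allclose(X1_rev[:, k], X1_raw[:, k], atol=1e-12)


class TestClosedFormOracles:
    def test_lambda_zero_matches_least_squares(self, rng):
        X, y = _standard_design(rng)
        ols = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(fit_elastic_net(X, y, 0.0), ols, atol=1e-10)
        # path solver at (numerically) zero penalty
        grid = np.array([1e-12])
        path = enet_path_gram(X.T @ X, X.T @ y, len(y), grid, 1.0, tol=1e-12)
        np.testing.assert_allclose(path[:, 0], ols, atol=1e-4)

    def test_orthonormal_design_soft_threshold(self, rng):
        # columns scaled so X'X = n I: lasso coefficient j is
        # sign(b_j) * max(|b_j| - lam, 0) with b = X'y / n
        n, p = 1024, 8
        Q, _ = np.linalg.qr(rng.standard_normal((n, p)))
        X = Q * np.sqrt(n)
        beta = np.linspace(-0.5, 0.5, p)
        y = X @ beta + rng.standard_normal(n)
        b = X.T @ y / n
        for lam in (0.05, 0.2, 0.4):
            expected = np.sign(b) * np.maximum(np.abs(b) - lam, 0.0)
            got = fit_elastic_net(X, y, lam, alpha=1.0)
            np.testing.assert_allclose(got, expected, atol=1e-6)
            path = enet_path_gram(X.T @ X, X.T @ y, n, np.array([lam]), 1.0, tol=1e-12)
            np.testing.assert_allclose(path[:, 0], expected, atol=1e-8)

    def test_lambda_max_zeroes_every_coefficient(self, rng):
        X, y = _standard_design(rng, n=500)
        lam_max = np.max(np.abs(X.T @ y)) / len(y)
        assert np.all(fit_elastic_net(X, y, lam_max * 1.0001) == 0)

    @pytest.mark.parametrize("alpha", [1.0, 0.5])
    def test_path_solver_matches_sklearn(self, rng, alpha):
        # dual-route check of the Gram-based coordinate descent
        X, y = _standard_design(rng, n=800, p=10)
        grid = lambda_grid(X, y, alpha, n_lambdas=12)
        path = enet_path_gram(X.T @ X, X.T @ y, len(y), grid, alpha, tol=1e-12)
        for m in (0, 5, 11):
            sk = ElasticNet(
                alpha=grid[m], l1_ratio=alpha, fit_intercept=False,
                tol=1e-12, max_iter=200_000,
            ).fit(X, y)
            np.testing.assert_allclose(path[:, m], sk.coef_, atol=1e-8)


class TestFitOutcome:
    def test_cv_recovers_signal_and_records_curve(self, rng):
        X, y = _standard_design(rng)
        fit = fit_outcome(X, y, seed=1)
        assert fit.cv_mse.shape == fit.grid.shape
        assert fit.lambda_ in fit.grid
        assert fit.cv_mse.min() <= 1.0  # never worse than the null model

    def test_edge_count_monotone_along_path(self, rng):
        X, y = _standard_design(rng)
        fit = fit_outcome(X, y, seed=2)
        nnz = (np.abs(fit.coef_path) > 1e-12).sum(axis=0)
        assert np.all(np.diff(nnz) >= 0)  # grid is decreasing in penalty

    def test_seed_determinism(self, rng):
        X, y = _standard_design(rng, n=600)
        a = fit_outcome(X, y, seed=3)
        b = fit_outcome(X, y, seed=3)
        np.testing.assert_array_equal(a.coef, b.coef)
        assert a.lambda_ == b.lambda_

    def test_invalid_folds_rejected(self, rng):
        X, y = _standard_design(rng, n=50)
        with pytest.raises(ValueError, match="folds"):
            fit_outcome(X, y, k=51)
        with pytest.raises(ValueError, match="grid"):
            fit_outcome(X, y, grid=np.array([]))


class TestEstimateClpn:
    def test_null_structure_yields_near_empty_network(self, null_truth):
        panel = simulate.simulate_panel(null_truth, n=10_000, seed=200)
        net = estimate_clpn(panel, k=FAST.cv_folds, n_lambdas=FAST.n_lambdas, seed=5)
        off = ~np.eye(15, dtype=bool)
        assert np.abs(net.B[off]).mean() < 0.02
        assert (np.abs(net.B[off]) >= 0.05).mean() <= 0.05

    def test_planted_edge_recovered_with_sign(self, planted_truth, planted_panel):
        net = estimate_clpn(planted_panel, k=FAST.cv_folds, n_lambdas=FAST.n_lambdas, seed=6)
        off = ~np.eye(15, dtype=bool)
        planted = (planted_truth.true_B != 0) & off
        strongest = np.unravel_index(
            np.argmax(np.abs(planted_truth.true_B * planted)), (15, 15)
        )
        assert np.sign(net.B[strongest]) == np.sign(planted_truth.true_B[strongest])
        # the strongest planted edge ranks among the top off-diagonal estimates
        rank = (np.abs(net.B[off]) >= abs(net.B[strongest])).sum()
        assert rank <= 20

    def test_autoregressive_effects_on_diagonal(self, planted_panel):
        net = estimate_clpn(planted_panel, k=FAST.cv_folds, n_lambdas=FAST.n_lambdas, seed=7)
        # stationarity + positive AR in truth: diagonal mostly positive
        assert (np.diag(net.B) > 0).mean() > 0.8

    def test_determinism_given_seed(self, planted_panel):
        a = estimate_clpn(planted_panel, k=5, n_lambdas=20, seed=8)
        b = estimate_clpn(planted_panel, k=5, n_lambdas=20, seed=8)
        np.testing.assert_array_equal(a.B, b.B)
        np.testing.assert_array_equal(a.lambdas, b.lambdas)


class TestDisplayFilter:
    def _toy(self):
        B = np.zeros((15, 15))
        B[1, 3] = -0.19
        B[2, 4] = 0.04
        B[0, 0] = 0.5
        ids = [f"N{i}" for i in range(15)]
        return CLPNetwork(B, ids, ["depressive"] * 10 + ["internet"] * 5)

    def test_threshold_and_autoregressive_exclusion(self):
        disp = filter_display(self._toy(), threshold=0.05)
        assert disp.mask[1, 3]       # |−0.19| retained
        assert not disp.mask[2, 4]   # 0.04 dropped
        assert not disp.mask[0, 0]   # autoregressive dropped
        assert disp.n_retained == 1

    def test_zero_threshold_keeps_everything(self):
        disp = filter_display(self._toy(), threshold=0.0, drop_autoregressive=False)
        assert disp.mask.all()

    def test_negative_threshold_rejected(self):
        with pytest.raises(ValueError):
            filter_display(self._toy(), threshold=-0.1)

    def test_retained_edges_sorted_by_magnitude(self):
        net = self._toy()
        net.B[5, 6] = 0.30
        edges = filter_display(net).retained_edges()
        assert list(edges.beta.abs()) == sorted(edges.beta.abs(), reverse=True)


class TestNetworkIO:
    def test_csv_round_trip(self, planted_panel, tmp_path):
        net = estimate_clpn(planted_panel, k=5, n_lambdas=20, seed=9)
        write_network_csv(net, tmp_path / "adj.csv")
        back = read_network_csv(tmp_path / "adj.csv")
        np.testing.assert_allclose(back.B, net.B, atol=1e-9)
        assert back.node_ids == net.node_ids

    def test_graphml_export_has_weights_and_flags(self, tmp_path):
        import networkx as nx

        B = np.zeros((15, 15))
        B[0, 10] = 0.2
        B[1, 2] = -0.03
        ids = [f"De{i}" for i in range(1, 11)] + [f"In{i}" for i in range(1, 6)]
        net = CLPNetwork(B, ids, ["depressive"] * 10 + ["internet"] * 5)
        write_network_graphml(net, tmp_path / "net.graphml")
        g = nx.read_graphml(tmp_path / "net.graphml")
        assert g["De1"]["In1"]["weight"] == pytest.approx(0.2)
        assert g["De1"]["In1"]["retained"] is True
        assert g["De2"]["De3"]["retained"] is False
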