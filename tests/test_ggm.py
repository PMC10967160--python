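"""Correlation input, graphical lasso, EBIC and network selection."""

import numpy as np
import pandas as pd
import pytest

from nssinet import (
    SimConfig,
    correlation_matrix,
    ebic,
    estimate_network,
    glasso,
    make_true_network,
    partial_corr_from_precision,
    sample_likert,
)
from nssinet.ggm import (
    CorrMatrix,
    ZeroVarianceError,
    lambda_path,
    nearest_psd,
    _bvn_cdf,
)


class TestCorrelationMatrix:
    def test_identical_columns_correlate_perfectly(self):
        frame = pd.DataFrame({"a": [1, 2, 3, 4, 5, 1], "b": [1, 2, 3, 4, 5, 1],
                              "c": [2, 1, 4, 3, 1, 5]})
        C = correlation_matrix(frame, "spearman")
        assert C.S[0, 1] == pytest.approx(1.0)

    def test_spearman_invariant_to_monotone_transform(self, toy_table):
        C1 = correlation_matrix(toy_table, "spearman")
        warped = toy_table.copy()
        warped["GAD1"] = np.exp(warped["GAD1"].astype(float))  # strictly monotone
        C2 = correlation_matrix(warped, "spearman")
        np.testing.assert_allclose(C1.S, C2.S, atol=1e-12)

    def test_spearman_matches_rank_then_pearson_oracle(self, toy_table):
        """Six-participant toy table against explicit rank->Pearson."""
        C = correlation_matrix(toy_table, "spearman")
        cols = list(toy_table.columns)
        for i, a in enumerate(cols):
            for j, b in enumerate(cols):
                x = toy_table[a].rank().to_numpy()
                y = toy_table[b].rank().to_numpy()
                xm, ym = x - x.mean(), y - y.mean()
                expect = (xm @ ym) / np.sqrt((xm @ xm) * (ym @ ym))
                assert C.S[i, j] == pytest.approx(expect, abs=1e-12)

    def test_zero_variance_item_named_in_error(self, toy_table):
        bad = toy_table.assign(GAD9=1)
        with pytest.raises(ZeroVarianceError, match="GAD9"):
            correlation_matrix(bad)

    def test_nearest_psd_output_is_psd_unit_diagonal(self):
        S = np.array([[1.0, 0.9, -0.9], [0.9, 1.0, 0.9], [-0.9, 0.9, 1.0]])
        assert np.linalg.eigvalsh(S)[0] < 0  # genuinely indefinite input
        A = nearest_psd(S)
        assert np.linalg.eigvalsh(A)[0] >= 0
        np.testing.assert_allclose(np.diag(A), 1.0)

    def test_polychoric_recovers_latent_correlation(self):
        """5-category ordinal pair with known latent rho = 0.5."""
        rng = np.random.default_rng(0)
        n = 4000
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=n)
        cuts = [-1.0, -0.3, 0.4, 1.1]
        frame = pd.DataFrame(
            {"a": np.searchsorted(cuts, z[:, 0]), "b": np.searchsorted(cuts, z[:, 1])}
        )
        C = correlation_matrix(frame, "polychoric")
        assert C.S[0, 1] == pytest.approx(0.5, abs=0.04)

    def test_bvn_cdf_against_scipy(self):
        from scipy.stats import multivariate_normal

        pts = [(-0.5, 1.2), (0.0, 0.7), (0.3, 0.0), (0.0, 0.0), (2.0, -1.5)]
        for rho in (-0.6, 0.0, 0.45, 0.9):
            mvn = multivariate_normal([0, 0], [[1, rho], [rho, 1]])
            for h, k in pts:
                ours = float(_bvn_cdf(np.array(h), np.array(k), rho))
                assert ours == pytest.approx(mvn.cdf([h, k]), abs=5e-7)


class TestGlasso:
    def _corr(self, S, n=500):
        return CorrMatrix(S=S, n=n, method="pearson",
                          node_labels=tuple(f"V{i}" for i in range(S.shape[0])))

    def test_identity_input_gives_identity_precision(self):
        fit = glasso(self._corr(np.eye(4)), 0.1)
        np.testing.assert_allclose(fit.precision, np.eye(4), atol=1e-8)
        assert fit.n_edges == 0

    def test_penalty_above_threshold_empties_graph(self, rng):
        A = rng.normal(size=(200, 5))
        S = np.corrcoef(A, rowvar=False)
        lam_max = np.abs(S[np.triu_indices(5, 1)]).max()
        fit = glasso(self._corr(S), lam_max * 1.0001)
        assert fit.n_edges == 0

    def test_unpenalized_fit_equals_direct_inversion(self, rng):
        A = rng.normal(size=(2000, 4))
        S = np.corrcoef(A, rowvar=False)
        fit = glasso(self._corr(S), 0.0)
        np.testing.assert_allclose(fit.precision, np.linalg.inv(S), atol=1e-5)

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError, match=">= 0"):
            glasso(self._corr(np.eye(3)), -0.1)

    def test_edge_count_nonincreasing_in_lambda(self, small_world):
        _, _, table = small_world
        C = correlation_matrix(table)
        counts = [glasso(C, lam).n_edges for lam in np.linspace(0.01, 0.5, 12)]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestEbic:
    def _fit(self, loglik, E):
        class F:  # minimal stand-in carrying the two fields ebic reads
            pass

        f = F()
        f.loglik = loglik
        f.n_edges = E
        return f

    def test_worked_arithmetic_example(self):
        """loglik=-100, E=5, n=100, p=10, gamma=0.5 -> 246.0517."""
        score = ebic(self._fit(-100.0, 5), n=100, p=10, gamma=0.5)
        assert score == pytest.approx(200 + 5 * np.log(100) + 10 * np.log(10), abs=1e-4)
        assert score == pytest.approx(246.0517, abs=1e-4)

    def test_gamma_zero_reduces_to_bic(self):
        score = ebic(self._fit(-50.0, 7), n=200, p=12, gamma=0.0)
        assert score == pytest.approx(100 + 7 * np.log(200))

    def test_empty_graph_scores_minus_twice_loglik(self):
        assert ebic(self._fit(-33.0, 0), n=100, p=5, gamma=0.5) == pytest.approx(66.0)


class TestEstimateNetwork:
    def test_single_lambda_at_max_gives_empty_network(self, small_world):
        _, _, table = small_world
        net = estimate_network(table, n_lambda=1)
        assert net.n_edges() == 0

    def test_lambda_override_unpenalized_matches_inversion(self, small_world):
        _, _, table = small_world
        C = correlation_matrix(table)
        net = estimate_network(table, lambdas=[0.0])
        expect = partial_corr_from_precision(np.linalg.inv(C.S))
        np.testing.assert_allclose(net.weights, expect, atol=1e-5)

    def test_permutation_equivariance(self, small_world, rng):
        """Relabeling nodes permutes the weight matrix (up to the coordinate
        descent solver's sweep-order tolerance, ~1e-4)."""
        _, _, table = small_world
        net = estimate_network(table.values)
        perm = rng.permutation(table.values.shape[1])
        cols = [table.values.columns[k] for k in perm]
        net_p = estimate_network(table.values[cols])
        np.testing.assert_allclose(
            net_p.weights, net.weights[np.ix_(perm, perm)], atol=5e-4
        )

    def test_abs_weight_sum_shrinks_along_path(self, small_world):
        """Total |partial correlation| decreases as the penalty grows."""
        _, _, table = small_world
        C = correlation_matrix(table)
        lams = lambda_path(C.S, 12, 0.01)
        sums = []
        for lam in lams:  # lams descend; reverse later for the check
            W = partial_corr_from_precision(glasso(C, lam).precision)
            sums.append(np.abs(W).sum())
        increasing_lam = sums[::-1]
        assert all(a >= b - 1e-6 for a, b in zip(increasing_lam, increasing_lam[1:]))

    def test_strong_edges_recovered_with_correct_sign(self):
        """All true edges with |rho| >= 0.3 appear with the right sign at
        n = 2000."""
        cfg = SimConfig(n=2000, seed=77)
        truth = make_true_network(cfg)
        table = sample_likert(truth, cfg)
        net = estimate_network(table)
        strong = np.abs(truth.partial_corr) >= 0.3
        strong[np.tril_indices(truth.p)] = False
        assert strong.sum() > 0
        for i, j in zip(*np.where(strong)):
            assert np.sign(net.weights[i, j]) == np.sign(truth.partial_corr[i, j])

    def test_edge_list_ordering_contract(self, small_world):
        _, _, table = small_world
        net = estimate_network(table)
        edges = net.edge_list()
        assert (edges["node_a"] < edges["node_b"]).all()
        assert (edges["weight"].abs() > 0).all()
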