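"""Polychoric estimation, graphical lasso, EBIC selection, descriptives."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from griefnet._rng import substream
from griefnet.data import NODE_LABELS
from griefnet.network import (
    CorrelationMatrix,
    EBICConfig,
    SymptomNetwork,
    build_node_table,
    bvn_cdf,
    ebic,
    ebic_select,
    estimate_network_stacked,
    graphical_lasso,
    network_descriptives,
    polychoric_corr,
    polychoric_matrix,
    precision_to_partial,
)
from griefnet.synthetic import generate_true_network, sample_ordinal


class TestBuildNodeTable:
    def test_cluster_sum(self, cohort):
        nodes = build_node_table(cohort.items.values)
        expected = cohort.items.values["CAPS_01"] + cohort.items.values["CAPS_02"]
        assert (nodes["Re"] == expected).all()

    def test_thirteen_labels(self, cohort):
        nodes = build_node_table(cohort.items.values)
        assert tuple(nodes.columns) == NODE_LABELS
        assert len(nodes.columns) == 13

    def test_minimum_items_give_minimum_nodes(self):
        row = {c: 1.0 for c in cohort_items_min().columns}
        df = pd.DataFrame([row])
        df[[c for c in df.columns if not c.startswith("TGI")]] = 0.0
        nodes = build_node_table(df)
        assert (nodes[["Pr", "Ye", "AL", "BA", "ML", "Nu", "PD"]] == 1).all().all()
        assert (nodes[["Re", "Av", "Th", "ad", "NSC", "DR"]] == 0).all().all()

    def test_missing_constituent_raises(self, cohort):
        with pytest.raises(ValueError, match="CAPS_01"):
            broken = cohort.items.values.copy()
            broken.loc[0, "CAPS_01"] = np.nan
            build_node_table(broken)


def cohort_items_min():
    from griefnet.data import ITEM_COLUMNS
    return pd.DataFrame(columns=list(ITEM_COLUMNS))


class TestBivariateNormal:
    def test_matches_scipy_mvn(self):
        rng = substream(1, "bvn")
        for rho in (-0.9, -0.4, 0.0, 0.3, 0.8):
            pts = rng.uniform(-3.5, 3.5, size=(25, 2))
            ref = np.array([stats.multivariate_normal([0, 0], [[1, rho], [rho, 1]]).cdf(p)
                            for p in pts])
            assert np.abs(bvn_cdf(pts[:, 0], pts[:, 1], rho) - ref).max() < 1e-12

    def test_boundary_values(self):
        assert bvn_cdf(np.array(8.0), np.array(8.0), 0.5) == pytest.approx(1.0, abs=1e-10)
        assert bvn_cdf(np.array(-8.0), np.array(3.0), 0.5) == pytest.approx(0.0, abs=1e-10)


class TestPolychoric:
    def test_duplicated_column_clips_at_bound(self):
        rng = substream(2, "poly")
        x = rng.integers(0, 5, size=400)
        assert polychoric_corr(x, x) == pytest.approx(0.999, abs=1e-6)

    def test_independent_ordinals_near_zero(self):
        rng = substream(3, "poly")
        x = rng.integers(0, 5, size=5000)
        y = rng.integers(0, 5, size=5000)
        assert abs(polychoric_corr(x, y)) <= 0.05

    @pytest.mark.parametrize("rho", [0.0, 0.3, 0.6])
    def test_grid_search_likelihood_oracle(self, rho):
        """The optimizer agrees with a brute-force grid search of the same
        cell-probability likelihood to within 0.01."""
        from griefnet.network import _cell_probabilities, _marginal_thresholds

        net = generate_true_network(2, 1.0, rho, rho, seed=5) if rho else \
            generate_true_network(2, 0.0, 0, 0, seed=5)
        x = sample_ordinal(2000, net, seed=6)
        a, b = x.iloc[:, 0].to_numpy(), x.iloc[:, 1].to_numpy()
        est = polychoric_corr(a, b)

        cx, ti = _marginal_thresholds(a)
        cy, tj = _marginal_thresholds(b)
        counts = np.zeros((len(cx), len(cy)))
        np.add.at(counts, (np.searchsorted(cx, a), np.searchsorted(cy, b)), 1.0)
        grid = np.arange(-0.99, 0.995, 0.01)
        nll = [-np.sum(counts * np.log(np.maximum(_cell_probabilities(ti, tj, g), 1e-300)))
               for g in grid]
        assert abs(est - grid[int(np.argmin(nll))]) <= 0.01

    def test_many_categories_approach_pearson(self):
        """With 50 categories the polychoric matches Pearson's r closely."""
        rng = substream(7, "poly")
        z = rng.multivariate_normal([0, 0], [[1, 0.5], [0.5, 1]], size=4000)
        t = stats.norm.ppf(np.arange(1, 50) / 50)
        x, y = np.searchsorted(t, z[:, 0]), np.searchsorted(t, z[:, 1])
        assert abs(polychoric_corr(x, y) - np.corrcoef(x, y)[0, 1]) < 0.02

    def test_constant_column_raises_with_name(self):
        df = pd.DataFrame({"A": [1, 1, 1, 1], "B": [0, 1, 2, 3]})
        with pytest.raises(ValueError, match="A"):
            polychoric_matrix(df)

    def test_matrix_positive_definite_unit_diagonal(self, true_network):
        x = sample_ordinal(300, true_network, seed=8)
        S = polychoric_matrix(x)
        assert np.linalg.eigvalsh(S.S).min() >= 1e-8
        assert np.allclose(np.diag(S.S), 1.0)


class TestGraphicalLasso:
    @staticmethod
    def random_corr(rng, p=5, n=100):
        A = rng.normal(size=(n, p))
        return np.corrcoef(A.T)

    def test_zero_penalty_inverts(self):
        S = self.random_corr(substream(9, "gl"))
        assert np.abs(graphical_lasso(S, 0.0) - np.linalg.inv(S)).max() < 1e-8

    def test_saturation_gives_diagonal_precision(self):
        S = self.random_corr(substream(10, "gl"))
        lam = np.abs(S - np.diag(np.diag(S))).max()
        theta = graphical_lasso(S, lam * 1.0001)
        assert np.abs(theta - np.diag(np.diag(theta))).max() == 0.0
        assert np.abs(precision_to_partial(theta)).max() == 0.0

    def test_matches_independent_solver(self):
        """Coordinate descent agrees elementwise with an independent
        convex solver of the same objective."""
        from sklearn.covariance import graphical_lasso as oracle

        rng = substream(11, "gl")
        S = self.random_corr(rng)
        import warnings
        for lam in (0.02, 0.1, 0.3):
            theta = graphical_lasso(S, lam)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, ref = oracle(S, alpha=lam, tol=1e-12, enet_tol=1e-12, max_iter=20000)
            assert np.abs(theta - ref).max() < 1e-4

    def test_partial_correlation_involution(self):
        S = self.random_corr(substream(12, "gl"))
        theta = graphical_lasso(S, 0.05)
        w = precision_to_partial(theta)
        d = np.sqrt(np.diag(theta))
        back = -w * np.outer(d, d)
        np.fill_diagonal(back, np.diag(theta))
        assert np.abs(back - theta).max() < 1e-10

    def test_negative_penalty_rejected(self):
        with pytest.raises(ValueError):
            graphical_lasso(np.eye(3), -0.1)


class TestEBICSelect:
    @staticmethod
    def corr_from_data(seed, n=400, p=6, density=0.5):
        net = generate_true_network(p, density, 0.1, 0.4, seed=seed)
        x = sample_ordinal(n, net, seed=seed + 1)
        return polychoric_matrix(x)

    def test_gamma_zero_equals_plain_bic(self):
        S = self.corr_from_data(20)
        cfg = EBICConfig(gamma=0.0, n_lambda=30)
        net = ebic_select(S, cfg)
        path = net.path
        # recompute BIC = -n*ll + E*log n for every path entry
        bic = path["ebic"]  # gamma=0 reduces EBIC to BIC
        assert net.selected_lambda == path.loc[bic.idxmin(), "lambda"] or \
            bic.min() == pytest.approx(bic[path["lambda"] == net.selected_lambda].iloc[0])

    def test_selected_ebic_is_path_minimum(self):
        S = self.corr_from_data(21)
        net = ebic_select(S, EBICConfig(n_lambda=40))
        sel = ebic(S.S, net.precision, S.n, 0.5)
        assert sel == pytest.approx(net.path["ebic"].min(), rel=1e-10)

    def test_identity_data_selects_empty_network(self):
        net0 = generate_true_network(6, 0.0, 0, 0, seed=22)
        x = sample_ordinal(1000, net0, seed=23)
        S = polychoric_matrix(x)
        sel = ebic_select(S, EBICConfig())
        assert len(sel.edge_set()) == 0

    def test_edge_support_monotone_nested_along_path(self):
        """Larger penalties select subsets of the smaller-penalty support."""
        S = self.corr_from_data(24)
        lam_max = np.abs(S.S - np.eye(len(S.S))).max()
        prev = None
        for lam in np.exp(np.linspace(np.log(lam_max), np.log(lam_max * 0.05), 12)):
            theta = graphical_lasso(S.S, lam)
            support = {(i, j) for i in range(len(theta)) for j in range(i + 1, len(theta))
                       if theta[i, j] != 0}
            if prev is not None:
                assert prev <= support
            prev = support

    def test_degenerate_path_warns_and_returns_empty(self):
        S = CorrelationMatrix(np.eye(4), "pearson", 100)
        with pytest.warns(UserWarning, match="empty network"):
            net = ebic_select(S, EBICConfig())
        assert len(net.edge_set()) == 0


class TestStackingContract:
    def test_identical_imputations_match_single_dataset(self, cohort):
        from griefnet.imputation import ImputationConfig, ImputationStack

        single = ImputationStack([cohort.items], ImputationConfig(m=1))
        triple = ImputationStack([cohort.items] * 3, ImputationConfig(m=3))
        n1 = estimate_network_stacked(single, EBICConfig(n_lambda=25))
        n3 = estimate_network_stacked(triple, EBICConfig(n_lambda=25))
        assert np.array_equal(n1.weights, n3.weights)
        assert n1.selected_lambda == n3.selected_lambda

    def test_effective_n_is_participant_count(self, cohort):
        from griefnet.imputation import ImputationConfig, ImputationStack

        for m in (1, 4):
            stack = ImputationStack([cohort.items] * m, ImputationConfig(m=m))
            net = estimate_network_stacked(stack, EBICConfig(n_lambda=10))
            assert net.n == cohort.items.n

    def test_inconsistent_shapes_rejected(self, cohort):
        from griefnet.imputation import ImputationConfig, ImputationStack

        short = type(cohort.items)(cohort.items.values.iloc[:10])
        stack = ImputationStack([cohort.items, short], ImputationConfig(m=2))
        with pytest.raises(ValueError, match="shape"):
            estimate_network_stacked(stack)


class TestDescriptives:
    @staticmethod
    def net_from_weights(w):
        p = len(w)
        return SymptomNetwork(tuple(f"V{i}" for i in range(p)), np.asarray(w, float),
                              np.eye(p), 0.1, 100)

    def test_density_half_with_39_edges(self):
        w = np.zeros((13, 13))
        iu = list(zip(*np.triu_indices(13, 1)))
        for (i, j) in iu[:39]:
            w[i, j] = w[j, i] = 0.1
        d = network_descriptives(self.net_from_weights(w))
        assert d.density == pytest.approx(0.5)
        assert d.n_edges == 39

    def test_empty_network(self):
        d = network_descriptives(self.net_from_weights(np.zeros((5, 5))))
        assert d.density == 0 and d.mean_weight_all == 0 and d.max_weight == 0

    def test_constructed_three_node_arithmetic(self):
        w = np.zeros((3, 3))
        w[0, 1] = w[1, 0] = 0.3
        w[1, 2] = w[2, 1] = -0.1
        d = network_descriptives(self.net_from_weights(w))
        assert d.density == pytest.approx(2 / 3)
        assert d.mean_weight_all == pytest.approx((0.3 - 0.1) / 3)
        assert d.mean_weight_nonzero == pytest.approx(0.1)
        assert (d.min_weight, d.max_weight) == (-0.1, 0.3)
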