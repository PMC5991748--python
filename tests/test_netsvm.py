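"""Network-SVM: Laplacian identities, QP-oracle equivalence, ranking and
cross-validated evaluation."""

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from sklearn.svm import SVC

from mirmod import (ExpressionMatrix, NetworkSVM, build_laplacian,
                    rank_nodes, extract_subnetwork, evaluate_classifier)
import networkx as nx


def _expr(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])]))


def _toy():
    v = np.array([[1.0, 2.0, -1.0, -2.0],
                  [0.5, 1.5, -0.5, -1.2]])
    return _expr(v), np.array([1, 1, -1, -1])


def primal_qp_oracle(z, y, lam):
    """Soft-margin SVM QP (mean hinge + lam*||w||^2, free bias) solved with
    SLSQP on the slack formulation — independent of the package solver."""
    d, n = z.shape

    def obj(p):
        return p[d + 1:].mean() + lam * (p[:d] @ p[:d])

    cons = [{"type": "ineq",
             "fun": (lambda p, i=i:
                     y[i] * (p[:d] @ z[:, i] + p[d]) - 1 + p[d + 1 + i])}
            for i in range(n)]
    cons += [{"type": "ineq", "fun": lambda p, i=i: p[d + 1 + i]}
             for i in range(n)]
    r = minimize(obj, np.zeros(d + 1 + n), constraints=cons,
                 method="SLSQP", options={"maxiter": 1000, "ftol": 1e-14})
    assert r.success
    return r.x[:d], r.x[d]


class TestLaplacian:
    def test_empty_edge_set_is_identity(self):
        lap = build_laplacian([], nodes=["a", "b", "c"])
        assert np.allclose(lap.to_numpy(), np.eye(3))

    def test_single_edge_block(self):
        lap = build_laplacian([("a", "b", 1.0)], nodes=["a", "b", "c"])
        expected = np.array([[1.0, -1.0, 0.0],
                             [-1.0, 1.0, 0.0],
                             [0.0, 0.0, 1.0]])
        assert np.allclose(lap.to_numpy(), expected)

    def test_quadratic_form_identity(self):
        rng = np.random.default_rng(0)
        g = nx.gnm_random_graph(8, 14, seed=1)
        for u, v in g.edges:
            g.edges[u, v]["weight"] = float(rng.uniform(0.1, 2.0))
        nodes = sorted(g.nodes)
        lap = build_laplacian(g, nodes=nodes).to_numpy()
        x = rng.standard_normal(8)
        deg = {u: sum(g.edges[u, v]["weight"] for v in g[u]) for u in nodes}
        direct = sum(
            g.edges[u, v]["weight"]
            * (x[u] / np.sqrt(deg[u]) - x[v] / np.sqrt(deg[v])) ** 2
            for u, v in g.edges)
        assert x @ lap @ x == pytest.approx(direct, abs=1e-10)

    def test_negative_weight_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            build_laplacian([("a", "b", -0.5)])


class TestFit:
    def test_matches_qp_oracle_without_network_penalty(self):
        X, y = _toy()
        lam = 0.05
        res = NetworkSVM(X, y, lambda_margin=lam, lambda_net=0.0).fit()
        v = X.values
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1,
                                                        keepdims=True)
        w_star, b_star = primal_qp_oracle(z, y, lam)
        assert np.abs(res.weights.to_numpy() - w_star).max() < 1e-4
        assert abs(res.bias - b_star) < 1e-4

    def test_matches_sklearn_svc_with_c_mapping(self):
        # independent QP route: libsvm SMO with C = 1/(2*lam*n)
        rng = np.random.default_rng(8)
        n, d = 12, 3
        v = rng.standard_normal((d, n))
        y = np.where(v[0] + 0.3 * rng.standard_normal(n) > 0, 1, -1)
        if len(set(y)) < 2:
            y[0] = -y[0]
        lam = 0.1
        res = NetworkSVM(_expr(v), y, lambda_margin=lam,
                         lambda_net=0.0).fit()
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1,
                                                        keepdims=True)
        svc = SVC(kernel="linear", C=1 / (2 * lam * n)).fit(z.T, y)
        assert np.abs(res.weights.to_numpy() - svc.coef_[0]).max() < 1e-3
        assert abs(res.bias - svc.intercept_[0]) < 1e-3

    def test_network_penalty_ties_connected_identical_features(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(20)
        noise = rng.standard_normal((2, 20))
        v = np.vstack([base, base, noise])
        y = np.where(base > 0, 1, -1)
        lap = build_laplacian([("f0", "f1", 1.0)],
                              nodes=["f0", "f1", "f2", "f3"])
        res = NetworkSVM(_expr(v), y, laplacian=lap, lambda_margin=0.01,
                         lambda_net=100.0).fit()
        assert abs(res.weights["f0"] - res.weights["f1"]) < 1e-3

    def test_separable_toy_training_performance(self):
        X, y = _toy()
        res = NetworkSVM(X, y, lambda_margin=0.01, lambda_net=0.0).fit()
        f = res.decision_function(X).to_numpy()
        assert ((f > 0) == (y == 1)).all()

    def test_objective_trace_is_non_increasing(self):
        X, y = _toy()
        res = NetworkSVM(X, y, lambda_margin=0.01, lambda_net=0.0).fit()
        diffs = np.diff(res.objective_trace)
        assert (diffs <= 1e-12).all()
        assert res.converged

    def test_single_class_rejected(self):
        X, _ = _toy()
        with pytest.raises(ValueError, match="classes"):
            NetworkSVM(X, np.ones(4))

    def test_positive_weight_means_disease_association(self):
        rng = np.random.default_rng(5)
        n = 40
        y = np.r_[np.ones(20), -np.ones(20)]
        signal = y + 0.3 * rng.standard_normal(n)
        v = np.vstack([signal, rng.standard_normal(n)])
        res = NetworkSVM(_expr(v), y, lambda_margin=0.05,
                         lambda_net=0.0).fit()
        assert res.weights["f0"] > 0
        assert abs(res.weights["f1"]) < abs(res.weights["f0"])


class TestRanking:
    def test_simple_ordering(self):
        w = pd.Series({"a": 0.2, "b": -0.22, "c": 0.1})
        up, down, merged = rank_nodes(w, 1, 1)
        assert up == ["a"] and down == ["b"]
        assert merged == ["b", "a"]

    def test_published_weight_table_ordering(self):
        # the printed hub-weight table as input: largest positive and
        # largest negative weights lead their respective lists
        w = pd.Series({
            "hsa-miR-424": 0.2001, "hsa-miR-503": 0.1984,
            "hsa-miR-224": 0.1888, "hsa-miR-486": 0.1570,
            "hsa-miR-451": 0.1296,
            "hsa-miR-146a": -0.2201, "hsa-miR-376a": -0.2149,
            "hsa-miR-647": -0.1615, "hsa-miR-375": -0.1514,
        })
        up, down, merged = rank_nodes(w, 3, 3)
        assert up[0] == "hsa-miR-424"
        assert down[0] == "hsa-miR-146a"
        assert merged[:3] == ["hsa-miR-146a", "hsa-miR-376a", "hsa-miR-424"]

    def test_merged_top_k_by_absolute_weight(self):
        w = pd.Series({"a": 0.3, "b": -0.29, "c": 0.1})
        _, _, merged = rank_nodes(w, 1, 1)
        assert merged == ["a", "b"]


class TestSubnetwork:
    def test_disconnected_top_nodes(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b", "c"])
        w = pd.Series({"a": 1.0, "b": -1.0, "c": 0.5})
        sub = extract_subnetwork(g, ["a", "b"], w)
        assert sub.graph.number_of_edges() == 0

    def test_complete_graph_induces_all_edges(self):
        g = nx.complete_graph(["a", "b", "c", "d"])
        w = pd.Series(1.0, index=list("abcd"))
        sub = extract_subnetwork(g, ["a", "b", "c"], w)
        assert sub.graph.number_of_edges() == 3

    def test_matches_brute_force_edge_filter(self):
        g = nx.gnp_random_graph(12, 0.3, seed=3)
        g = nx.relabel_nodes(g, {i: f"f{i}" for i in range(12)})
        w = pd.Series(np.linspace(-1, 1, 12),
                      index=[f"f{i}" for i in range(12)])
        top = [f"f{i}" for i in (0, 3, 5, 7, 11)]
        sub = extract_subnetwork(g, top, w)
        expected = {(u, v) for u, v in g.edges
                    if u in top and v in top}
        got = {tuple(sorted(e)) for e in sub.graph.edges}
        assert got == {tuple(sorted(e)) for e in expected}

    def test_direction_conflict_flagged(self):
        g = nx.Graph()
        g.add_nodes_from(["a", "b"])
        w = pd.Series({"a": 1.0, "b": -1.0})
        fc = pd.Series({"a": -0.5, "b": -0.2})
        sub = extract_subnetwork(g, ["a", "b"], w, log2fc=fc)
        assert bool(sub.nodes.loc["a", "direction_conflict"])
        assert not bool(sub.nodes.loc["b", "direction_conflict"])


class TestEvaluate:
    def _separable(self, seed=0, n_per=20, d=6):
        rng = np.random.default_rng(seed)
        y = np.r_[np.ones(n_per), -np.ones(n_per)]
        v = rng.standard_normal((d, 2 * n_per))
        v[0] += 2.5 * y
        v[1] -= 2.5 * y
        return _expr(v), y

    def test_separable_data_high_cv_performance(self):
        X, y = self._separable()
        out = evaluate_classifier(X, y, lambda_grid=[(0.01, 0.0)],
                                  folds=5, seed=1)
        assert out["best"]["cv_sensitivity"] >= 0.95
        assert out["best"]["cv_specificity"] >= 0.95

    def test_shuffled_labels_give_chance_auc(self):
        X, y = self._separable(seed=2)
        rng = np.random.default_rng(3)
        y_shuf = rng.permutation(y)
        out = evaluate_classifier(X, y_shuf, lambda_grid=[(0.1, 0.0)],
                                  folds=5, seed=4)
        assert abs(out["best"]["cv_auc"] - 0.5) <= 0.15

    def test_apparent_metrics_exceed_cv_on_average(self):
        # optimism direction, averaged over 20 seeds on noisy data
        rng = np.random.default_rng(6)
        diffs = []
        for seed in range(20):
            y = np.r_[np.ones(12), -np.ones(12)]
            v = rng.standard_normal((5, 24))
            v[0] += 0.6 * y
            out = evaluate_classifier(_expr(v), y,
                                      lambda_grid=[(0.05, 0.0)],
                                      folds=3, seed=seed)
            diffs.append(out["apparent"]["apparent_auc"]
                         - out["best"]["cv_auc"])
        assert np.mean(diffs) >= 0
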