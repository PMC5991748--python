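"""Network construction: correlation, soft threshold, TOM, tree cut,
eigengenes — each checked against an independent oracle."""

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import adjusted_rand_score

from mirmod import (correlation_matrix, scale_free_fit, pick_power,
                    tom_matrix, cluster_and_cut, module_eigengene,
                    kme_and_kim, CoexpressionNetwork, ExpressionMatrix,
                    ModulePartition)


def _expr(values, prefix="f"):
    values = np.asarray(values, dtype=float)
    return ExpressionMatrix(pd.DataFrame(
        values, index=[f"{prefix}{i}" for i in range(values.shape[0])],
        columns=[f"s{j}" for j in range(values.shape[1])]))


class TestCorrelation:
    def test_duplicate_and_negated_features(self):
        rng = np.random.default_rng(0)
        base = rng.standard_normal(10)
        X = _expr(np.vstack([base, base, -base]))
        c = correlation_matrix(X)
        assert c.loc["f0", "f1"] == pytest.approx(1.0)
        assert c.loc["f0", "f2"] == pytest.approx(-1.0)

    def test_matches_textbook_formula(self):
        rng = np.random.default_rng(1)
        v = rng.standard_normal((5, 10))
        c = correlation_matrix(_expr(v)).to_numpy()
        # direct covariance / sd computation
        vc = v - v.mean(axis=1, keepdims=True)
        cov = vc @ vc.T / 10
        sd = np.sqrt(np.diag(cov))
        expected = cov / np.outer(sd, sd)
        assert np.abs(c - expected).max() < 1e-12

    def test_zero_variance_feature_named_in_error(self):
        v = np.vstack([np.ones(6), np.arange(6.0), np.arange(6.0) ** 2])
        with pytest.raises(ValueError, match="f0"):
            correlation_matrix(_expr(v))


class TestScaleFreeFit:
    def test_exactly_linear_binned_frequencies(self):
        # counts proportional to 1/k at k = 1,2,4,8 with 7 equal-width
        # bins -> log10(freq) is exactly linear in log10(k)
        k = np.concatenate([np.full(240, 1.0), np.full(120, 2.0),
                            np.full(60, 4.0), np.full(30, 8.0)])
        fit = scale_free_fit(k, n_bins=7)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-12)
        assert fit.slope == pytest.approx(-1.0, abs=1e-12)

    def test_constant_connectivity_is_degenerate(self):
        with pytest.warns(UserWarning):
            fit = scale_free_fit(np.full(50, 3.0))
        assert fit.r_squared == 0.0 and fit.degenerate

    def test_power_law_sample_fits_well(self):
        rng = np.random.default_rng(7)
        k = rng.pareto(2.0, size=500) + 1.0
        fit = scale_free_fit(k)
        assert fit.r_squared >= 0.8
        assert fit.slope < 0


class TestPickPower:
    def test_selected_beta_reproduces_brute_force_scan(self, small_cohorts):
        X = small_cohorts["ref"]
        grid = list(range(1, 13))
        scan = pick_power(X, grid, fit_cut=0.8)
        # independent brute-force re-scan outside the selector
        corr = np.corrcoef(X.values)
        r2 = []
        for beta in grid:
            a = np.abs(corr) ** beta
            np.fill_diagonal(a, 0.0)
            r2.append(scale_free_fit(a.sum(axis=1)).r_squared)
        r2 = np.array(r2)
        if (r2 >= 0.8).any():
            expected = grid[int(np.argmax(r2 >= 0.8))]
            assert scan.reached_cut
        else:
            expected = grid[int(np.argmax(r2))]
            assert not scan.reached_cut
        assert scan.beta == expected
        assert np.allclose(scan.table["r_squared"].to_numpy(), r2)

    def test_no_power_reaches_cut_returns_argmax_with_flag(self, toy_expr):
        scan = pick_power(toy_expr, [1, 2], fit_cut=0.999999)
        assert not scan.reached_cut
        best = scan.table.loc[scan.table["r_squared"].idxmax(), "power"]
        assert scan.beta == best


class TestTom:
    def test_isolated_pair_closed_form(self):
        a = np.zeros((4, 4))
        a[0, 1] = a[1, 0] = 0.37
        t = tom_matrix(a)
        assert t.iloc[0, 1] == pytest.approx(0.37)

    def test_complete_unit_graph(self):
        n = 6
        a = np.ones((n, n)) - np.eye(n)
        t = tom_matrix(a).to_numpy()
        assert np.allclose(t, 1.0)

    def test_against_triple_loop_oracle(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            n = rng.integers(4, 11)
            a = rng.uniform(0, 1, (n, n))
            a = (a + a.T) / 2
            np.fill_diagonal(a, 0.0)
            t = tom_matrix(a).to_numpy()
            k = a.sum(axis=1)
            for i in range(n):
                for j in range(n):
                    if i == j:
                        assert t[i, j] == 1.0
                        continue
                    num = sum(a[i, u] * a[u, j] for u in range(n)) + a[i, j]
                    den = min(k[i], k[j]) + 1 - a[i, j]
                    assert abs(t[i, j] - num / den) < 1e-12

    def test_symmetry_required(self):
        a = np.zeros((3, 3))
        a[0, 1] = 0.5
        with pytest.raises(ValueError, match="symmetric"):
            tom_matrix(a)


def _block_tom(sizes, within=0.8, between=0.02):
    n = sum(sizes)
    t = np.full((n, n), between)
    pos = 0
    for s in sizes:
        t[pos:pos + s, pos:pos + s] = within
        pos += s
    np.fill_diagonal(t, 1.0)
    ids = [f"f{i}" for i in range(n)]
    return pd.DataFrame(t, index=ids, columns=ids)


class TestClusterAndCut:
    def test_two_planted_blocks_recovered_exactly(self):
        tom = _block_tom([10, 5])
        part = cluster_and_cut(tom, min_module_size=3)
        assert part.module_sizes() == {1: 10, 2: 5}
        assert len(set(part.labels[:10])) == 1
        assert len(set(part.labels[10:])) == 1

    def test_block_below_min_size_unassigned(self):
        tom = _block_tom([10, 2])
        part = cluster_and_cut(tom, min_module_size=3)
        assert list(part.labels[10:]) == [0, 0]

    def test_flat_dendrogram_degenerates_to_one_module(self):
        n = 8
        t = np.full((n, n), 0.5)
        np.fill_diagonal(t, 1.0)
        tom = pd.DataFrame(t, index=[f"f{i}" for i in range(n)],
                           columns=[f"f{i}" for i in range(n)])
        with pytest.warns(UserWarning, match="flat"):
            part = cluster_and_cut(tom)
        assert set(part.labels) == {1}

    def test_detection_is_deterministic(self, study):
        p1 = study["net"].detect_modules()
        p2 = study["net"].detect_modules()
        pd.testing.assert_series_equal(p1.labels, p2.labels)

    def test_planted_module_recovery(self, study):
        truth = study["truth"].labels
        detected = study["partition"].labels.reindex(truth.index)
        mask = truth.to_numpy() != 0
        ari = adjusted_rand_score(truth.to_numpy()[mask],
                                  detected.to_numpy()[mask])
        assert ari >= 0.9


class TestEigengene:
    def test_identical_members_give_unit_prop_var(self):
        base = np.arange(10.0)
        X = _expr(np.vstack([base, base, base]))
        part = ModulePartition(pd.Series([1, 1, 1],
                                         index=["f0", "f1", "f2"]))
        _, pve = module_eigengene(X, part)
        assert pve[1] == pytest.approx(1.0)

    def test_sign_flip_reorients_eigengene(self):
        rng = np.random.default_rng(5)
        v = rng.standard_normal((4, 12))
        part = ModulePartition(pd.Series(1, index=[f"f{i}" for i in range(4)]))
        eig1, pve1 = module_eigengene(_expr(v), part)
        eig2, pve2 = module_eigengene(_expr(-v), part)
        assert pve1[1] == pytest.approx(pve2[1])
        assert np.allclose(eig1["ME1"], -eig2["ME1"]) or \
            np.allclose(eig1["ME1"], eig2["ME1"])

    def test_prop_var_matches_svd_oracle(self):
        rng = np.random.default_rng(8)
        v = rng.standard_normal((5, 20)) + rng.standard_normal((1, 20))
        part = ModulePartition(pd.Series(1, index=[f"f{i}" for i in range(5)]))
        _, pve = module_eigengene(_expr(v), part)
        # independent SVD-based route: mean squared correlation with PC1
        z = (v - v.mean(axis=1, keepdims=True)) / v.std(axis=1, ddof=1,
                                                        keepdims=True)
        u, s, vt = np.linalg.svd(z)
        pc1 = vt[0]
        cors = [np.corrcoef(z[i], pc1)[0, 1] for i in range(5)]
        assert pve[1] == pytest.approx(np.mean(np.square(cors)), abs=1e-10)


class TestKmeKim:
    def test_identical_members_have_unit_kme(self):
        base = np.arange(8.0)
        X = _expr(np.vstack([base, base, np.random.default_rng(0)
                             .standard_normal(8)]))
        part = ModulePartition(pd.Series([1, 1, 0],
                                         index=["f0", "f1", "f2"]))
        net = CoexpressionNetwork.from_expression(X, beta=2)
        kme, kim = kme_and_kim(X, net.network.adjacency, part)
        assert kme.loc["f0", "ME1"] == pytest.approx(1.0)
        assert kme.loc["f1", "ME1"] == pytest.approx(1.0)
        assert kim["f2"] == 0.0

    def test_kim_equals_manual_row_sum(self, toy_expr):
        part = ModulePartition(pd.Series([1, 1, 1, 2, 2],
                                         index=toy_expr.feature_ids))
        net = CoexpressionNetwork.from_expression(toy_expr, beta=3)
        adj = net.network.adjacency
        kme, kim = kme_and_kim(toy_expr, adj, part)
        a = adj.to_numpy().copy()
        np.fill_diagonal(a, 0.0)
        assert kim["f1"] == pytest.approx(a[1, 0] + a[1, 2])
        assert kim["f3"] == pytest.approx(a[3, 4])
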