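"""Network-constrained linear SVM for hub-miRNA ranking.

The classifier separates disease from normal samples with a linear decision
function f(x) = w'x + b while encouraging the weight vector to vary
smoothly over the co-expression network.  The objective is

    (1/n) * sum_i hinge(y_i f(x_i)) + lambda_margin ||w||^2
                                    + lambda_net  w' L w

with L the symmetric normalized graph Laplacian of the (thresholded TOM)
network, so w'Lw penalizes weight differences between connected miRNAs.
With lambda_net = 0 this is exactly the standard soft-margin SVM.

The solver is deterministic: the problem is a quadratic program whose dual
is a box-plus-hyperplane constrained concave quadratic, maximized by
projected gradient ascent with a fixed 1/Lipschitz step, so the recorded
(minimization) objective trace is non-increasing by construction.

Features with large |w| are the hub candidates; the induced subgraph of
the top-ranked features is the biomarker sub-network.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import networkx as nx
from sklearn.model_selection import StratifiedKFold

from .containers import ExpressionMatrix
from .diagnostics import roc_and_auc

__all__ = ["build_laplacian", "NetworkSVM", "NetSVMResults", "rank_nodes",
           "extract_subnetwork", "SubNetwork", "evaluate_classifier"]


def build_laplacian(graph: nx.Graph | Iterable[tuple],
                    nodes: Sequence[str] | None = None) -> pd.DataFrame:
    """Symmetric normalized Laplacian L = I - D^{-1/2} A D^{-1/2}.

    ``graph`` is a networkx graph or an iterable of ``(u, v[, weight])``
    edges; ``nodes`` fixes the row/column order (defaults to sorted node
    set).  Isolated nodes get identity rows.  Negative edge weights are
    rejected.
    """
    if not isinstance(graph, nx.Graph):
        g = nx.Graph()
        for e in graph:
            if len(e) == 2:
                g.add_edge(e[0], e[1], weight=1.0)
            else:
                g.add_edge(e[0], e[1], weight=float(e[2]))
        graph = g
    for u, v, d in graph.edges(data=True):
        if d.get("weight", 1.0) < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
    if nodes is None:
        nodes = sorted(graph.nodes)
    else:
        nodes = list(nodes)
        graph = graph.copy()
        graph.add_nodes_from(n for n in nodes if n not in graph)
    a = nx.to_numpy_array(graph, nodelist=nodes, weight="weight")
    deg = a.sum(axis=1)
    inv_sqrt = np.zeros_like(deg)
    nz = deg > 0
    inv_sqrt[nz] = 1.0 / np.sqrt(deg[nz])
    lap = np.eye(len(nodes)) - (inv_sqrt[:, None] * a * inv_sqrt[None, :])
    lap[~nz, :] = 0.0
    lap[:, ~nz] = 0.0
    lap[~nz, ~nz] = 1.0
    return pd.DataFrame(lap, index=nodes, columns=nodes)


def _project_box_hyperplane(v: np.ndarray, y: np.ndarray,
                            upper: float) -> np.ndarray:
    """Euclidean projection onto {0 <= a <= upper, y'a = 0}, y in {-1,+1}.

    The hyperplane multiplier nu solves y'clip(v - nu*y, 0, upper) = 0, a
    strictly decreasing piecewise-linear function whose kinks lie at
    u_i and u_i - upper*y_i (u = y*v); the exact root is found by
    evaluating at every kink and interpolating the bracketing segment.
    """
    u = y * v
    bps = np.unique(np.concatenate([u, u - upper * y]))
    pos, neg = u[y > 0], u[y < 0]
    g = (np.clip(pos[None, :] - bps[:, None], 0.0, upper).sum(axis=1)
         - np.clip(bps[:, None] - neg[None, :], 0.0, upper).sum(axis=1))
    idx = int(np.searchsorted(-g, 0.0))   # g is non-increasing in bps
    if idx == 0:
        nu = bps[0]
    elif idx >= bps.size:
        nu = bps[-1]
    else:
        b1, b2, g1, g2 = bps[idx - 1], bps[idx], g[idx - 1], g[idx]
        nu = b1 if g1 == g2 else b1 + (b2 - b1) * g1 / (g1 - g2)
    return np.clip(v - nu * y, 0.0, upper)


class NetworkSVM:
    """Network-constrained soft-margin SVM model.

    Parameters
    ----------
    X : features x samples expression matrix (features are standardized to
        mean 0 / sd 1 internally before fitting).
    y : array of sample labels in {-1, +1}; +1 is the disease class.
    laplacian : normalized Laplacian over (a superset of) the features, or
        None for lambda_net = 0 behaviour.
    lambda_margin : ridge penalty on ||w||^2 (must be > 0).
    lambda_net : network-smoothness penalty on w'Lw.
    """

    def __init__(self, X: ExpressionMatrix, y: Sequence[int],
                 laplacian: pd.DataFrame | None = None,
                 lambda_margin: float = 0.01, lambda_net: float = 0.01):
        X.validate(min_features=1, min_samples=2)
        y = np.asarray(y, dtype=float)
        if y.shape[0] != X.n_samples:
            raise ValueError("y length must match the sample count")
        if set(np.unique(y)) != {-1.0, 1.0}:
            raise ValueError("y must contain both classes, coded -1/+1")
        if lambda_margin <= 0:
            raise ValueError("lambda_margin must be positive")
        if lambda_net < 0:
            raise ValueError("lambda_net must be nonnegative")
        self.X = X
        self.y = y
        self.lambda_margin = float(lambda_margin)
        self.lambda_net = float(lambda_net)
        if laplacian is not None:
            missing = [f for f in X.feature_ids if f not in laplacian.index]
            if missing:
                raise ValueError(f"features absent from Laplacian: "
                                 f"{missing[:5]}")
            laplacian = laplacian.loc[X.feature_ids, X.feature_ids]
        self.laplacian = laplacian

    def fit(self, max_iter: int = 20000, tol: float = 1e-6,
            seed: int | None = None) -> "NetSVMResults":
        """Solve the QP to a relative duality gap below ``tol``; ``seed``
        is recorded for provenance (the solver itself is deterministic)."""
        v = self.X.values
        mu, sd = v.mean(axis=1), v.std(axis=1, ddof=0)
        if (sd == 0).any():
            raise ValueError("zero-variance features cannot be standardized")
        z = (v - mu[:, None]) / sd[:, None]          # d x n
        d, n = z.shape
        y = self.y
        m = self.lambda_margin * np.eye(d)
        if self.laplacian is not None and self.lambda_net > 0:
            m = m + self.lambda_net * self.laplacian.to_numpy()
        # primal: C*sum hinge + (1/2) w' (2M) w  with C = 1/n
        c_cost = 1.0 / n
        m_inv_z = np.linalg.solve(2.0 * m, z)        # (2M)^-1 X
        kernel = z.T @ m_inv_z                       # n x n
        q = (y[:, None] * kernel * y[None, :])
        q = (q + q.T) / 2.0
        lip = max(np.linalg.eigvalsh(q).max(), 1e-12)

        def primal_dual(alpha):
            w = m_inv_z @ (alpha * y)
            f0 = w @ z
            bias = self._bias_from_kkt(alpha, y, f0, c_cost)
            margins = y * (f0 + bias)
            primal = (c_cost * np.maximum(0.0, 1.0 - margins).sum()
                      + w @ (m @ w))
            dual = alpha.sum() - 0.5 * alpha @ q @ alpha
            gap = abs(primal - dual) / (1.0 + abs(primal))
            return w, bias, primal, dual, gap

        alpha = np.zeros(n)
        trace = []
        obj_prev = np.inf
        gap = np.inf
        for it in range(max_iter):
            grad = q @ alpha - 1.0                   # gradient of (1/2)a'Qa - 1'a
            alpha = _project_box_hyperplane(alpha - grad / lip, y, c_cost)
            obj = 0.5 * alpha @ q @ alpha - alpha.sum()
            trace.append(obj)
            if (it + 1) % 25 == 0:
                gap = primal_dual(alpha)[4]
                if gap < tol:
                    break
            if obj_prev - obj < 1e-15 * (1.0 + abs(obj)):
                break                               # fixed point reached
            obj_prev = obj
        iterations = len(trace)

        w, bias, primal, dual, gap = primal_dual(alpha)
        return NetSVMResults(
            model=self, weights=pd.Series(w, index=self.X.feature_ids,
                                          name="weight"),
            bias=float(bias), alpha=alpha,
            feature_means=pd.Series(mu, index=self.X.feature_ids),
            feature_sds=pd.Series(sd, index=self.X.feature_ids),
            objective=float(primal), duality_gap=float(gap),
            objective_trace=np.asarray(trace), iterations=iterations,
            converged=bool(gap < 1e-3),
            seed=seed)

    @staticmethod
    def _bias_from_kkt(alpha: np.ndarray, y: np.ndarray, f0: np.ndarray,
                       upper: float) -> float:
        eps = 1e-8 * upper
        free = (alpha > eps) & (alpha < upper - eps)
        if free.any():
            return float(np.mean(y[free] - f0[free]))
        lower, higher = [], []
        for ai, yi, fi in zip(alpha, y, f0):
            bound = yi - fi
            at_zero = ai <= eps
            if (at_zero and yi > 0) or (not at_zero and yi < 0):
                lower.append(bound)
            else:
                higher.append(bound)
        lo = max(lower) if lower else min(higher)
        hi = min(higher) if higher else max(lower)
        return float(0.5 * (lo + hi))


@dataclass
class NetSVMResults:
    """Fitted network-SVM: signed feature weights and diagnostics."""

    model: NetworkSVM
    weights: pd.Series
    bias: float
    alpha: np.ndarray
    feature_means: pd.Series
    feature_sds: pd.Series
    objective: float
    duality_gap: float
    objective_trace: np.ndarray
    iterations: int
    converged: bool
    seed: int | None = None

    def decision_function(self, X: ExpressionMatrix) -> pd.Series:
        """w'x + b on new samples (features standardized with the training
        means/sds)."""
        sub = X.data.loc[self.weights.index]
        z = (sub.to_numpy(dtype=float)
             - self.feature_means.to_numpy()[:, None]) \
            / self.feature_sds.to_numpy()[:, None]
        return pd.Series(self.weights.to_numpy() @ z + self.bias,
                         index=X.sample_ids, name="decision")

    def predict(self, X: ExpressionMatrix) -> pd.Series:
        return np.sign(self.decision_function(X)).replace(0, 1).astype(int)

    def rank_table(self, partition=None) -> pd.DataFrame:
        """Features sorted by |weight| with direction and optional module
        attribution."""
        tbl = pd.DataFrame({"weight": self.weights})
        tbl["direction"] = np.where(tbl["weight"] >= 0, "up", "down")
        tbl = tbl.sort_values("weight", key=lambda s: -s.abs(),
                              kind="mergesort")
        tbl["rank"] = np.arange(1, len(tbl) + 1)
        if partition is not None:
            tbl["module"] = [int(partition.labels.get(f, 0))
                             for f in tbl.index]
        return tbl

    def summary(self) -> str:
        w = self.weights
        top = self.rank_table().head(10)
        return "\n".join([
            "Network-constrained SVM",
            f"  features: {len(w)}   samples: {self.model.X.n_samples}",
            f"  lambda_margin: {self.model.lambda_margin:g}   "
            f"lambda_net: {self.model.lambda_net:g}",
            f"  iterations: {self.iterations}   "
            f"duality gap: {self.duality_gap:.2e}   "
            f"converged: {self.converged}",
            f"  objective: {self.objective:.6g}   bias: {self.bias:.4g}",
            "", "Top features by |weight|:", top.round(4).to_string(),
        ])


def rank_nodes(weights: pd.Series, k_up: int, k_down: int
               ) -> tuple[list[str], list[str], list[str]]:
    """Top up-regulated (most positive weight first), top down-regulated
    (most negative first) and the merged top-(k_up + k_down) by |weight|.
    Ties break by feature id, lexicographically."""
    if not np.isfinite(weights.to_numpy()).all():
        raise ValueError("weights must be finite")
    order_key = pd.DataFrame({"w": weights, "id": weights.index.astype(str)})
    up = order_key[order_key["w"] > 0].sort_values(
        ["w", "id"], ascending=[False, True])
    down = order_key[order_key["w"] < 0].sort_values(
        ["w", "id"], ascending=[True, True])
    merged = order_key.assign(a=weights.abs()).sort_values(
        ["a", "id"], ascending=[False, True])
    return (list(up.index[:k_up]), list(down.index[:k_down]),
            list(merged.index[:k_up + k_down]))


@dataclass
class SubNetwork:
    """Induced sub-network of the top-ranked features."""

    nodes: pd.DataFrame       # index: feature; weight, direction, log2fc
    graph: nx.Graph

    def write_sif(self, path) -> None:
        with open(path, "w") as fh:
            for u, v, dd in self.graph.edges(data=True):
                fh.write(f"{u}\ttom\t{v}\t{dd.get('weight', 1.0):.6g}\n")

    def write_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


def extract_subnetwork(network: nx.Graph, top_nodes: Sequence[str],
                       weights: pd.Series,
                       log2fc: pd.Series | None = None) -> SubNetwork:
    """Induced subgraph of the selected nodes, annotated with weight sign
    (direction) and, when given, the disease-vs-normal log2 fold change
    used for display; a sign disagreement between weight and fold change
    is flagged rather than resolved."""
    missing = [f for f in top_nodes if f not in network.nodes]
    if missing:
        raise ValueError(f"nodes absent from network: {missing[:5]}")
    g = network.subgraph(top_nodes).copy()
    tbl = pd.DataFrame({"weight": weights.loc[list(top_nodes)]})
    tbl["direction"] = np.where(tbl["weight"] >= 0, "up", "down")
    if log2fc is not None:
        tbl["log2fc"] = log2fc.reindex(tbl.index)
        tbl["direction_conflict"] = (
            np.sign(tbl["weight"]) * np.sign(tbl["log2fc"]) < 0)
    for f in tbl.index:
        g.nodes[f]["weight"] = float(tbl.loc[f, "weight"])
        g.nodes[f]["direction"] = str(tbl.loc[f, "direction"])
    return SubNetwork(nodes=tbl, graph=g)


def evaluate_classifier(
    X: ExpressionMatrix,
    y: Sequence[int],
    lambda_grid: Sequence[tuple[float, float]] = ((0.01, 0.0), (0.01, 0.01)),
    laplacian: pd.DataFrame | None = None,
    folds: int = 5,
    seed: int | None = 0,
) -> dict:
    """Stratified K-fold cross-validated performance over a lambda grid.

    For every (lambda_margin, lambda_net) pair the held-out decision values
    are pooled across folds and summarized as sensitivity, specificity
    (at the f = 0 operating point) and AUC.  Apparent (resubstitution)
    metrics for the best pair are reported separately and labelled as such.
    """
    y = np.asarray(y, dtype=float)
    if folds < 2:
        raise ValueError("folds must be >= 2")
    if min((y == 1).sum(), (y == -1).sum()) < folds:
        raise ValueError("each class needs at least `folds` samples")
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    cols = X.data.columns
    rows = []
    pooled = {}
    for lam_m, lam_n in lambda_grid:
        scores = np.empty_like(y)
        for train, test in skf.split(cols, y):
            xt = ExpressionMatrix(X.data.iloc[:, train])
            res = NetworkSVM(xt, y[train], laplacian=laplacian,
                             lambda_margin=lam_m, lambda_net=lam_n).fit(
                                 seed=seed)
            scores[test] = res.decision_function(
                ExpressionMatrix(X.data.iloc[:, test])).to_numpy()
        sens = float((scores[y == 1] > 0).mean())
        spec = float((scores[y == -1] <= 0).mean())
        auc = roc_and_auc(scores, y == 1).auc
        rows.append({"lambda_margin": lam_m, "lambda_net": lam_n,
                     "cv_sensitivity": sens, "cv_specificity": spec,
                     "cv_auc": auc})
        pooled[(lam_m, lam_n)] = scores.copy()
    table = pd.DataFrame(rows)
    best = table.loc[table["cv_auc"].idxmax()]
    res = NetworkSVM(X, y, laplacian=laplacian,
                     lambda_margin=float(best["lambda_margin"]),
                     lambda_net=float(best["lambda_net"])).fit(seed=seed)
    f_all = res.decision_function(X).to_numpy()
    apparent = {
        "apparent_sensitivity": float((f_all[y == 1] > 0).mean()),
        "apparent_specificity": float((f_all[y == -1] <= 0).mean()),
        "apparent_auc": roc_and_auc(f_all, y == 1).auc,
    }
    return {"cv_table": table, "best": dict(best), "apparent": apparent,
            "results": res,
            "cv_scores": pooled[(best["lambda_margin"], best["lambda_net"])]}
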