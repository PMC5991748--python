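"""Weighted co-expression network construction and module detection.

The WGCNA-style recipe: Pearson correlation across samples, unsigned soft
thresholding (adjacency = |cor|^beta with beta chosen by the scale-free
topology criterion), the topological overlap measure (TOM) as a
neighborhood-aware similarity, average-linkage hierarchical clustering on
1 - TOM, and a dynamic branch cut with a minimum module size.  Modules are
summarised by their eigengene (first principal component of the standardized
member submatrix), module membership kME (correlation with the eigengene)
and intramodular connectivity kIM.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import NamedTuple, Sequence
import warnings

import numpy as np
import pandas as pd
import networkx as nx
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .containers import ExpressionMatrix, ModulePartition, color_for_label

__all__ = [
    "correlation_matrix", "scale_free_fit", "pick_power", "tom_matrix",
    "cluster_and_cut", "module_eigengene", "kme_and_kim",
    "CoexpressionNetwork", "ScaleFreeFit",
]


def correlation_matrix(X: ExpressionMatrix) -> pd.DataFrame:
    """Pearson correlation between all feature pairs, across samples."""
    X.validate()
    v = X.values
    sd = v.std(axis=1)
    if (sd == 0).any():
        bad = [X.feature_ids[i] for i in np.flatnonzero(sd == 0)]
        raise ValueError(f"zero-variance features: {bad[:5]}")
    corr = np.corrcoef(v)
    corr = np.clip((corr + corr.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(corr, 1.0)
    return pd.DataFrame(corr, index=X.feature_ids, columns=X.feature_ids)


class ScaleFreeFit(NamedTuple):
    """R^2 of the log-log frequency/connectivity regression."""
    r_squared: float
    slope: float
    degenerate: bool


def scale_free_fit(k: np.ndarray | pd.Series, n_bins: int = 10) -> ScaleFreeFit:
    """Scale-free topology fit index of a connectivity vector.

    Connectivities are grouped into ``n_bins`` equal-width bins; the linear
    regression of log10(bin frequency) on log10(bin mean connectivity) gives
    the fit R^2.  Empty bins are dropped.  A constant connectivity vector is
    degenerate and returns R^2 = 0 with the ``degenerate`` flag set.
    """
    k = np.asarray(k, dtype=float)
    if n_bins < 4:
        raise ValueError("n_bins must be >= 4")
    if (k < 0).any():
        raise ValueError("connectivities must be nonnegative")
    if np.ptp(k) == 0:
        warnings.warn("all connectivities equal; scale-free fit undefined")
        return ScaleFreeFit(0.0, 0.0, True)
    edges = np.linspace(k.min(), k.max(), n_bins + 1)
    which = np.clip(np.digitize(k, edges[1:-1]), 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    keep = np.flatnonzero(counts > 0)
    mean_k = np.array([k[which == b].mean() for b in keep])
    freq = counts[keep] / k.size
    pos = mean_k > 0
    mean_k, freq = mean_k[pos], freq[pos]
    if mean_k.size < 2 or np.ptp(np.log10(mean_k)) == 0:
        warnings.warn("too few populated bins; scale-free fit undefined")
        return ScaleFreeFit(0.0, 0.0, True)
    x, y = np.log10(mean_k), np.log10(freq)
    slope, intercept = np.polyfit(x, y, 1)
    ss_res = np.sum((y - (slope * x + intercept)) ** 2)
    ss_tot = np.sum((y - y.mean()) ** 2)
    r2 = 1.0 if ss_tot == 0 else 1.0 - ss_res / ss_tot
    return ScaleFreeFit(float(max(0.0, r2)), float(slope), False)


class PowerScan(NamedTuple):
    beta: float
    table: pd.DataFrame  # columns: power, r_squared, slope, mean_k
    reached_cut: bool


def pick_power(
    X: ExpressionMatrix,
    candidate_powers: Sequence[float] = tuple(range(1, 21)),
    fit_cut: float = 0.8,
    n_bins: int = 10,
    corr: pd.DataFrame | None = None,
) -> PowerScan:
    """Soft-threshold selection: the smallest candidate power whose
    scale-free fit R^2 reaches ``fit_cut``; if none does, the power with the
    best fit (``reached_cut`` False)."""
    powers = list(candidate_powers)
    if not powers or any(b <= 0 for b in powers):
        raise ValueError("candidate_powers must be positive")
    if sorted(powers) != powers:
        raise ValueError("candidate_powers must be ascending")
    if corr is None:
        corr = correlation_matrix(X)
    ac = np.abs(corr.to_numpy())
    np.fill_diagonal(ac, 0.0)
    rows = []
    for beta in powers:
        adj = ac ** beta
        k = adj.sum(axis=1)
        fit = scale_free_fit(k, n_bins=n_bins)
        rows.append((beta, fit.r_squared, fit.slope, float(k.mean())))
    table = pd.DataFrame(rows,
                         columns=["power", "r_squared", "slope", "mean_k"])
    ok = table["r_squared"] >= fit_cut
    if ok.any():
        beta = float(table.loc[ok, "power"].iloc[0])
        return PowerScan(beta, table, True)
    beta = float(table.loc[table["r_squared"].idxmax(), "power"])
    return PowerScan(beta, table, False)


def tom_matrix(adjacency: pd.DataFrame | np.ndarray) -> pd.DataFrame:
    """Topological overlap measure.

    For i != j,  TOM_ij = (sum_u a_iu a_uj + a_ij) / (min(k_i, k_j) + 1 - a_ij),
    with k the connectivity (adjacency row sum, diagonal excluded); the
    diagonal is reported as 1.
    """
    if isinstance(adjacency, pd.DataFrame):
        ids = list(adjacency.index)
        a = adjacency.to_numpy(dtype=float).copy()
    else:
        a = np.array(adjacency, dtype=float)
        ids = list(range(a.shape[0]))
    if a.shape[0] != a.shape[1] or not np.allclose(a, a.T, atol=1e-10):
        raise ValueError("adjacency must be symmetric")
    if a.min() < 0 or a.max() > 1:
        raise ValueError("adjacency entries must lie in [0, 1]")
    np.fill_diagonal(a, 0.0)
    k = a.sum(axis=1)
    shared = a @ a
    denom = np.minimum.outer(k, k) + 1.0 - a
    tom = (shared + a) / denom
    np.fill_diagonal(tom, 1.0)
    return pd.DataFrame(tom, index=ids, columns=ids)


# deep_split -> position of the branch cut within the merge-height range
# (min + frac * (max - min)); between-branch joins concentrate at the very
# top of the dendrogram, so the cut sits just below them.  Higher fractions
# split less aggressively.
_CUT_FRACTION = {0: 0.95, 1: 0.97, 2: 0.99, 3: 0.995}


def cluster_and_cut(
    tom: pd.DataFrame,
    min_module_size: int = 3,
    deep_split: int = 2,
) -> ModulePartition:
    """Average-linkage clustering on 1 - TOM with a dynamic branch cut.

    The dendrogram is cut at a height fraction of the top merge (controlled
    by ``deep_split``); connected branches of size >= ``min_module_size``
    become modules, labelled 1..K by decreasing size, everything else is
    unassigned (label 0).  A flat dendrogram (all merge heights equal) is
    degenerate: the whole feature set becomes one module, with a warning.
    """
    if deep_split not in _CUT_FRACTION:
        raise ValueError(f"deep_split must be one of {sorted(_CUT_FRACTION)}")
    ids = list(tom.index)
    n = len(ids)
    if n < min_module_size:
        warnings.warn("fewer features than min_module_size; all unassigned")
        return ModulePartition(pd.Series(0, index=ids))
    diss = 1.0 - tom.to_numpy(dtype=float)
    np.fill_diagonal(diss, 0.0)
    z = linkage(squareform(diss, checks=False), method="average")
    heights = z[:, 2]
    if np.allclose(heights, heights[0]):
        warnings.warn("flat dendrogram: all merge heights equal; "
                      "returning a single module spanning all features")
        return ModulePartition(pd.Series(1, index=ids))
    h_min, h_max = heights.min(), heights.max()
    cut = h_min + _CUT_FRACTION[deep_split] * (h_max - h_min)
    raw = fcluster(z, t=cut, criterion="distance")
    sizes = pd.Series(raw).value_counts()
    big = sizes[sizes >= min_module_size]
    order = big.sort_values(ascending=False).index
    relabel = {old: new for new, old in enumerate(order, start=1)}
    labels = pd.Series([relabel.get(c, 0) for c in raw], index=ids)
    return ModulePartition(labels)


def module_eigengene(
    X: ExpressionMatrix,
    partition: ModulePartition,
) -> tuple[pd.DataFrame, pd.Series]:
    """Eigengene (first PC of the standardized member submatrix) per module.

    Returns ``(eigengenes, prop_var_expl)`` where eigengenes is a
    samples x modules frame.  Each eigengene is sign-oriented so that its
    mean correlation with the module members is positive; prop_var_expl is
    the mean squared member/eigengene correlation.  A singleton module's
    eigengene is the standardized feature itself.
    """
    eig = {}
    pve = {}
    for m in partition.module_labels:
        members = [f for f in partition.members(m) if f in X.data.index]
        if not members:
            continue
        sub = X.data.loc[members].to_numpy(dtype=float)
        sd = sub.std(axis=1, ddof=1)
        if (sd == 0).any():
            raise ValueError(
                f"zero-variance members in module {m}; cannot standardize")
        z = (sub - sub.mean(axis=1, keepdims=True)) / sd[:, None]
        if len(members) == 1:
            e = z[0]
        else:
            _, _, vt = np.linalg.svd(z, full_matrices=False)
            e = vt[0]
        cors = _row_cor_with(z, e)
        if cors.mean() < 0:
            e = -e
            cors = -cors
        eig[m] = e
        pve[m] = float(np.mean(cors ** 2))
    frame = pd.DataFrame(eig, index=X.sample_ids)
    frame.columns = [f"ME{m}" for m in frame.columns]
    return frame, pd.Series(pve, name="prop_var_expl")


def _row_cor_with(rows: np.ndarray, v: np.ndarray) -> np.ndarray:
    """Pearson correlation of each row with vector v (n >= 2)."""
    rc = rows - rows.mean(axis=1, keepdims=True)
    vc = v - v.mean()
    denom = np.sqrt((rc ** 2).sum(axis=1) * (vc ** 2).sum())
    return (rc @ vc) / denom


def kme_and_kim(
    X: ExpressionMatrix,
    adjacency: pd.DataFrame,
    partition: ModulePartition,
) -> tuple[pd.DataFrame, pd.Series]:
    """Module membership kME and intramodular connectivity kIM.

    kME is the feature x module matrix of correlations with the module
    eigengenes; kIM is each feature's adjacency row sum restricted to its
    own module (0 for unassigned features).
    """
    eig, _ = module_eigengene(X, partition)
    v = X.values
    if (v.std(axis=1) == 0).any():
        raise ValueError("zero-variance features; kME undefined")
    kme = pd.DataFrame(index=X.feature_ids, columns=eig.columns, dtype=float)
    for col in eig.columns:
        kme[col] = _row_cor_with(v, eig[col].to_numpy())
    kim = pd.Series(0.0, index=X.feature_ids)
    a = adjacency.to_numpy(dtype=float).copy()
    np.fill_diagonal(a, 0.0)
    pos = {f: i for i, f in enumerate(adjacency.index)}
    for m in partition.module_labels:
        members = partition.members(m)
        idx = [pos[f] for f in members if f in pos]
        block = a[np.ix_(idx, idx)]
        ks = block.sum(axis=1)
        for f, kv in zip([f for f in members if f in pos], ks):
            kim[f] = kv
    return kme, kim


@dataclass
class CoexprNetwork:
    """A built weighted co-expression network for one cohort."""

    corr: pd.DataFrame
    beta: float
    adjacency: pd.DataFrame
    tom: pd.DataFrame
    k: pd.Series
    power_scan: pd.DataFrame | None = None
    reached_fit_cut: bool = True

    @property
    def feature_ids(self) -> list[str]:
        return list(self.adjacency.index)

    def to_graph(self, tom_cutoff: float = 0.1) -> nx.Graph:
        """Thresholded TOM graph (edge kept when TOM >= cutoff)."""
        g = nx.Graph()
        g.add_nodes_from(self.feature_ids)
        t = self.tom.to_numpy()
        ids = self.feature_ids
        iu, ju = np.triu_indices(len(ids), k=1)
        keep = t[iu, ju] >= tom_cutoff
        g.add_weighted_edges_from(
            (ids[i], ids[j], float(t[i, j]))
            for i, j in zip(iu[keep], ju[keep]))
        return g

    def write_sif(self, path, tom_cutoff: float = 0.1) -> None:
        with open(path, "w") as fh:
            for u, v, d in self.to_graph(tom_cutoff).edges(data=True):
                fh.write(f"{u}\ttom\t{v}\t{d['weight']:.6g}\n")

    def write_graphml(self, path, tom_cutoff: float = 0.1) -> None:
        nx.write_graphml(self.to_graph(tom_cutoff), path)


class CoexpressionNetwork:
    """Builder facade: expression matrix in, network + modules out.

    Example
    -------
    >>> net = CoexpressionNetwork.from_expression(expr)   # doctest: +SKIP
    >>> part = net.detect_modules(min_module_size=3)      # doctest: +SKIP
    """

    def __init__(self, network: CoexprNetwork, X: ExpressionMatrix):
        self.network = network
        self.X = X

    @classmethod
    def from_expression(
        cls,
        X: ExpressionMatrix,
        candidate_powers: Sequence[float] = tuple(range(1, 21)),
        fit_cut: float = 0.8,
        beta: float | None = None,
    ) -> "CoexpressionNetwork":
        corr = correlation_matrix(X)
        scan_table, reached = None, True
        if beta is None:
            scan = pick_power(X, candidate_powers, fit_cut, corr=corr)
            beta, scan_table, reached = scan.beta, scan.table, scan.reached_cut
        ac = np.abs(corr.to_numpy()) ** beta
        np.fill_diagonal(ac, 1.0)
        adjacency = pd.DataFrame(ac, index=corr.index, columns=corr.columns)
        tom = tom_matrix(adjacency)
        a0 = ac.copy()
        np.fill_diagonal(a0, 0.0)
        k = pd.Series(a0.sum(axis=1), index=corr.index, name="k")
        net = CoexprNetwork(corr=corr, beta=float(beta), adjacency=adjacency,
                            tom=tom, k=k, power_scan=scan_table,
                            reached_fit_cut=reached)
        return cls(net, X)

    def detect_modules(self, min_module_size: int = 3,
                       deep_split: int = 2) -> ModulePartition:
        return cluster_and_cut(self.network.tom, min_module_size, deep_split)

    def eigengenes(self, partition: ModulePartition):
        return module_eigengene(self.X, partition)

    def membership(self, partition: ModulePartition):
        return kme_and_kim(self.X, self.network.adjacency, partition)
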