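"""Permutation-based module preservation (Z_summary) between cohorts.

Given a module partition learned on a reference cohort and an independent
test cohort, each module is scored by seven statistics: four *density*
statistics measured in the test data (mean member correlation, mean member
adjacency, proportion of variance explained by the module eigengene, mean
module membership kME) and three *connectivity* statistics correlating the
module's wiring between reference and test (intramodular connectivity kIM,
kME profiles, and the member-pair correlation pattern itself).  Each
observed statistic is standardized against a permutation null built from
random pseudo-modules of the same size, giving seven Z components, and

    Z_summary = ( median(Z_meanCor, Z_meanAdj, Z_propVarExpl, Z_meanKME)
                + median(Z_cor_kIM, Z_cor_kME, Z_cor_cor) ) / 2.

Interpretation thresholds follow the permutation-Z convention:
Z_summary >= 10 strong preservation, >= 2 preservation, [0, 2) weak
evidence, < 0 disruption.  A module disrupted against normal controls but
reproducible against a technical replicate is an *activated* module — the
candidate disease biomarker.

Usage::

    model = ModulePreservation(ref, test, partition, beta=6)
    res = model.fit(n_perm=200, seed=11)
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, NamedTuple, Sequence
import warnings

import numpy as np
import pandas as pd

from .containers import ExpressionMatrix, ModulePartition

__all__ = [
    "DensityStats", "ConnectivityStats", "observed_density_stats",
    "observed_connectivity_stats", "permutation_null", "zsummary",
    "classify_modules", "ModulePreservation", "PreservationResults",
]

DENSITY_STATS = ("meanCor", "meanAdj", "propVarExpl", "meanKME")
CONNECTIVITY_STATS = ("cor_kIM", "cor_kME", "cor_cor")
ALL_STATS = DENSITY_STATS + CONNECTIVITY_STATS


class DensityStats(NamedTuple):
    meanCor: float
    meanAdj: float
    propVarExpl: float
    meanKME: float


class ConnectivityStats(NamedTuple):
    cor_kIM: float
    cor_kME: float
    cor_cor: float


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std(axis=1, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance feature; statistics undefined")
    return (v - v.mean(axis=1, keepdims=True)) / sd[:, None]


def _eigengene(z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First right singular vector of standardized rows, sign-oriented so
    the mean member correlation is positive; returns (eigengene, kME)."""
    if z.shape[0] == 1:
        e = z[0]
    else:
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        e = vt[0]
    ec = e - e.mean()
    denom = np.sqrt((z ** 2).sum(axis=1) * (ec ** 2).sum())
    kme = (z @ ec) / denom
    if kme.mean() < 0:
        kme = -kme
        e = -e
    return e, kme


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return float("nan")
    return float(np.corrcoef(a, b)[0, 1])


class _Cohort:
    """Precomputed per-cohort matrices reused across modules and draws."""

    def __init__(self, X: ExpressionMatrix, beta: float):
        X.validate()
        self.ids = list(X.feature_ids)
        self.z = _standardize(X.values)
        self.corr = np.corrcoef(X.values)
        np.fill_diagonal(self.corr, 1.0)
        self.adj = np.abs(self.corr) ** beta
        np.fill_diagonal(self.adj, 0.0)
        self.pos = {f: i for i, f in enumerate(self.ids)}


def _density_from(cohort: _Cohort, ix: np.ndarray) -> DensityStats:
    c = cohort.corr[np.ix_(ix, ix)]
    a = cohort.adj[np.ix_(ix, ix)]
    s = ix.size
    off = ~np.eye(s, dtype=bool)
    _, kme = _eigengene(cohort.z[ix])
    return DensityStats(
        meanCor=float(c[off].mean()),
        meanAdj=float(a[off].mean()),
        propVarExpl=float(np.mean(kme ** 2)),
        meanKME=float(kme.mean()),
    )


def _connectivity_from(ref: _Cohort, test: _Cohort,
                       ix_ref: np.ndarray, ix_test: np.ndarray
                       ) -> ConnectivityStats:
    a_ref = ref.adj[np.ix_(ix_ref, ix_ref)]
    a_test = test.adj[np.ix_(ix_test, ix_test)]
    kim_ref, kim_test = a_ref.sum(axis=1), a_test.sum(axis=1)
    _, kme_ref = _eigengene(ref.z[ix_ref])
    _, kme_test = _eigengene(test.z[ix_test])
    iu = np.triu_indices(ix_ref.size, k=1)
    c_ref = ref.corr[np.ix_(ix_ref, ix_ref)][iu]
    c_test = test.corr[np.ix_(ix_test, ix_test)][iu]
    return ConnectivityStats(
        cor_kIM=_pearson(kim_ref, kim_test),
        cor_kME=_pearson(kme_ref, kme_test),
        cor_cor=_pearson(c_ref, c_test),
    )


# -- public single-module operations ------------------------------------


def observed_density_stats(X_test: ExpressionMatrix, members: Sequence[str],
                           beta: float) -> DensityStats:
    """Density statistics of a member set measured in the test cohort."""
    members = list(members)
    missing = [f for f in members if f not in set(X_test.feature_ids)]
    if missing:
        raise ValueError(f"members missing from test data: {missing}")
    if len(members) < 3:
        raise ValueError("module must have >= 3 members")
    cohort = _Cohort(X_test, beta)
    ix = np.array([cohort.pos[f] for f in members])
    return _density_from(cohort, ix)


def observed_connectivity_stats(X_ref: ExpressionMatrix,
                                X_test: ExpressionMatrix,
                                members: Sequence[str],
                                beta: float) -> ConnectivityStats:
    """Connectivity-preservation statistics between reference and test."""
    members = list(members)
    if len(members) < 3:
        raise ValueError("module must have >= 3 members")
    for name, X in (("reference", X_ref), ("test", X_test)):
        missing = [f for f in members if f not in set(X.feature_ids)]
        if missing:
            raise ValueError(f"members missing from {name} data: {missing}")
    ref = _Cohort(X_ref, beta)
    test = _Cohort(X_test, beta)
    ix_ref = np.array([ref.pos[f] for f in members])
    ix_test = np.array([test.pos[f] for f in members])
    return _connectivity_from(ref, test, ix_ref, ix_test)


class PermutationNull(NamedTuple):
    mean: float
    sd: float
    degenerate: bool

    def z(self, observed: float) -> float:
        """Permutation Z-score; NaN (flagged) when the null sd is zero."""
        if self.degenerate or not np.isfinite(self.sd) or self.sd == 0:
            return float("nan")
        return (observed - self.mean) / self.sd


def permutation_null(
    X_ref: ExpressionMatrix,
    X_test: ExpressionMatrix,
    module_size: int,
    statistic: Callable[[Sequence[str]], float],
    n_perm: int = 200,
    seed: int | None = None,
) -> PermutationNull:
    """Null distribution of an arbitrary member-set statistic.

    Draws ``n_perm`` pseudo-modules of ``module_size`` features uniformly
    without replacement from the test cohort's features (in sorted-id order,
    so the null is invariant to input feature ordering) and evaluates
    ``statistic`` on each.  A constant statistic yields a degenerate null
    (flagged); Z-scores against it are NaN rather than infinite.
    """
    if n_perm < 20:
        raise ValueError("n_perm must be >= 20")
    universe = sorted(X_test.feature_ids)
    if module_size > len(universe):
        raise ValueError("module size exceeds the feature count")
    rng = np.random.default_rng(seed)
    draws = np.empty(n_perm)
    for b in range(n_perm):
        ix = rng.choice(len(universe), size=module_size, replace=False)
        draws[b] = statistic([universe[i] for i in ix])
    sd = float(draws.std(ddof=1))
    return PermutationNull(float(draws.mean()), sd, degenerate=(sd == 0))


def zsummary(z_components: Sequence[float]) -> tuple[float, float, float]:
    """(Z_density, Z_connectivity, Z_summary) from the 7 Z components,
    ordered (meanCor, meanAdj, propVarExpl, meanKME, cor_kIM, cor_kME,
    cor_cor).  Any undefined (NaN) component propagates the flag."""
    z = np.asarray(list(z_components), dtype=float)
    if z.size != 7:
        raise ValueError("expected exactly 7 Z components")
    z_density = float(np.median(z[:4]))
    z_connectivity = float(np.median(z[4:]))
    return z_density, z_connectivity, (z_density + z_connectivity) / 2.0


def classify_z(z: float) -> str:
    """Preservation class of one Z_summary value."""
    if not np.isfinite(z):
        return "undefined"
    if z >= 10:
        return "strong"
    if z >= 2:
        return "preserved"
    if z >= 0:
        return "weak"
    return "activated"


def classify_modules(z_vs_rep: pd.Series,
                     z_vs_norm: pd.Series) -> tuple[pd.DataFrame, list[int]]:
    """Per-module classes and the activated-biomarker set.

    A module is an activated biomarker when its Z_summary against the
    normal cohort is negative (disrupted co-expression) while its
    Z_summary against the technical replicate is nonnegative (the module
    itself is reproducible, so the disruption is not an artifact).
    """
    if set(z_vs_rep.index) != set(z_vs_norm.index):
        raise ValueError("both Z vectors must cover the same modules")
    z_vs_norm = z_vs_norm.reindex(z_vs_rep.index)
    table = pd.DataFrame({
        "z_vs_rep": z_vs_rep,
        "z_vs_norm": z_vs_norm,
        "class_vs_rep": [classify_z(z) for z in z_vs_rep],
        "class_vs_norm": [classify_z(z) for z in z_vs_norm],
    })
    biomarkers = [int(m) for m in table.index
                  if table.loc[m, "z_vs_norm"] < 0
                  and table.loc[m, "z_vs_rep"] >= 0]
    table["activated_biomarker"] = [int(m) in biomarkers for m in table.index]
    return table, biomarkers


# -- the Model / Results pair -------------------------------------------


class ModulePreservation:
    """Permutation preservation model for one reference/test comparison.

    Parameters
    ----------
    X_ref, X_test : expression matrices over a shared feature universe.
    partition : module partition learned on the reference cohort.
    beta : soft power fitted on the reference cohort (reused for the test
        adjacency so statistics are comparable).
    min_module_size : modules smaller than this are skipped with a warning.
    """

    def __init__(self, X_ref: ExpressionMatrix, X_test: ExpressionMatrix,
                 partition: ModulePartition, beta: float,
                 min_module_size: int = 3):
        self.X_ref = X_ref
        self.X_test = X_test
        self.partition = partition
        self.beta = float(beta)
        self.min_module_size = int(min_module_size)
        shared = set(X_ref.feature_ids) & set(X_test.feature_ids)
        if not shared:
            raise ValueError("cohorts share no features")
        self._ref = _Cohort(X_ref, self.beta)
        self._test = _Cohort(X_test, self.beta)

    def _stats_for(self, members: list[str]) -> np.ndarray:
        ix_ref = np.array([self._ref.pos[f] for f in members])
        ix_test = np.array([self._test.pos[f] for f in members])
        d = _density_from(self._test, ix_test)
        c = _connectivity_from(self._ref, self._test, ix_ref, ix_test)
        return np.array(list(d) + list(c))

    def fit(self, n_perm: int = 200, seed: int | None = None
            ) -> "PreservationResults":
        """Run the permutation study and score every module."""
        if seed is None:
            raise ValueError("a seed is mandatory for the permutation null")
        if n_perm < 20:
            raise ValueError("n_perm must be >= 20")
        shared = set(self._ref.pos) & set(self._test.pos)
        universe = sorted(shared)
        rng = np.random.default_rng(seed)

        modules, observed = [], []
        for m in self.partition.module_labels:
            members = sorted(f for f in self.partition.members(m)
                             if f in shared)
            if len(members) < self.min_module_size:
                warnings.warn(f"module {m} has fewer than "
                              f"{self.min_module_size} members; skipped")
                continue
            modules.append((m, members))
            observed.append(self._stats_for(members))
        observed = np.array(observed) if modules else np.empty((0, 7))

        # one null per module size; modules of equal size share draws
        sizes = sorted({len(members) for _, members in modules})
        null_stats: dict[int, np.ndarray] = {}
        for size in sizes:
            draws = np.empty((n_perm, 7))
            for b in range(n_perm):
                ix = rng.choice(len(universe), size=size, replace=False)
                draws[b] = self._stats_for([universe[i] for i in ix])
            null_stats[size] = draws

        rows = {}
        for (m, members), obs in zip(modules, observed):
            draws = null_stats[len(members)]
            mu, sd = draws.mean(axis=0), draws.std(axis=0, ddof=1)
            z = np.full(7, np.nan)
            ok = sd > 0
            z[ok] = (obs[ok] - mu[ok]) / sd[ok]
            z_den, z_con, z_sum = zsummary(z)
            row = {"size": len(members)}
            row.update({s: o for s, o in zip(ALL_STATS, obs)})
            row.update({f"Z_{s}": zz for s, zz in zip(ALL_STATS, z)})
            row.update({"Z_density": z_den, "Z_connectivity": z_con,
                        "Z_summary": z_sum,
                        "class": classify_z(z_sum),
                        "flagged": bool(np.isnan(z).any())})
            rows[m] = row
        table = pd.DataFrame.from_dict(rows, orient="index")
        table.index.name = "module"
        return PreservationResults(self, table, n_perm=n_perm, seed=seed)


@dataclass
class PreservationResults:
    """Per-module preservation statistics from :class:`ModulePreservation`."""

    model: ModulePreservation
    table: pd.DataFrame
    n_perm: int
    seed: int

    @property
    def z_summary(self) -> pd.Series:
        return self.table["Z_summary"]

    @property
    def classes(self) -> pd.Series:
        return self.table["class"]

    def activated_modules(self) -> list[int]:
        """Modules with negative Z_summary in this comparison."""
        return [int(m) for m in self.table.index
                if self.table.loc[m, "Z_summary"] < 0]

    def summary(self) -> str:
        cols = ["size", "Z_density", "Z_connectivity", "Z_summary", "class"]
        lines = [
            "Module preservation (permutation Z_summary)",
            f"  modules scored: {len(self.table)}   "
            f"n_perm: {self.n_perm}   seed: {self.seed}   "
            f"beta: {self.model.beta:g}",
            "",
            self.table[cols].round(3).to_string(),
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.table.to_csv(path)
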