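"""Module-partition comparison: overlap tables, Fisher tests, and the
module-based consensus ratio (MCR).

Two cohorts' partitions are compared by cross-tabulating module membership
over the shared feature universe; each module pair gets a one-sided
(enrichment) hypergeometric p-value, and the MCR is the percentage of module
pairs that overlap significantly:

    MCR_ab = NM_overlap / (NM_a * NM_b) * 100%

with NM_a and NM_b the module counts of the two partitions and NM_overlap
the number of pairs with p below alpha.
"""

from __future__ import annotations

from dataclasses import dataclass
import json

import numpy as np
import pandas as pd
from scipy.stats import hypergeom

from .containers import ModulePartition

__all__ = ["OverlapResult", "overlap_counts", "fisher_overlap_p", "mcr",
           "compare_partitions"]


@dataclass
class OverlapResult:
    """Cross-tabulation of two partitions with per-pair enrichment p-values."""

    counts: pd.DataFrame     # modules of a (rows) x modules of b (cols)
    pvalues: pd.DataFrame
    nm_a: int
    nm_b: int
    nm_overlap: int
    mcr_percent: float
    alpha: float = 0.05
    universe_size: int = 0

    def to_json(self) -> str:
        return json.dumps({
            "NM_a": self.nm_a, "NM_b": self.nm_b,
            "NM_overlap": self.nm_overlap,
            "mcr_percent": self.mcr_percent,
            "alpha": self.alpha, "universe_size": self.universe_size,
        }, indent=2)


def overlap_counts(pa: ModulePartition, pb: ModulePartition,
                   universe: str = "intersection") -> pd.DataFrame:
    """Member-count cross-table over the common feature universe.

    Rows are modules of ``pa``, columns modules of ``pb``; label 0
    (unassigned) is excluded from both axes.  ``universe`` chooses whether
    features must be present in both partitions ("intersection", default)
    or either ("union", with absent features counting in no module).
    """
    if universe not in ("intersection", "union"):
        raise ValueError("universe must be 'intersection' or 'union'")
    shared = set(pa.feature_ids) & set(pb.feature_ids)
    if not shared:
        raise ValueError("partitions share no feature ids")
    mods_a, mods_b = pa.module_labels, pb.module_labels
    table = pd.DataFrame(0, index=mods_a, columns=mods_b, dtype=int)
    for f in shared:
        la, lb = int(pa.labels[f]), int(pb.labels[f])
        if la != 0 and lb != 0:
            table.loc[la, lb] += 1
    return table


def fisher_overlap_p(overlap: int, size_a: int, size_b: int, n: int) -> float:
    """One-sided enrichment p-value P(X >= overlap), X hypergeometric with
    ``size_a`` draws from a universe of ``n`` containing ``size_b``
    successes (equivalently Fisher's exact test, greater alternative)."""
    if overlap > min(size_a, size_b):
        raise ValueError("overlap cannot exceed either module size")
    if max(size_a, size_b) > n:
        raise ValueError("module sizes cannot exceed the universe size")
    if overlap < 0 or n <= 0:
        raise ValueError("counts must be nonnegative and universe positive")
    return float(hypergeom.sf(overlap - 1, n, size_b, size_a))


def mcr(pvalues: pd.DataFrame, alpha: float = 0.05) -> tuple[int, float]:
    """Count significant module pairs and the consensus ratio in percent."""
    if pvalues.size == 0:
        raise ValueError("empty p-value table")
    nm_overlap = int((pvalues.to_numpy() < alpha).sum())
    mcr_percent = nm_overlap / pvalues.size * 100.0
    return nm_overlap, float(mcr_percent)


def compare_partitions(
    pa: ModulePartition,
    pb: ModulePartition,
    alpha: float = 0.05,
    universe: str = "intersection",
    include_unassigned_in_universe: bool = True,
) -> OverlapResult:
    """Full comparison: counts, per-pair Fisher p-values, and MCR.

    The universe N of each hypergeometric test is the shared feature set
    (all clustered features, including the unassigned ones by default);
    module sizes are counted within that universe.
    """
    counts = overlap_counts(pa, pb, universe=universe)
    if universe == "intersection":
        shared = set(pa.feature_ids) & set(pb.feature_ids)
    else:
        shared = set(pa.feature_ids) | set(pb.feature_ids)
    if not include_unassigned_in_universe:
        shared = {f for f in shared
                  if int(pa.labels.get(f, 0)) != 0
                  or int(pb.labels.get(f, 0)) != 0}
    n = len(shared)
    sizes_a = {m: sum(1 for f in pa.members(m) if f in shared)
               for m in counts.index}
    sizes_b = {m: sum(1 for f in pb.members(m) if f in shared)
               for m in counts.columns}
    pvals = pd.DataFrame(1.0, index=counts.index, columns=counts.columns)
    for i in counts.index:
        for j in counts.columns:
            pvals.loc[i, j] = fisher_overlap_p(
                int(counts.loc[i, j]), sizes_a[i], sizes_b[j], n)
    if counts.size == 0:
        return OverlapResult(counts, pvals, len(counts.index),
                             len(counts.columns), 0, 0.0, alpha, n)
    nm_overlap, mcr_percent = mcr(pvals, alpha)
    return OverlapResult(
        counts=counts, pvalues=pvals,
        nm_a=len(counts.index), nm_b=len(counts.columns),
        nm_overlap=nm_overlap, mcr_percent=mcr_percent,
        alpha=alpha, universe_size=n)
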