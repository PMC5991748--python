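"""Target-gene consensus and functional enrichment for miRNA modules.

Target predictions from three local database export files (tab- or
comma-separated ``miRNA, gene[, score]`` rows) are intersected per miRNA —
a gene counts as a target only when all three sources agree — and the
module's target set is the union of its members' consensus sets.  Term
enrichment of a gene set against a local annotation table (GMT or
two-column TSV) uses the one-sided hypergeometric test with
Benjamini-Hochberg adjustment within each category.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence
import csv
import warnings

import numpy as np
import pandas as pd
import networkx as nx
from statsmodels.stats.multitest import multipletests

from .modcompare import fisher_overlap_p

__all__ = ["TargetMap", "load_target_file", "consensus_targets",
           "ConsensusTargets", "load_gmt", "enrich"]


@dataclass
class TargetMap:
    """miRNA -> gene-set maps from exactly three prediction sources."""

    sources: dict[str, dict[str, set[str]]]

    def __post_init__(self) -> None:
        if len(self.sources) != 3:
            raise ValueError("consensus mode requires exactly three sources")
        for name, mapping in self.sources.items():
            for mir, genes in mapping.items():
                if any(not g for g in genes):
                    raise ValueError(
                        f"empty gene symbol under {name}/{mir}")

    @property
    def source_names(self) -> list[str]:
        return list(self.sources)


def load_target_file(path) -> dict[str, set[str]]:
    """Read one export file of ``miRNA, gene[, score]`` rows (TSV or CSV,
    optional header)."""
    mapping: dict[str, set[str]] = {}
    with open(path, newline="") as fh:
        sample = fh.read(4096)
        fh.seek(0)
        delim = "\t" if "\t" in sample.splitlines()[0] else ","
        reader = csv.reader(fh, delimiter=delim)
        for row in reader:
            if len(row) < 2 or not row[0].strip():
                continue
            mir, gene = row[0].strip(), row[1].strip()
            if mir.lower() in ("mirna", "mir", "feature"):  # header row
                continue
            mapping.setdefault(mir, set()).add(gene)
    return mapping


@dataclass
class ConsensusTargets:
    per_mirna: dict[str, set[str]]
    union: set[str]
    attribution: dict[str, set[str]]      # gene -> miRNAs that target it
    missing: list[str] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        rows = [(g, ";".join(sorted(mirs)))
                for g, mirs in sorted(self.attribution.items())]
        return pd.DataFrame(rows, columns=["gene", "mirnas"])

    def to_graph(self) -> nx.Graph:
        """Bipartite miRNA-target network (Fig-style analog)."""
        g = nx.Graph()
        for mir, genes in self.per_mirna.items():
            g.add_node(mir, kind="mirna")
            for gene in genes:
                g.add_node(gene, kind="gene")
                g.add_edge(mir, gene)
        return g


def consensus_targets(targets: TargetMap,
                      mirnas: Sequence[str]) -> ConsensusTargets:
    """Three-way intersection per miRNA; union (with per-gene attribution)
    over the queried miRNAs.  A miRNA absent from a source contributes an
    empty set there (hence an empty consensus) and is flagged, not fatal."""
    per: dict[str, set[str]] = {}
    missing = []
    for mir in mirnas:
        sets = []
        absent = [name for name, mapping in targets.sources.items()
                  if mir not in mapping]
        if absent:
            missing.append(mir)
            warnings.warn(f"{mir} missing from sources {absent}; "
                          "treated as empty")
        for mapping in targets.sources.values():
            sets.append(mapping.get(mir, set()))
        per[mir] = set.intersection(*sets) if sets else set()
    attribution: dict[str, set[str]] = {}
    for mir, genes in per.items():
        for g in genes:
            attribution.setdefault(g, set()).add(mir)
    return ConsensusTargets(per_mirna=per,
                            union=set(attribution),
                            attribution=attribution,
                            missing=missing)


def load_gmt(path) -> pd.DataFrame:
    """Read a GMT (term, description, genes...) or a two-column
    ``term<TAB>gene`` file into a (term, category, genes) frame."""
    rows = []
    with open(path) as fh:
        first = fh.readline()
        fh.seek(0)
        if first.count("\t") >= 2:          # GMT
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 3:
                    continue
                rows.append((parts[0], parts[1] or "NA",
                             frozenset(g for g in parts[2:] if g)))
        else:                                # term<TAB>gene pairs
            pairs: dict[str, set[str]] = {}
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                if len(parts) < 2:
                    continue
                pairs.setdefault(parts[0], set()).add(parts[1])
            rows = [(t, "NA", frozenset(gs)) for t, gs in pairs.items()]
    return pd.DataFrame(rows, columns=["term", "category", "genes"])


def enrich(query: Sequence[str],
           annotation: pd.DataFrame | Mapping[str, set[str]],
           universe: Sequence[str] | None = None,
           alpha: float = 0.05,
           skip_zero_overlap: bool = True) -> pd.DataFrame:
    """Hypergeometric term enrichment with Benjamini-Hochberg adjustment.

    ``annotation`` is either the frame from :func:`load_gmt` or a plain
    term -> gene-set mapping.  The universe defaults to all genes in the
    annotation table; the query must be a subset of the universe.  The BH
    adjustment runs within each annotation category.  The returned frame
    reports both the raw p and p_adjusted plus a significance flag at
    ``alpha`` on the adjusted value.
    """
    if isinstance(annotation, Mapping):
        annotation = pd.DataFrame(
            [(t, "NA", frozenset(gs)) for t, gs in annotation.items()],
            columns=["term", "category", "genes"])
    if universe is None:
        universe = set().union(*annotation["genes"]) if len(annotation) \
            else set()
    universe = set(universe)
    if not universe:
        raise ValueError("empty universe")
    query = set(query)
    stray = query - universe
    if stray:
        raise ValueError(f"query genes outside the universe: "
                         f"{sorted(stray)[:5]}")
    rows = []
    for _, rec in annotation.iterrows():
        term_genes = set(rec["genes"]) & universe
        overlap = len(term_genes & query)
        if skip_zero_overlap and overlap == 0:
            continue
        p = fisher_overlap_p(overlap, len(query), len(term_genes),
                             len(universe))
        rows.append({"term": rec["term"],
                     "category": rec["category"],
                     "overlap": overlap,
                     "term_size": len(term_genes),
                     "query_size": len(query),
                     "universe_size": len(universe),
                     "p": p})
    out = pd.DataFrame(rows)
    if out.empty:
        out["p_adjusted"] = []
        out["significant"] = []
        return out
    out["p_adjusted"] = np.nan
    for cat, idx in out.groupby("category").groups.items():
        out.loc[idx, "p_adjusted"] = multipletests(
            out.loc[idx, "p"].to_numpy(), method="fdr_bh")[1]
    out["significant"] = out["p_adjusted"] < alpha
    return out.sort_values(["p_adjusted", "p", "term"],
                           kind="mergesort").reset_index(drop=True)
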