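"""Diagnostic evaluation of module biomarkers: ROC, AUC, Youden cutoffs.

A module biomarker's per-sample score is the (optionally weighted) mean of
its member miRNAs' expression; diagnostic value against the normal cohort
is summarized by the ROC curve, the AUC (computed with the pairwise
concordance estimator, ties counted 1/2) and the cutoff maximizing
Youden's J = sensitivity + specificity - 1.  For small modules every member
subset can be enumerated to find the best-performing combination.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import NamedTuple, Sequence
import json

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .containers import ExpressionMatrix

__all__ = ["module_score", "roc_and_auc", "youden_optimal",
           "evaluate_combinations", "evaluate_marker", "DiagnosticResult",
           "RocCurve"]


def module_score(X: ExpressionMatrix, members: Sequence[str],
                 weights: Sequence[float] | None = None) -> pd.Series:
    """Per-sample biomarker score of a member set.

    Unweighted: the arithmetic mean of member expression.  Weighted:
    sum(w_j x_j) / sum(|w_j|), so mixed-sign weights (up- and down-
    regulated members) contribute with their direction while the
    denominator stays away from zero.
    """
    members = list(members)
    sub = X.subset(members).values
    if weights is None:
        score = sub.mean(axis=0)
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape[0] != len(members):
            raise ValueError("one weight per member required")
        if np.all(w == 0):
            raise ValueError("weights must not all be zero")
        score = (w @ sub) / np.abs(w).sum()
    return pd.Series(score, index=X.sample_ids, name="score")


class RocCurve(NamedTuple):
    points: pd.DataFrame   # columns: cutoff, fpr, tpr
    auc: float


def roc_and_auc(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC points (one per candidate cutoff) and the concordance AUC.

    ``labels`` is truthy for cases.  A sample is called positive when its
    score is >= the cutoff; candidate cutoffs are the midpoints between
    consecutive distinct scores plus -inf/+inf endpoints.  The AUC is the
    probability a random case outscores a random control, ties counted
    1/2 — computed via the rank-sum identity, which equals the explicit
    all-pairs average exactly.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=bool)
    if s.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(y.sum()), int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    distinct = np.unique(s)
    cuts = np.concatenate(([-np.inf],
                           (distinct[:-1] + distinct[1:]) / 2.0,
                           [np.inf]))
    rows = []
    for c in cuts:
        called = s >= c
        tpr = float((called & y).sum() / n_pos)
        fpr = float((called & ~y).sum() / n_neg)
        rows.append((c, fpr, tpr))
    pts = pd.DataFrame(rows, columns=["cutoff", "fpr", "tpr"])
    return RocCurve(pts, float(auc))


class YoudenPoint(NamedTuple):
    cutoff: float
    sensitivity: float
    specificity: float
    j: float


def youden_optimal(roc: RocCurve | pd.DataFrame) -> YoudenPoint:
    """Operating point maximizing J = sensitivity + specificity - 1.

    Ties are broken toward the highest specificity, then the lowest
    cutoff.
    """
    pts = roc.points if isinstance(roc, RocCurve) else roc
    if len(pts) == 0:
        raise ValueError("empty ROC")
    cand = pts.assign(
        sensitivity=pts["tpr"],
        specificity=1.0 - pts["fpr"],
    )
    cand["j"] = cand["sensitivity"] + cand["specificity"] - 1.0
    cand = cand.sort_values(["j", "specificity", "cutoff"],
                            ascending=[False, False, True],
                            kind="mergesort")
    top = cand.iloc[0]
    return YoudenPoint(float(top["cutoff"]), float(top["sensitivity"]),
                       float(top["specificity"]), float(top["j"]))


@dataclass
class DiagnosticResult:
    """One marker (member set) evaluated against case/control labels."""

    name: str
    members: list[str]
    weights: list[float] | None
    scores: pd.Series
    roc: RocCurve
    auc: float
    cutoff: float
    sensitivity: float
    specificity: float
    youden_j: float
    flipped_orientation: bool = False

    def to_dict(self) -> dict:
        return {
            "name": self.name, "members": self.members,
            "weighted": self.weights is not None,
            "auc": self.auc, "cutoff": self.cutoff,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "youden_j": self.youden_j,
            "flipped_orientation": self.flipped_orientation,
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def evaluate_marker(X: ExpressionMatrix, members: Sequence[str],
                    labels: Sequence[bool],
                    weights: Sequence[float] | None = None,
                    name: str | None = None) -> DiagnosticResult:
    """Score a member set and evaluate its ROC/AUC and Youden optimum.

    A marker whose AUC falls below 0.5 is reported as-is with the
    ``flipped_orientation`` flag set, rather than silently inverted.
    """
    members = list(members)
    scores = module_score(X, members, weights)
    roc = roc_and_auc(scores.to_numpy(), labels)
    opt = youden_optimal(roc)
    return DiagnosticResult(
        name=name or "+".join(members), members=members,
        weights=None if weights is None else [float(w) for w in weights],
        scores=scores, roc=roc, auc=roc.auc,
        cutoff=opt.cutoff, sensitivity=opt.sensitivity,
        specificity=opt.specificity, youden_j=opt.j,
        flipped_orientation=bool(roc.auc < 0.5))


def evaluate_combinations(
    X: ExpressionMatrix,
    members: Sequence[str],
    labels: Sequence[bool],
    weights: Sequence[float] | None = None,
    min_size: int = 1,
) -> list[DiagnosticResult]:
    """Evaluate every member subset of size >= ``min_size``.

    Results are ordered by AUC (descending), ties by the lexicographic
    member tuple, so the ordering is deterministic.  Weights, when given,
    are subset along with the members.  Capped at 12 members (exhaustive
    enumeration).
    """
    members = list(members)
    if len(members) > 12:
        raise ValueError("exhaustive subset search capped at 12 members")
    if min_size < 1 or min_size > len(members):
        raise ValueError("min_size out of range")
    wmap = None
    if weights is not None:
        weights = list(weights)
        if len(weights) != len(members):
            raise ValueError("one weight per member required")
        wmap = dict(zip(members, weights))
    out = []
    for size in range(min_size, len(members) + 1):
        for combo in combinations(members, size):
            w = None if wmap is None else [wmap[f] for f in combo]
            out.append(evaluate_marker(X, list(combo), labels, w))
    out.sort(key=lambda r: (-r.auc, tuple(r.members)))
    return out
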