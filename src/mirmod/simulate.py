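"""Synthetic three-cohort miRNA expression generator with planted modules.

Emulates the study design the pipeline targets: a disease (reference) cohort,
a technical replicate of the same samples, and a smaller normal cohort, over
a few hundred miRNA features organised into block-correlated co-expression
modules.  A chosen subset of modules loses its co-expression structure in the
normal cohort (so they appear "activated" in disease), and a chosen subset of
features carries a differential-expression mean shift in the disease groups.

The generative model per module m with within-module correlation rho_m is a
one-factor Gaussian model

    x_ij = sqrt(rho_m) * f_mj + sqrt(1 - rho_m) * eps_ij

with f_mj a per-sample standard-normal factor shared by the module's members
and eps independent standard normal, so every within-module pair has
correlation exactly rho_m in expectation.  The replicate cohort reuses the
reference cohort's values plus additive technical noise (same samples); the
normal cohort draws fresh samples, and disrupted modules there give each
feature its own private factor, which destroys the block correlation without
changing marginal variances.  Differential expression is an additive mean
shift on the log-intensity scale applied in the disease groups only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
import json

import numpy as np
import pandas as pd
import yaml

from .containers import ExpressionMatrix, ModulePartition

__all__ = ["SyntheticDesign", "generate_cohorts", "truth_table",
           "default_design"]


@dataclass
class SyntheticDesign:
    """Parameters of the three-cohort generator.

    Parameters
    ----------
    n_features : total feature count; features beyond ``sum(module_sizes)``
        are unassigned independent noise.
    module_sizes : member count per planted module (labels 1..K in order).
    rho_within : within-module pairwise correlation, one value per module
        or a single value recycled for all; each in [0, 1).
    n_ref, n_rep, n_norm : sample counts of the disease, replicate and
        normal cohorts (the replicate shares the disease samples).
    disrupted_in_norm : labels of modules whose co-expression is destroyed
        in the normal cohort.
    de_features : feature id -> additive mean shift (log-units) applied in
        the disease (ref and rep) groups only.
    rep_noise_sd : sd of the additive technical noise of the replicate.
    seed : RNG seed; identical design + seed reproduces bit-identical data.
    """

    n_features: int
    module_sizes: list[int]
    rho_within: list[float] | float
    n_ref: int = 90
    n_rep: int = 90
    n_norm: int = 34
    disrupted_in_norm: set[int] = field(default_factory=set)
    de_features: dict[str, float] = field(default_factory=dict)
    rep_noise_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if np.isscalar(self.rho_within):
            self.rho_within = [float(self.rho_within)] * len(self.module_sizes)
        self.rho_within = [float(r) for r in self.rho_within]
        self.disrupted_in_norm = set(int(m) for m in self.disrupted_in_norm)
        self.validate()

    def validate(self) -> None:
        if sum(self.module_sizes) > self.n_features:
            raise ValueError(
                "sum(module_sizes) exceeds n_features: "
                f"{sum(self.module_sizes)} > {self.n_features}")
        if any(s < 1 for s in self.module_sizes):
            raise ValueError("all module sizes must be >= 1")
        if len(self.rho_within) != len(self.module_sizes):
            raise ValueError("rho_within length must match module_sizes")
        if any(not (0.0 <= r <= 1.0) for r in self.rho_within):
            # rho = 1 is the degenerate shared-vector limit, kept for tests
            raise ValueError("all rho_within must lie in [0, 1]")
        if min(self.n_ref, self.n_rep, self.n_norm) < 1:
            raise ValueError("sample counts must be positive")
        if self.n_rep != self.n_ref:
            raise ValueError(
                "replicate cohort re-measures the reference samples; "
                "n_rep must equal n_ref")
        if self.rep_noise_sd < 0:
            raise ValueError("rep_noise_sd must be nonnegative")
        bad = set(self.disrupted_in_norm) - set(
            range(1, len(self.module_sizes) + 1))
        if bad:
            raise ValueError(f"disrupted_in_norm has unknown module labels: "
                             f"{sorted(bad)}")
        unknown_de = [f for f in self.de_features
                      if f not in set(self.feature_ids())]
        if unknown_de:
            raise ValueError(f"de_features not in feature universe: "
                             f"{unknown_de[:5]}")

    def feature_ids(self) -> list[str]:
        return [f"miR-{i + 1:04d}" for i in range(self.n_features)]

    def labels(self) -> pd.Series:
        """Planted module label per feature (0 = unassigned)."""
        lab = np.zeros(self.n_features, dtype=int)
        pos = 0
        for m, size in enumerate(self.module_sizes, start=1):
            lab[pos:pos + size] = m
            pos += size
        return pd.Series(lab, index=self.feature_ids())

    # -- config I/O ------------------------------------------------------
    @classmethod
    def from_file(cls, path) -> "SyntheticDesign":
        """Load a design from a YAML or JSON document."""
        with open(path) as fh:
            doc = yaml.safe_load(fh)
        return cls.from_dict(doc)

    @classmethod
    def from_dict(cls, doc: dict) -> "SyntheticDesign":
        doc = dict(doc)
        doc["disrupted_in_norm"] = set(doc.get("disrupted_in_norm", []))
        doc["de_features"] = dict(doc.get("de_features", {}))
        return cls(**doc)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["disrupted_in_norm"] = sorted(self.disrupted_in_norm)
        return d

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2)


def default_design(seed: int = 0) -> SyntheticDesign:
    """Study-scale default: 300 features in 10 modules (sizes 5-40,
    rho 0.7), three modules disrupted in the normal cohort, ten
    differentially expressed members of the smallest disrupted module plus
    scattered DE features, cohort sizes 90/90/34."""
    module_sizes = [40, 35, 30, 25, 22, 20, 15, 12, 8, 5]
    design = SyntheticDesign(
        n_features=300,
        module_sizes=module_sizes,
        rho_within=0.7,
        n_ref=90,
        n_rep=90,
        n_norm=34,
        disrupted_in_norm={8, 9, 10},
        rep_noise_sd=0.3,
        seed=seed,
    )
    # DE features: all members of the disrupted modules 9 and 10 are shifted
    # up in disease (an "activated, up-regulated" module), plus the first two
    # members of preserved modules 1 and 2 as scattered single-marker DE.
    labels = design.labels()
    de: dict[str, float] = {}
    for m, shift in ((9, 1.2), (10, 1.5)):
        for f in labels.index[labels == m]:
            de[f] = shift
    for m in (1, 2):
        for f in list(labels.index[labels == m])[:2]:
            de[f] = 1.0
    design.de_features = de
    return design


def generate_cohorts(
    design: SyntheticDesign,
) -> tuple[ExpressionMatrix, ExpressionMatrix, ExpressionMatrix,
           ModulePartition]:
    """Draw the three cohorts and the ground-truth partition.

    Returns ``(ref, rep, norm, truth)``.  ``rep`` shares ``ref``'s samples
    (same latent factors) and differs only by additive technical noise;
    ``norm`` has fresh samples and disrupted modules there have their factor
    resampled independently per feature (block correlation destroyed).
    """
    design.validate()
    rng = np.random.default_rng(design.seed)
    labels = design.labels()
    p, n_ref, n_norm = design.n_features, design.n_ref, design.n_norm

    def draw_group(n_samples: int, disrupted: set[int]) -> np.ndarray:
        x = np.empty((p, n_samples))
        for m, (size, rho) in enumerate(
                zip(design.module_sizes, design.rho_within), start=1):
            idx = np.flatnonzero(labels.to_numpy() == m)
            eps = rng.standard_normal((size, n_samples))
            if m in disrupted:
                # private factor per feature: marginals unchanged, block
                # correlation gone
                f = rng.standard_normal((size, n_samples))
                x[idx] = np.sqrt(rho) * f + np.sqrt(1 - rho) * eps
            else:
                f = rng.standard_normal(n_samples)
                x[idx] = np.sqrt(rho) * f[None, :] + np.sqrt(1 - rho) * eps
        free = np.flatnonzero(labels.to_numpy() == 0)
        x[free] = rng.standard_normal((free.size, n_samples))
        return x

    x_ref = draw_group(n_ref, disrupted=set())
    x_rep = x_ref + design.rep_noise_sd * rng.standard_normal(x_ref.shape)
    x_norm = draw_group(n_norm, disrupted=design.disrupted_in_norm)

    # DE mean shift in the disease groups only
    fid = {f: i for i, f in enumerate(labels.index)}
    for f, shift in design.de_features.items():
        x_ref[fid[f]] += shift
        x_rep[fid[f]] += shift

    features = design.feature_ids()
    ref_samples = [f"GC_{j + 1:03d}" for j in range(n_ref)]
    rep_samples = [f"Rep_{j + 1:03d}" for j in range(n_ref)]
    norm_samples = [f"Norm_{j + 1:03d}" for j in range(n_norm)]

    ref = ExpressionMatrix(pd.DataFrame(x_ref, index=features,
                                        columns=ref_samples))
    rep = ExpressionMatrix(pd.DataFrame(x_rep, index=features,
                                        columns=rep_samples))
    norm = ExpressionMatrix(pd.DataFrame(x_norm, index=features,
                                         columns=norm_samples))
    truth = ModulePartition(labels)
    return ref, rep, norm, truth


def truth_table(design: SyntheticDesign) -> pd.DataFrame:
    """One row per feature: (feature, module, is_de, module_disrupted_in_norm)."""
    design.validate()
    labels = design.labels()
    return pd.DataFrame({
        "feature": labels.index,
        "module": labels.to_numpy(),
        "is_de": [f in design.de_features for f in labels.index],
        "module_disrupted_in_norm": [
            int(l) in design.disrupted_in_norm for l in labels.to_numpy()],
    })
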