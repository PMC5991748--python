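"""Core data containers: expression matrices and module partitions.

An :class:`ExpressionMatrix` is a features x samples table of normalized,
log-scale expression values (rows = miRNA probes, columns = samples), the
standard orientation for microarray co-expression analysis.  A
:class:`ModulePartition` assigns each feature an integer module label, with
label 0 reserved for unassigned ("grey") features, mirroring the WGCNA
convention of naming modules by colors.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix", "ModulePartition", "MODULE_COLORS"]

# WGCNA's standard color sequence for module labels 1, 2, 3, ...
MODULE_COLORS = (
    "turquoise", "blue", "brown", "yellow", "green", "red", "black", "pink",
    "magenta", "purple", "greenyellow", "tan", "salmon", "cyan",
    "midnightblue", "lightcyan", "grey60", "lightgreen", "lightyellow",
    "royalblue", "darkred", "darkgreen", "darkturquoise", "darkgrey",
    "orange", "darkorange", "white", "skyblue", "saddlebrown", "steelblue",
    "paleturquoise", "violet", "darkolivegreen", "darkmagenta",
)


def color_for_label(label: int) -> str:
    """Color name for an integer module label (0 -> grey)."""
    if label == 0:
        return "grey"
    return MODULE_COLORS[(label - 1) % len(MODULE_COLORS)]


@dataclass
class ExpressionMatrix:
    """Features x samples expression table with unique ids on both axes."""

    data: pd.DataFrame  # index = feature ids, columns = sample ids

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        self.data.index = self.data.index.astype(str)
        self.data.columns = self.data.columns.astype(str)

    # -- basic accessors -------------------------------------------------
    @property
    def feature_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def n_features(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy(dtype=float)

    def validate(self, min_samples: int = 3, min_features: int = 3) -> None:
        """Raise ``ValueError`` on non-finite values, duplicate ids, or a
        table too small for network construction."""
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique()
            raise ValueError(f"duplicate feature ids: {list(dupes)[:5]}")
        if self.data.columns.has_duplicates:
            dupes = self.data.columns[self.data.columns.duplicated()].unique()
            raise ValueError(f"duplicate sample ids: {list(dupes)[:5]}")
        if not np.isfinite(self.values).all():
            bad = self.data.index[~np.isfinite(self.values).all(axis=1)]
            raise ValueError(f"non-finite values in features: {list(bad)[:5]}")
        if self.n_samples < min_samples:
            raise ValueError(
                f"need >= {min_samples} samples, got {self.n_samples}")
        if self.n_features < min_features:
            raise ValueError(
                f"need >= {min_features} features, got {self.n_features}")

    def subset(self, features) -> "ExpressionMatrix":
        missing = [f for f in features if f not in self.data.index]
        if missing:
            raise KeyError(f"features missing from matrix: {missing}")
        return ExpressionMatrix(self.data.loc[list(features)])

    # -- I/O -------------------------------------------------------------
    @classmethod
    def from_csv(cls, path) -> "ExpressionMatrix":
        """Read a CSV whose first column holds feature ids and whose header
        row holds sample ids."""
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.data.to_csv(path)


@dataclass
class ModulePartition:
    """Feature -> integer module label map (0 = unassigned / grey)."""

    labels: pd.Series  # index = feature ids, values = nonnegative ints
    colors: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels).astype(int)
        self.labels.index = self.labels.index.astype(str)
        if (self.labels < 0).any():
            raise ValueError("module labels must be nonnegative")
        if not self.colors:
            self.colors = {
                int(lab): color_for_label(int(lab))
                for lab in sorted(self.labels.unique())
            }

    @property
    def feature_ids(self) -> list[str]:
        return list(self.labels.index)

    @property
    def module_labels(self) -> list[int]:
        """Sorted nonzero module labels."""
        return sorted(int(l) for l in self.labels.unique() if l != 0)

    def members(self, label: int) -> list[str]:
        return list(self.labels.index[self.labels == label])

    def module_sizes(self) -> dict[int, int]:
        return {lab: int((self.labels == lab).sum())
                for lab in self.module_labels}

    @classmethod
    def from_csv(cls, path) -> "ModulePartition":
        df = pd.read_csv(path)
        labels = pd.Series(df["label"].to_numpy(),
                           index=df["feature"].astype(str))
        colors = {}
        if "color" in df.columns:
            colors = {int(l): c for l, c in zip(df["label"], df["color"])}
        return cls(labels, colors)

    def to_csv(self, path) -> None:
        pd.DataFrame({
            "feature": self.labels.index,
            "label": self.labels.to_numpy(),
            "color": [self.colors.get(int(l), color_for_label(int(l)))
                      for l in self.labels],
        }).to_csv(path, index=False)
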