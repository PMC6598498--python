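"""Core data containers: grouped sample tables and correlation networks.

A study consists of one samples-by-variables table whose rows are partitioned
into r >= 2 condition groups (states).  Every downstream comparison builds one
undirected, weighted correlation network per group over the *same* ordered set
of variables, so the column order of the table is the canonical node order.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

CORRELATION_METHODS = ("pearson", "spearman", "kendall")
ASSOCIATION_SCALES = ("abs_corr", "one_minus_p", "one_minus_q")


@dataclass(frozen=True)
class AssociationConfig:
    """How pairwise association is measured and mapped to edge weights.

    Parameters
    ----------
    method : {"pearson", "spearman", "kendall"}
        Correlation coefficient used to measure monotone association.
    scale : {"abs_corr", "one_minus_p", "one_minus_q"}
        Mapping of the correlation result to a weight in [0, 1]: the absolute
        coefficient, one minus the p-value of the independence test, or one
        minus the Benjamini-Hochberg adjusted p-value.
    threshold : float in [0, 1]
        Weights at or below (strict mode) the threshold are removed.
    weighted : bool
        If False, surviving edges get weight 1 (binary network).
    strict_threshold : bool
        If True (default) keep edges with weight strictly greater than the
        threshold; if False keep weight >= threshold (zero-weight pairs are
        never edges in either mode).
    """

    method: str = "spearman"
    scale: str = "abs_corr"
    threshold: float = 0.0
    weighted: bool = True
    strict_threshold: bool = True

    def __post_init__(self) -> None:
        if self.method not in CORRELATION_METHODS:
            raise ValueError(
                f"method must be one of {CORRELATION_METHODS}, got {self.method!r}"
            )
        if self.scale not in ASSOCIATION_SCALES:
            raise ValueError(
                f"scale must be one of {ASSOCIATION_SCALES}, got {self.scale!r}"
            )
        if not (0.0 <= float(self.threshold) <= 1.0):
            raise ValueError(f"threshold must lie in [0, 1], got {self.threshold}")


@dataclass
class GroupedData:
    """A samples-by-variables matrix partitioned into condition groups.

    Attributes
    ----------
    values : ndarray, shape (n_samples, n_variables)
    variable_names : list of str, unique, in canonical (column) order.
    group_labels : ndarray of str, one label per row.
    groups : list of str, the distinct labels in fixed order.
    """

    values: np.ndarray
    variable_names: list[str]
    group_labels: np.ndarray
    groups: list[str] = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-d samples-by-variables matrix")
        self.variable_names = [str(v) for v in self.variable_names]
        if len(self.variable_names) != self.values.shape[1]:
            raise ValueError("variable_names length must match number of columns")
        if len(set(self.variable_names)) != len(self.variable_names):
            dupes = sorted(
                {v for v in self.variable_names if self.variable_names.count(v) > 1}
            )
            raise ValueError(f"duplicated variable names: {dupes}")
        self.group_labels = np.asarray([str(g) for g in self.group_labels])
        if self.group_labels.shape != (self.values.shape[0],):
            raise ValueError("group_labels must supply exactly one label per sample")
        if self.groups is None:
            # fixed order: first appearance in the table
            seen: dict[str, None] = {}
            for g in self.group_labels:
                seen.setdefault(g, None)
            self.groups = list(seen)
        else:
            self.groups = [str(g) for g in self.groups]
            if set(self.groups) != set(np.unique(self.group_labels)):
                raise ValueError("groups must be exactly the distinct labels")
        if len(self.groups) < 2:
            raise ValueError("at least two condition groups are required")
        for g, size in zip(self.groups, self.group_sizes):
            if size < 3:
                raise ValueError(
                    f"group {g!r} has {size} samples; correlation needs >= 3"
                )

    # -- constructors -----------------------------------------------------

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str) -> "GroupedData":
        """Build from a DataFrame with one categorical label column."""
        if label_column not in df.columns:
            raise ValueError(
                f"label column {label_column!r} not found; available columns: "
                f"{list(df.columns)}"
            )
        labels = df[label_column].astype(str).to_numpy()
        data = df.drop(columns=[label_column])
        bad = [c for c in data.columns if not np.issubdtype(data[c].dtype, np.number)]
        if bad:
            raise ValueError(
                f"non-numeric variable columns (and not the label column): {bad}"
            )
        return cls(
            values=data.to_numpy(dtype=float),
            variable_names=[str(c) for c in data.columns],
            group_labels=labels,
        )

    @classmethod
    def from_arrays(cls, values, labels, variable_names=None) -> "GroupedData":
        values = np.asarray(values, dtype=float)
        if variable_names is None:
            variable_names = [f"v{i}" for i in range(values.shape[1])]
        return cls(values=values, variable_names=list(variable_names), group_labels=labels)

    # -- accessors ---------------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def group_sizes(self) -> list[int]:
        return [int(np.sum(self.group_labels == g)) for g in self.groups]

    def group_values(self, group: str) -> np.ndarray:
        """Rows of one condition group, in table order."""
        mask = self.group_labels == str(group)
        if not mask.any():
            raise KeyError(f"unknown group {group!r}")
        return self.values[mask]

    def group_codes(self) -> np.ndarray:
        """Integer code per sample: index of its group in ``self.groups``."""
        index = {g: i for i, g in enumerate(self.groups)}
        return np.asarray([index[g] for g in self.group_labels], dtype=int)

    def subset(self, variables) -> "GroupedData":
        """Restrict to a subset of variables (order as given)."""
        variables = [str(v) for v in variables]
        index = {v: i for i, v in enumerate(self.variable_names)}
        missing = [v for v in variables if v not in index]
        if missing:
            raise KeyError(f"unknown variables: {missing}")
        cols = [index[v] for v in variables]
        return GroupedData(
            values=self.values[:, cols],
            variable_names=variables,
            group_labels=self.group_labels,
            groups=list(self.groups),
        )


@dataclass
class CorrelationNetwork:
    """Undirected weighted network over a fixed, ordered node set.

    The adjacency matrix is symmetric with zero diagonal and entries in
    [0, 1]; in unweighted mode every entry is 0 or 1.
    """

    adjacency: np.ndarray
    node_names: list[str]
    group_label: str = ""

    def __post_init__(self) -> None:
        A = np.asarray(self.adjacency, dtype=float)
        if A.ndim != 2 or A.shape[0] != A.shape[1]:
            raise ValueError("adjacency must be square")
        if not np.allclose(A, A.T, atol=1e-12):
            raise ValueError("adjacency must be symmetric")
        A = (A + A.T) / 2.0  # enforce exact symmetry
        np.fill_diagonal(A, 0.0)
        if A.min() < -1e-12 or A.max() > 1 + 1e-12:
            raise ValueError("adjacency entries must lie in [0, 1]")
        self.adjacency = np.clip(A, 0.0, 1.0)
        self.node_names = [str(v) for v in self.node_names]
        if len(self.node_names) != A.shape[0]:
            raise ValueError("node_names length must match adjacency size")

    @property
    def n_nodes(self) -> int:
        return self.adjacency.shape[0]

    def edges(self) -> list[tuple[int, int]]:
        """Index pairs (i < j) of present edges."""
        iu, ju = np.triu_indices(self.n_nodes, k=1)
        keep = self.adjacency[iu, ju] > 0
        return list(zip(iu[keep].tolist(), ju[keep].tolist()))
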