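"""scikit-learn-style estimators wrapping the permutation tests.

These are fit-only estimators in the spirit of ``sklearn.covariance``:
``fit(X, y)`` takes the samples-by-variables matrix X and the per-sample
condition labels y, runs the full analysis, and exposes the results as
fitted attributes with a trailing underscore.  ``get_params``/``set_params``
and ``clone`` work as usual, so the estimators compose with sklearn model
selection utilities.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .centrality import MEASURES
from .data import AssociationConfig, GroupedData
from .inference import (
    FEATURES,
    bh_adjust,
    permutation_test,
    theta_centrality_vector,
    theta_pdfg,
    theta_per_node,
)
from .network import networks_from_grouped_data


class _BaseNetworkTest(BaseEstimator):
    def _validate(self, X, y) -> GroupedData:
        if isinstance(X, pd.DataFrame):
            self.feature_names_in_ = np.asarray(X.columns, dtype=object)
            names = [str(c) for c in X.columns]
            values = X.to_numpy(dtype=float)
        else:
            values = np.asarray(X, dtype=float)
            if values.ndim != 2:
                raise ValueError("X must be a 2-d samples-by-variables matrix")
            names = [f"v{i}" for i in range(values.shape[1])]
        y = np.asarray(y)
        if y.shape != (values.shape[0],):
            raise ValueError("y must hold one condition label per row of X")
        self.n_features_in_ = values.shape[1]
        return GroupedData.from_arrays(values, y, variable_names=names)

    def _config(self) -> AssociationConfig:
        return AssociationConfig(
            method=self.method,
            scale=self.scale,
            threshold=self.threshold,
            weighted=self.weighted,
            strict_threshold=self.strict_threshold,
        )


class NetworkDifferenceTest(_BaseNetworkTest):
    """Permutation test for a difference among per-condition networks.

    Builds one correlation network per condition from (X, y), summarizes each
    network by its spectral density ("pdfg") or by a centrality vector, and
    tests H0: theta = 0 where theta is the mean distance of each group's
    summary from the cross-group mean.

    Parameters
    ----------
    method, scale, threshold, weighted, strict_threshold
        Network construction options (see :class:`AssociationConfig`).
    feature : {"pdfg", "degree", "eigenvector", "closeness", "betweenness",
        "clustering", "edge_betweenness"}
    bandwidth_rule : {"sturges", "silverman"}
        Kernel bandwidth criterion for the spectral density.
    n_permutations : int
        Number of label permutations B.
    random_state : int or None
        Seed for the permutation stream.

    Attributes
    ----------
    theta_ : float
        Observed statistic.
    p_value_ : float
        Permutation p-value, (1 + #{theta* >= theta_}) / (1 + B).
    per_group_distance_ : ndarray of shape (r,)
        Distance D_i of each group's summary from the mean summary.
    null_distribution_ : ndarray of shape (B,)
    networks_ : list of CorrelationNetwork
    groups_ : list of str

    Examples
    --------
    >>> import numpy as np
    >>> rng = np.random.default_rng(0)
    >>> X = rng.normal(size=(40, 6))
    >>> y = np.repeat(["a", "b"], 20)
    >>> test = NetworkDifferenceTest(feature="degree", n_permutations=99,
    ...                              random_state=0).fit(X, y)
    >>> bool(test.p_value_ > 0.05)
    True
    """

    def __init__(
        self,
        method: str = "spearman",
        scale: str = "abs_corr",
        threshold: float = 0.0,
        weighted: bool = True,
        strict_threshold: bool = True,
        feature: str = "pdfg",
        bandwidth_rule: str = "sturges",
        n_permutations: int = 1000,
        random_state: int | None = None,
    ):
        self.method = method
        self.scale = scale
        self.threshold = threshold
        self.weighted = weighted
        self.strict_threshold = strict_threshold
        self.feature = feature
        self.bandwidth_rule = bandwidth_rule
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        if self.feature not in FEATURES:
            raise ValueError(f"feature must be one of {FEATURES}")
        data = self._validate(X, y)
        config = self._config()
        res = permutation_test(
            data,
            config=config,
            feature=self.feature,
            level="set",
            bandwidth_rule=self.bandwidth_rule,
            n_perm=self.n_permutations,
            seed=self.random_state,
        )
        self.networks_ = networks_from_grouped_data(data, config)
        if self.feature == "pdfg":
            _, D = theta_pdfg(self.networks_, self.bandwidth_rule)
        else:
            _, D = theta_centrality_vector(self.networks_, self.feature)
        self.groups_ = list(data.groups)
        self.theta_ = res.theta
        self.p_value_ = res.p_value
        self.per_group_distance_ = D
        self.null_distribution_ = res.null
        return self


class NodeDifferenceTest(_BaseNetworkTest):
    """Per-node (or per-edge) permutation test of centrality differences.

    For every node j (or edge, for ``measure="edge_betweenness"``), tests
    whether its centrality differs across the condition networks using
    theta_j = mean_i |C_i^j - M^j|.  One shared batch of permutations feeds
    every item's null sample; q-values are BH-adjusted across items.

    Attributes
    ----------
    names_ : list of str — node (or edge) identifiers.
    theta_ : ndarray — per-item statistic.
    p_values_, q_values_ : ndarray
    centrality_by_group_ : DataFrame, one centrality column per group.
    """

    def __init__(
        self,
        method: str = "spearman",
        scale: str = "abs_corr",
        threshold: float = 0.0,
        weighted: bool = True,
        strict_threshold: bool = True,
        measure: str = "degree",
        n_permutations: int = 1000,
        random_state: int | None = None,
    ):
        self.method = method
        self.scale = scale
        self.threshold = threshold
        self.weighted = weighted
        self.strict_threshold = strict_threshold
        self.measure = measure
        self.n_permutations = n_permutations
        self.random_state = random_state

    def fit(self, X, y):
        if self.measure not in MEASURES:
            raise ValueError(f"measure must be one of {MEASURES}")
        data = self._validate(X, y)
        config = self._config()
        res = permutation_test(
            data,
            config=config,
            feature=self.measure,
            level="node",
            n_perm=self.n_permutations,
            seed=self.random_state,
        )
        self.networks_ = networks_from_grouped_data(data, config)
        theta, names, C = theta_per_node(self.networks_, self.measure)
        self.groups_ = list(data.groups)
        self.names_ = names
        self.theta_ = theta
        self.p_values_ = np.asarray(res.p_value)
        self.q_values_ = bh_adjust(self.p_values_)
        self.null_distribution_ = res.null
        self.centrality_by_group_ = pd.DataFrame(
            C.T, index=names, columns=self.groups_
        )
        return self

    def results_(self) -> pd.DataFrame:
        """Result table sorted by descending theta (Table-style layout)."""
        table = pd.DataFrame(
            {
                "name": self.names_,
                "n_groups": len(self.groups_),
                "measure": self.measure,
                "theta": self.theta_,
                "p_value": self.p_values_,
                "q_value": self.q_values_,
            }
        )
        for g in self.groups_:
            table[f"centrality_{g}"] = self.centrality_by_group_[g].to_numpy()
        return (
            table.sort_values("theta", ascending=False, kind="mergesort")
            .reset_index(drop=True)
        )
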