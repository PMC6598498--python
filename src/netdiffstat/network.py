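"""Correlation-network construction.

One network per condition group: pairwise monotone association between
variables (Pearson, Spearman or Kendall), mapped onto a [0, 1] association
scale (|r|, 1 - p, or 1 - BH-adjusted p), thresholded, and optionally
binarized.  Constant variables (zero variance) have undefined correlations;
by convention their off-diagonal correlations are set to 0 with p-value 1 and
a warning is logged, which keeps the node set identical across groups.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .data import (
    ASSOCIATION_SCALES,
    CORRELATION_METHODS,
    AssociationConfig,
    CorrelationNetwork,
    GroupedData,
)

logger = logging.getLogger(__name__)

_MIN_COMPLETE_PAIRS = 3


def compute_correlation(values, method: str = "pearson"):
    """Pairwise correlation and two-sided p-value matrices.

    Parameters
    ----------
    values : array-like, shape (n_samples, n_variables)
        Rows with missing values are dropped pairwise; a pair with fewer than
        3 complete observations, or a constant variable, gets correlation 0
        and p-value 1 (warning logged).
    method : {"pearson", "spearman", "kendall"}

    Returns
    -------
    corr, pvals : ndarray, shape (n_variables, n_variables)
        Symmetric; diagonal correlation 1 and diagonal p-value 0 by
        convention.  Spearman p-values use the t approximation; Kendall is
        tau-b with scipy's exact/asymptotic handling.
    """
    X = np.asarray(values, dtype=float)
    if X.ndim != 2:
        raise ValueError("values must be 2-d (samples x variables)")
    n, p = X.shape
    if n < 3:
        raise ValueError("at least 3 samples are required")
    if p < 2:
        raise ValueError("at least 2 variables are required")
    if method not in CORRELATION_METHODS:
        raise ValueError(f"unknown correlation method {method!r}")

    if method == "kendall" or np.isnan(X).any():
        corr, pvals = _pairwise_correlation(X, method)
    else:
        Xw = stats.rankdata(X, axis=0) if method == "spearman" else X
        corr, pvals = _moment_correlation(Xw)

    np.fill_diagonal(corr, 1.0)
    np.fill_diagonal(pvals, 0.0)
    return corr, pvals


def _moment_correlation(X: np.ndarray):
    """Vectorized product-moment correlation with t-based two-sided p-values."""
    n = X.shape[0]
    sd = X.std(axis=0)
    const = ~(sd > 0)
    if const.any():
        names = np.where(const)[0].tolist()
        logger.warning(
            "constant variables at column indices %s: correlations set to 0, "
            "p-values to 1",
            names,
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        R = np.corrcoef(X, rowvar=False)
    bad = const[:, None] | const[None, :]
    R = np.where(bad, 0.0, R)
    R = np.clip(np.nan_to_num(R, nan=0.0), -1.0, 1.0)

    df = n - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        t2 = R * R * df / (1.0 - R * R)  # inf at |R| == 1
    t2 = np.where(np.isnan(t2), np.inf, t2)
    P = 2.0 * special.stdtr(df, -np.sqrt(t2))
    P = np.where(bad, 1.0, P)
    return R, np.clip(P, 0.0, 1.0)


def _pairwise_correlation(X: np.ndarray, method: str):
    """Pair-by-pair path: Kendall, and any method with missing values."""
    n, p = X.shape
    corr = np.zeros((p, p))
    pvals = np.ones((p, p))
    degenerate: list[tuple[int, int]] = []
    for i in range(p):
        for j in range(i + 1, p):
            mask = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
            x, y = X[mask, i], X[mask, j]
            if (
                mask.sum() < _MIN_COMPLETE_PAIRS
                or np.ptp(x) == 0
                or np.ptp(y) == 0
            ):
                degenerate.append((i, j))
                r, pv = 0.0, 1.0
            elif method == "pearson":
                r, pv = stats.pearsonr(x, y)
            elif method == "spearman":
                r, pv = stats.spearmanr(x, y)
            else:
                r, pv = stats.kendalltau(x, y)
            if not np.isfinite(r):
                r, pv = 0.0, 1.0
            corr[i, j] = corr[j, i] = float(np.clip(r, -1.0, 1.0))
            pvals[i, j] = pvals[j, i] = float(np.clip(pv, 0.0, 1.0))
    if degenerate:
        logger.warning(
            "%d variable pairs with a constant column or fewer than %d complete "
            "observations: correlation set to 0, p-value to 1",
            len(degenerate),
            _MIN_COMPLETE_PAIRS,
        )
    return corr, pvals


def association_matrix(corr, pvals, scale: str = "abs_corr") -> np.ndarray:
    """Map correlations/p-values to a symmetric weight matrix in [0, 1].

    For ``one_minus_q`` the Benjamini-Hochberg adjustment is applied over the
    n(n-1)/2 upper-triangle p-values only.  The diagonal is forced to zero.
    """
    corr = np.asarray(corr, dtype=float)
    pvals = np.asarray(pvals, dtype=float)
    if corr.shape != pvals.shape or corr.ndim != 2 or corr.shape[0] != corr.shape[1]:
        raise ValueError("corr and pvals must be conformable square matrices")
    if scale not in ASSOCIATION_SCALES:
        raise ValueError(f"unknown association scale {scale!r}")

    if scale == "abs_corr":
        W = np.abs(corr)
    elif scale == "one_minus_p":
        W = 1.0 - pvals
    else:  # one_minus_q
        n = corr.shape[0]
        iu = np.triu_indices(n, k=1)
        q = multipletests(pvals[iu], method="fdr_bh")[1] if iu[0].size else np.array([])
        W = np.zeros_like(corr)
        W[iu] = 1.0 - q
        W = W + W.T
    W = (W + W.T) / 2.0
    np.fill_diagonal(W, 0.0)
    return np.clip(W, 0.0, 1.0)


def build_network(
    weights,
    config: AssociationConfig,
    group_label: str = "",
    node_names=None,
) -> CorrelationNetwork:
    """Threshold a weight matrix into a correlation network.

    Default semantics keep edges with weight strictly greater than the
    threshold; with ``strict_threshold=False``, weight >= threshold (but never
    zero-weight pairs).  Unweighted mode binarizes surviving edges to 1.
    """
    W = np.asarray(weights, dtype=float)
    if node_names is None:
        node_names = [f"v{i}" for i in range(W.shape[0])]
    if config.strict_threshold:
        keep = W > config.threshold
    else:
        keep = (W >= config.threshold) & (W > 0)
    A = np.where(keep, W if config.weighted else 1.0, 0.0)
    return CorrelationNetwork(adjacency=A, node_names=node_names, group_label=group_label)


def networks_from_grouped_data(
    data: GroupedData, config: AssociationConfig
) -> list[CorrelationNetwork]:
    """One correlation network per condition group, shared node order."""
    networks = []
    for g in data.groups:
        corr, pvals = compute_correlation(data.group_values(g), config.method)
        W = association_matrix(corr, pvals, config.scale)
        networks.append(
            build_network(W, config, group_label=g, node_names=data.variable_names)
        )
    return networks
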