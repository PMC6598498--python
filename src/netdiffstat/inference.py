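"""The theta statistics, permutation test, FDR control and group distances.

The test statistic theta is the average distance of each group's network
summary from the cross-group mean summary:

* spectral feature ("pdfg"): D_i = KL(rho_i || rho_M) between each group's
  spectral density and the mean density; theta = mean(D_i);
* whole-network centrality feature: D_i is the Euclidean distance between the
  group's centrality vector and the element-wise mean vector;
* per-node (or per-edge) analysis: theta_j = mean_i |C_i^j - M^j|.

Significance comes from a permutation null: group labels are reshuffled over
the pooled samples (group sizes fixed), all r networks are rebuilt from
scratch, and theta is recomputed.  H0: theta = 0 vs H1: theta > 0, with
p = (1 + #{theta* >= theta_hat}) / (1 + B).
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import linkage, to_tree
from scipy.spatial.distance import squareform
from statsmodels.stats.multitest import multipletests

from .centrality import EDGE_MEASURES, MEASURES, centrality_vector, edge_union
from .data import AssociationConfig, CorrelationNetwork, GroupedData
from .network import association_matrix, build_network, compute_correlation
from .spectral import (
    estimate_density,
    floor_density,
    graph_spectrum,
    js_divergence,
    shared_grid,
)

logger = logging.getLogger(__name__)

FEATURES = ("pdfg",) + MEASURES

DEFAULT_MIN_SET_SIZE = 10


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any(p <= 0) or np.any(p > 1):
        raise ValueError("p-values must lie in (0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# theta statistics
# ---------------------------------------------------------------------------


def theta_pdfg(networks, bandwidth_rule: str = "sturges"):
    """Spectral theta: mean KL divergence of each density from the mean density.

    Returns (theta, per_group_distance).  Densities are floored before
    averaging so the mean provably contains each group's support and the KL
    +inf branch cannot fire on quadrature round-off.
    """
    networks = list(networks)
    if len(networks) < 2:
        raise ValueError("at least two networks are required")
    spectra = [graph_spectrum(net) for net in networks]
    grid = shared_grid(spectra, bandwidth_rule)
    densities = [estimate_density(s, bandwidth_rule, grid=grid) for s in spectra]
    floored = np.array([floor_density(d) for d in densities])
    m = floored.mean(axis=0)
    # where every group's density coincides the mean is that value exactly;
    # overriding the float round-off keeps identical groups at theta = 0
    same = np.all(floored == floored[0], axis=0)
    m[same] = floored[0][same]
    D = []
    for pd_ in floored:
        # points where the density equals the mean contribute log(1) = 0;
        # masking them keeps identical groups at exactly zero divergence
        pos = (pd_ > 0) & (pd_ != m)
        integrand = np.zeros_like(pd_)
        integrand[pos] = pd_[pos] * np.log(pd_[pos] / m[pos])
        D.append(max(float(np.trapezoid(integrand, grid)), 0.0))
    D = np.asarray(D)
    return float(D.mean()), D


def _centrality_matrix(networks, measure: str) -> tuple[np.ndarray, list[str]]:
    """r x m matrix of centralities over a common node/edge universe."""
    universe = edge_union(networks) if measure in EDGE_MEASURES else None
    vectors = [centrality_vector(net, measure, edge_universe=universe) for net in networks]
    names = vectors[0].names
    return np.array([v.values for v in vectors]), names


def _mean_deviations(C: np.ndarray) -> np.ndarray:
    """C_i^j - M^j with columns of identical values set to exactly zero.

    The deviation of identical centralities from their own mean is
    identically zero; this strips the floating-point round-off of the mean so
    identical groups give theta = 0 exactly.
    """
    dev = C - C.mean(axis=0)
    dev[:, np.all(C == C[0], axis=0)] = 0.0
    return dev


def theta_centrality_vector(networks, measure: str = "degree"):
    """Whole-network theta: mean Euclidean distance from the mean vector.

    Returns (theta, per_group_distance).
    """
    networks = list(networks)
    if len(networks) < 2:
        raise ValueError("at least two networks are required")
    C, _ = _centrality_matrix(networks, measure)
    D = np.linalg.norm(_mean_deviations(C), axis=1)
    return float(D.mean()), D


def theta_per_node(networks, measure: str = "degree"):
    """Per-node/per-edge theta: theta_j = mean_i |C_i^j - M^j|.

    Returns (theta vector, item names, r x m centrality matrix).
    """
    networks = list(networks)
    if len(networks) < 2:
        raise ValueError("at least two networks are required")
    C, names = _centrality_matrix(networks, measure)
    theta = np.abs(_mean_deviations(C)).mean(axis=0)
    return theta, names, C


def make_set_statistic(feature: str = "pdfg", bandwidth_rule: str = "sturges"):
    """Callable mapping a list of networks to the scalar set-level theta."""
    if feature == "pdfg":
        return lambda nets: theta_pdfg(nets, bandwidth_rule)[0]
    if feature in MEASURES:
        return lambda nets: theta_centrality_vector(nets, feature)[0]
    raise ValueError(f"unknown feature {feature!r}; choose from {FEATURES}")


# ---------------------------------------------------------------------------
# permutation test
# ---------------------------------------------------------------------------


@dataclass
class PermutationResult:
    """Observed statistic, permutation p-value(s) and the null sample."""

    theta: float | np.ndarray
    p_value: float | np.ndarray
    null: np.ndarray
    n_permutations: int


def _networks_for_codes(
    values: np.ndarray,
    codes: np.ndarray,
    n_groups: int,
    node_names,
    config: AssociationConfig,
) -> list[CorrelationNetwork]:
    nets = []
    for gi in range(n_groups):
        corr, pvals = compute_correlation(values[codes == gi], config.method)
        W = association_matrix(corr, pvals, config.scale)
        nets.append(build_network(W, config, group_label=str(gi), node_names=node_names))
    return nets


def _distinct_permutations(codes: np.ndarray):
    """All distinct orderings of a multiset of group codes (recursive)."""
    counts = np.bincount(codes)
    n = codes.size
    current = np.empty(n, dtype=int)

    def rec(pos: int):
        if pos == n:
            yield current.copy()
            return
        for value in range(counts.size):
            if counts[value] > 0:
                counts[value] -= 1
                current[pos] = value
                yield from rec(pos + 1)
                counts[value] += 1

    yield from rec(0)


def permutation_test(
    data: GroupedData,
    config: AssociationConfig | None = None,
    feature: str = "pdfg",
    level: str = "set",
    bandwidth_rule: str = "sturges",
    variable_subset=None,
    n_perm: int = 1000,
    seed: int | None = None,
    exhaustive: bool = False,
) -> PermutationResult:
    """Permutation test of H0: theta = 0 against H1: theta > 0.

    Parameters
    ----------
    data : GroupedData
    config : AssociationConfig, default AssociationConfig()
    feature : network summary being compared ("pdfg" or a centrality measure).
    level : "set" for one scalar theta, "node" for per-node/per-edge thetas
        (feature must then be a centrality measure); node-level analyses share
        one set of permutations across all items.
    variable_subset : optional list of variable names to restrict to.
    n_perm : number B of label permutations (ignored when ``exhaustive``).
    seed : RNG seed; the test is deterministic given the seed.
    exhaustive : enumerate every distinct label assignment instead of
        sampling; p = #{theta* >= theta_hat} / N over all N assignments
        (the identity assignment is among them, so p >= 1/N).

    Returns
    -------
    PermutationResult with p = (1 + #{theta* >= theta_hat}) / (1 + B) in
    sampled mode.  Ties theta* = theta_hat count toward the numerator.
    """
    if config is None:
        config = AssociationConfig()
    if variable_subset is not None:
        data = data.subset(variable_subset)
    if not exhaustive and n_perm < 1:
        raise ValueError("n_perm must be >= 1")

    codes = data.group_codes()
    r = data.n_groups
    X = data.values
    names = data.variable_names

    observed = _networks_for_codes(X, codes, r, names, config)
    if level == "set":
        stat = make_set_statistic(feature, bandwidth_rule)
    elif level == "node":
        if feature not in MEASURES:
            raise ValueError(
                f"node-level analysis needs a centrality measure, got {feature!r}"
            )
        universe = edge_union(observed) if feature in EDGE_MEASURES else None

        def stat(nets):
            if universe is not None:
                C = np.array(
                    [
                        centrality_vector(n_, feature, edge_universe=universe).values
                        for n_ in nets
                    ]
                )
            else:
                C = np.array([centrality_vector(n_, feature).values for n_ in nets])
            return np.abs(_mean_deviations(C)).mean(axis=0)

    else:
        raise ValueError("level must be 'set' or 'node'")

    theta_obs = stat(observed)

    if exhaustive:
        null = np.array(
            [
                stat(_networks_for_codes(X, perm, r, names, config))
                for perm in _distinct_permutations(codes)
            ]
        )
        count = (null >= theta_obs).sum(axis=0)
        p = count / null.shape[0]
    else:
        rng = np.random.default_rng(seed)
        null = np.empty((n_perm,) + np.shape(theta_obs))
        for b in range(n_perm):
            null[b] = stat(_networks_for_codes(X, rng.permutation(codes), r, names, config))
        count = (null >= theta_obs).sum(axis=0)
        p = (1.0 + count) / (1.0 + n_perm)

    if np.ndim(theta_obs) == 0:
        return PermutationResult(float(theta_obs), float(p), null, null.shape[0])
    return PermutationResult(np.asarray(theta_obs), np.asarray(p), null, null.shape[0])


# ---------------------------------------------------------------------------
# set-level and node-level analyses
# ---------------------------------------------------------------------------


def _set_seed(master_seed: int | None, set_name: str) -> int:
    """Per-set seed independent of set iteration order."""
    base = 0 if master_seed is None else int(master_seed)
    ss = np.random.SeedSequence([base & 0x7FFFFFFF, zlib.crc32(set_name.encode())])
    return int(ss.generate_state(1)[0] & 0x7FFFFFFF)


def run_set_analysis(
    data: GroupedData,
    sets,
    config: AssociationConfig | None = None,
    feature: str = "pdfg",
    n_perm: int = 1000,
    seed: int | None = None,
    min_set_size: int = DEFAULT_MIN_SET_SIZE,
    bandwidth_rule: str = "sturges",
) -> pd.DataFrame:
    """Differential network analysis for every variable set in a collection.

    Each set is intersected with the available variables (data column order);
    sets smaller than ``min_set_size`` (or with fewer than 2 members) are
    skipped with a log entry.  q-values are BH-adjusted across analyzed sets.

    ``sets`` iterates over (name, description, members) triples — see
    ``io.VariableSetCollection``.
    """
    if config is None:
        config = AssociationConfig()
    entries = list(sets)
    if not entries:
        raise ValueError("empty variable-set collection")
    available = set(data.variable_names)
    floor = max(int(min_set_size), 2)

    rows = []
    for name, _description, members in entries:
        member_set = set(members)
        present = [v for v in data.variable_names if v in member_set]
        if len(present) < floor:
            logger.info(
                "skipping set %r: %d variables present (< %d)",
                name,
                len(present),
                floor,
            )
            continue
        res = permutation_test(
            data,
            config=config,
            feature=feature,
            level="set",
            bandwidth_rule=bandwidth_rule,
            variable_subset=present,
            n_perm=n_perm,
            seed=_set_seed(seed, str(name)),
        )
        nets = _networks_for_codes(
            data.subset(present).values,
            data.group_codes(),
            data.n_groups,
            present,
            config,
        )
        if feature == "pdfg":
            _, D = theta_pdfg(nets, bandwidth_rule)
        else:
            _, D = theta_centrality_vector(nets, feature)
        row = {
            "name": str(name),
            "n_groups": data.n_groups,
            "size": len(present),
            "theta": res.theta,
            "p_value": res.p_value,
        }
        for g, d in zip(data.groups, D):
            row[f"distance_{g}"] = d
        rows.append(row)

    columns = ["name", "n_groups", "size", "theta", "p_value", "q_value"] + [
        f"distance_{g}" for g in data.groups
    ]
    if not rows:
        return pd.DataFrame(columns=columns)
    table = pd.DataFrame(rows)
    table.insert(5, "q_value", bh_adjust(table["p_value"].to_numpy()))
    table = table[columns].sort_values("theta", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)


def run_node_analysis(
    data: GroupedData,
    config: AssociationConfig | None = None,
    measure: str = "degree",
    variable_subset=None,
    n_perm: int = 1000,
    seed: int | None = None,
) -> pd.DataFrame:
    """Differential node (or edge) analysis for one set of variables.

    One shared batch of permutations yields every item's null sample;
    q-values are BH-adjusted across the items of this analysis.
    """
    if config is None:
        config = AssociationConfig()
    res = permutation_test(
        data,
        config=config,
        feature=measure,
        level="node",
        variable_subset=variable_subset,
        n_perm=n_perm,
        seed=seed,
    )
    sub = data.subset(variable_subset) if variable_subset is not None else data
    nets = _networks_for_codes(
        sub.values, sub.group_codes(), sub.n_groups, sub.variable_names, config
    )
    theta, names, C = theta_per_node(nets, measure)
    table = pd.DataFrame(
        {
            "name": names,
            "n_groups": sub.n_groups,
            "measure": measure,
            "theta": res.theta,
            "p_value": res.p_value,
            "q_value": bh_adjust(np.asarray(res.p_value)),
        }
    )
    for gi, g in enumerate(sub.groups):
        table[f"centrality_{g}"] = C[gi]
    table = table.sort_values("theta", ascending=False, kind="mergesort")
    return table.reset_index(drop=True)


# ---------------------------------------------------------------------------
# pairwise group distances and dendrogram
# ---------------------------------------------------------------------------


def _tree_to_newick(node, labels) -> str:
    def rec(n, parent_dist: float) -> str:
        length = max(parent_dist - n.dist, 0.0)
        if n.is_leaf():
            return f"{labels[n.id]}:{length:.10g}"
        inner = f"({rec(n.left, n.dist)},{rec(n.right, n.dist)})"
        return f"{inner}:{length:.10g}"

    if node.is_leaf():
        return f"({labels[node.id]}:0);"
    return f"({rec(node.left, node.dist)},{rec(node.right, node.dist)});"


def pairwise_group_distances(
    networks,
    feature: str = "pdfg",
    bandwidth_rule: str = "sturges",
) -> tuple[pd.DataFrame, str]:
    """Pairwise distances between group networks plus an average-linkage tree.

    The spectral feature uses the Jensen-Shannon divergence between spectral
    densities on one common grid; centrality features use the Euclidean
    distance between centrality vectors.  Returns (distance matrix as a
    labeled DataFrame, newick string of the UPGMA dendrogram).
    """
    networks = list(networks)
    r = len(networks)
    if r < 2:
        raise ValueError("at least two networks are required")
    labels = [net.group_label or f"group{i}" for i, net in enumerate(networks)]

    D = np.zeros((r, r))
    if feature == "pdfg":
        spectra = [graph_spectrum(net) for net in networks]
        grid = shared_grid(spectra, bandwidth_rule)
        densities = [estimate_density(s, bandwidth_rule, grid=grid) for s in spectra]
        for i in range(r):
            for j in range(i + 1, r):
                D[i, j] = D[j, i] = js_divergence(densities[i], densities[j])
    elif feature in MEASURES:
        C, _ = _centrality_matrix(networks, feature)
        for i in range(r):
            for j in range(i + 1, r):
                D[i, j] = D[j, i] = float(np.linalg.norm(C[i] - C[j]))
    else:
        raise ValueError(f"unknown feature {feature!r}; choose from {FEATURES}")

    Z = linkage(squareform(D, checks=False), method="average")
    newick = _tree_to_newick(to_tree(Z), labels)
    frame = pd.DataFrame(D, index=labels, columns=labels)
    return frame, newick
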