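"""Monte-Carlo evaluation harness: type-I-error calibration and power.

A synthetic sample pool replaces real expression data: a multivariate normal
with block-diagonal correlation (blocks of variables sharing one within-block
correlation, independent across blocks), so that groups subsampled from the
pool share one dependence structure under the null hypothesis.

Under the alternative, one group has the sample order of a fraction gamma of
its variables independently permuted — marginals preserved, correlations to
all other variables destroyed.  Power is summarized by the AUC of a ROC
built from alternative-branch versus null-branch permutation p-values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve

from .data import AssociationConfig, GroupedData
from .inference import permutation_test

logger = logging.getLogger(__name__)

NOMINAL_LEVELS = (0.01, 0.05, 0.1)


@dataclass(frozen=True)
class SimulationConfig:
    """Design of one Monte-Carlo experiment.

    Defaults are the desk-scale study conditions: 30 variables in 5 blocks
    with within-block correlation 0.7, five groups of 60 samples drawn
    disjointly per run from a fixed pool of 600, 100 label permutations per
    test, and the degree-centrality feature with Pearson |r| weights on a
    fully weighted (threshold 0) network.
    """

    n_groups: int = 5
    samples_per_group: int = 60
    n_variables: int = 30
    n_blocks: int = 5
    within_block_corr: float = 0.7
    gamma: float = 0.0
    n_runs: int = 100
    n_perm: int = 100
    seed: int | None = None
    feature: str = "degree"
    method: str = "pearson"
    scale: str = "abs_corr"
    threshold: float = 0.0
    weighted: bool = True
    bandwidth_rule: str = "sturges"
    pool_size: int | None = None

    def __post_init__(self) -> None:
        if self.n_variables < 1:
            raise ValueError("n_variables must be positive")
        if self.n_groups < 2:
            raise ValueError("n_groups must be >= 2")
        if not (0.0 <= self.gamma <= 1.0):
            raise ValueError("gamma must lie in [0, 1]")
        if not (0.0 <= self.within_block_corr < 1.0):
            raise ValueError("within_block_corr must lie in [0, 1)")
        if self.samples_per_group < 3:
            raise ValueError("samples_per_group must be >= 3")

    @property
    def effective_pool_size(self) -> int:
        needed = self.n_groups * self.samples_per_group
        if self.pool_size is not None:
            if self.pool_size < max(needed, 2 * self.samples_per_group):
                raise ValueError("pool_size too small for the requested draws")
            return self.pool_size
        return max(600, 2 * needed)

    def association_config(self) -> AssociationConfig:
        return AssociationConfig(
            method=self.method,
            scale=self.scale,
            threshold=self.threshold,
            weighted=self.weighted,
        )


def population_correlation(config: SimulationConfig) -> np.ndarray:
    """Block-diagonal population correlation matrix."""
    sigma = np.eye(config.n_variables)
    blocks = np.array_split(np.arange(config.n_variables), config.n_blocks)
    for block in blocks:
        for a in block:
            for b in block:
                if a != b:
                    sigma[a, b] = config.within_block_corr
    return sigma


def generate_population(config: SimulationConfig, rng=None) -> np.ndarray:
    """Sample pool (pool_size x n_variables) with the block structure."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    L = np.linalg.cholesky(population_correlation(config))
    Z = rng.standard_normal((config.effective_pool_size, config.n_variables))
    return Z @ L.T


def make_alternative(group_values: np.ndarray, gamma: float, rng) -> np.ndarray:
    """Permute the sample order of round(gamma * n_variables) random columns.

    Marginal distributions are untouched; the permuted columns' correlations
    with every other variable are destroyed.
    """
    if not (0.0 <= gamma <= 1.0):
        raise ValueError("gamma must lie in [0, 1]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    out = np.array(group_values, dtype=float, copy=True)
    n, p = out.shape
    k = int(round(gamma * p))
    if k == 0:
        return out
    cols = rng.choice(p, size=k, replace=False)
    for c in cols:
        out[:, c] = out[rng.permutation(n), c]
    return out


def _test_p_value(groups: list[np.ndarray], config: SimulationConfig, seed: int) -> float:
    """Full set-level permutation test on a list of group sample matrices."""
    values = np.vstack(groups)
    labels = np.concatenate(
        [np.repeat(f"g{i}", g.shape[0]) for i, g in enumerate(groups)]
    )
    data = GroupedData.from_arrays(values, labels)
    res = permutation_test(
        data,
        config=config.association_config(),
        feature=config.feature,
        level="set",
        bandwidth_rule=config.bandwidth_rule,
        n_perm=config.n_perm,
        seed=seed,
    )
    return res.p_value


def _run_streams(config: SimulationConfig):
    """Per-run RNG streams: (draw, perturb, test-seed) kept separate so that
    group draws match across gamma values under one master seed."""
    root = np.random.SeedSequence(0 if config.seed is None else config.seed)
    pool_ss, runs_ss = root.spawn(2)
    pool = generate_population(config, rng=np.random.default_rng(pool_ss))
    streams = []
    for run_ss in runs_ss.spawn(config.n_runs):
        draw_ss, perturb_ss, test_ss = run_ss.spawn(3)
        streams.append(
            (
                np.random.default_rng(draw_ss),
                np.random.default_rng(perturb_ss),
                int(test_ss.generate_state(1)[0] & 0x7FFFFFFF),
            )
        )
    return pool, streams


def _draw_disjoint_groups(pool: np.ndarray, n_groups: int, size: int, rng) -> list[np.ndarray]:
    idx = rng.choice(pool.shape[0], size=n_groups * size, replace=False)
    return [pool[idx[i * size : (i + 1) * size]] for i in range(n_groups)]


@dataclass
class TypeOneErrorResult:
    """Null-simulation p-values and empirical rejection rates."""

    p_values: np.ndarray
    rejection_rates: dict[float, float]
    config: SimulationConfig


def type_one_error_experiment(config: SimulationConfig) -> TypeOneErrorResult:
    """Estimate false-positive rates under the null (gamma must be 0).

    Each run subsamples r disjoint groups from one pool and runs the full
    permutation test; the output is the empirical rejection proportion at the
    nominal levels 0.01, 0.05 and 0.1.
    """
    if config.gamma != 0.0:
        raise ValueError("type-I-error experiment requires gamma = 0")
    pool, streams = _run_streams(config)
    p_values = np.empty(config.n_runs)
    for k, (draw_rng, _perturb_rng, test_seed) in enumerate(streams):
        groups = _draw_disjoint_groups(
            pool, config.n_groups, config.samples_per_group, draw_rng
        )
        p_values[k] = _test_p_value(groups, config, test_seed)
    rates = {lvl: float(np.mean(p_values <= lvl)) for lvl in NOMINAL_LEVELS}
    return TypeOneErrorResult(p_values=p_values, rejection_rates=rates, config=config)


@dataclass
class PowerResult:
    """Alternative/null p-value samples with the ROC curve and its AUC."""

    p_alternative: np.ndarray
    p_null: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    config: SimulationConfig
    runs: "list[dict]" = field(default_factory=list)


def power_experiment(config: SimulationConfig) -> PowerResult:
    """Empirical power summarized as the AUC of an ROC curve.

    Per run: (a) the alternative branch compares all r groups with exactly
    one group perturbed at the configured gamma; (b) the null branch compares
    two of the unperturbed groups (for r = 2, where no two unperturbed groups
    exist within the comparison, two fresh unperturbed groups are drawn
    instead).  The ROC sweeps a p-value threshold over both branches' pooled
    p-values; AUC is the trapezoidal area.
    """
    if config.gamma <= 0.0:
        logger.warning("power experiment with gamma = 0: both branches are null")
    pool, streams = _run_streams(config)
    p_alt = np.empty(config.n_runs)
    p_null = np.empty(config.n_runs)
    runs = []
    for k, (draw_rng, perturb_rng, test_seed) in enumerate(streams):
        groups = _draw_disjoint_groups(
            pool, config.n_groups, config.samples_per_group, draw_rng
        )
        perturbed = make_alternative(groups[0], config.gamma, perturb_rng)
        p_alt[k] = _test_p_value([perturbed] + groups[1:], config, test_seed)
        if config.n_groups >= 3:
            null_groups = [groups[1], groups[2]]
        else:
            null_groups = _draw_disjoint_groups(
                pool, 2, config.samples_per_group, draw_rng
            )
        p_null[k] = _test_p_value(null_groups, config, test_seed + 1)
        runs.append({"run": k, "p_alternative": p_alt[k], "p_null": p_null[k]})

    y_true = np.concatenate([np.ones_like(p_alt), np.zeros_like(p_null)])
    score = -np.concatenate([p_alt, p_null])  # smaller p = stronger evidence
    fpr, tpr, _ = roc_curve(y_true, score, drop_intermediate=False)
    return PowerResult(
        p_alternative=p_alt,
        p_null=p_null,
        fpr=fpr,
        tpr=tpr,
        auc=float(_trapezoid_auc(fpr, tpr)),
        config=config,
        runs=runs,
    )
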