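"""Pooling trajectories and the co-regulation toy simulator.

A pooling trajectory correlates a target gene against the cumulative sum
of a gene set's expression as members are added in seeded random orders.
The toy simulator plants a shared regulator C driving a block of genes
positively (A_i = C + eps_i) and one gene negatively (B = -C + delta);
under Gaussian noise the expected correlation of B with the mean of k
pooled A genes has the closed form

    corr_k = -1 / sqrt((1 + sigma_a^2 / k) * (1 + sigma_b^2))

which serves as the analytic oracle for the empirical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, ExpressionMatrix, GeneSet

__all__ = [
    "PoolingTrajectory",
    "CoregSimConfig",
    "pooling_trajectory",
    "simulate_coregulation",
    "coregulation_expected_corr",
    "trajectory_summary",
]


@dataclass
class PoolingTrajectory:
    """Iterations x pool-size matrix of correlations plus the orderings used."""

    correlations: np.ndarray  # (n_iter, n_pool_sizes)
    orderings: list[list[str]]
    method: str = "spearman"

    @property
    def n_iter(self) -> int:
        return self.correlations.shape[0]

    @property
    def pool_sizes(self) -> np.ndarray:
        return np.arange(1, self.correlations.shape[1] + 1)

    def trend(self, frac: float = 0.5) -> pd.DataFrame:
        """Locally weighted regression of correlation on pool size."""
        from statsmodels.nonparametric.smoothers_lowess import lowess

        k = np.tile(self.pool_sizes, self.n_iter).astype(float)
        c = self.correlations.ravel()
        fitted = lowess(c, k, frac=frac, return_sorted=True)
        out = pd.DataFrame(fitted, columns=["pool_size", "trend"])
        return out.drop_duplicates("pool_size", ignore_index=True)

    def to_long_frame(self) -> pd.DataFrame:
        n_iter, n_k = self.correlations.shape
        return pd.DataFrame(
            {
                "iteration": np.repeat(np.arange(n_iter), n_k),
                "pool_size": np.tile(np.arange(1, n_k + 1), n_iter),
                "correlation": self.correlations.ravel(),
            }
        )


def _corr_columns(target: np.ndarray, cum: np.ndarray, method: str) -> np.ndarray:
    """Correlate target (n,) against each column of cum (n, k)."""
    if method == "spearman":
        t = stats.rankdata(target)
        C = stats.rankdata(cum, axis=0)
    else:
        t = target
        C = cum
    tc = t - t.mean()
    Cc = C - C.mean(axis=0, keepdims=True)
    denom = np.sqrt((tc**2).sum()) * np.sqrt((Cc**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        return (Cc.T @ tc) / denom


def pooling_trajectory(
    expr: ExpressionMatrix | pd.DataFrame,
    gene_set: GeneSet,
    target: str,
    n_orders: int = 100,
    seed: int = 0,
    method: str = "spearman",
) -> PoolingTrajectory:
    """Correlation of a target vs cumulatively pooled set expression.

    For each seeded random ordering of the set, the target is correlated
    against the cumulative per-sample pseudocount sum at every pool size.
    The final column is identical across orderings (full pool).
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    gene_set.require_in(df.index)
    if target in gene_set.members:
        raise ValueError("target is a member of the pooled set (self-pooling)")
    if n_orders < 1:
        raise ValueError("n_orders must be >= 1")
    rng = np.random.default_rng(seed)
    members = list(gene_set.members)
    X = df.loc[members].to_numpy(dtype=float)  # members x samples
    t = df.loc[target].to_numpy(dtype=float)
    k = len(members)
    corrs = np.empty((n_orders, k))
    orderings = []
    for i in range(n_orders):
        perm = rng.permutation(k)
        orderings.append([members[j] for j in perm])
        cum = np.cumsum(X[perm], axis=0).T  # samples x k
        corrs[i] = _corr_columns(t, cum, method)
    return PoolingTrajectory(correlations=corrs, orderings=orderings, method=method)


@dataclass
class CoregSimConfig:
    """Toy co-regulation model configuration (defaults are the standard run:
    40 regulated genes, 500 samples, 1,000 repetitions)."""

    n_genes: int = 40
    n_samples: int = 500
    n_reps: int = 1000
    noise_sd_a: float = 1.0
    noise_sd_b: float = 1.0
    seed: int = 0
    reorder_per_rep: bool = True

    def __post_init__(self) -> None:
        for name in ("n_genes", "n_samples", "n_reps"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        for name in ("noise_sd_a", "noise_sd_b"):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be non-negative")


def coregulation_expected_corr(
    k: np.ndarray | int, noise_sd_a: float, noise_sd_b: float
) -> np.ndarray:
    """Closed-form E[corr(B, sum of k pooled A genes)] under the toy model."""
    k = np.asarray(k, dtype=float)
    return -1.0 / np.sqrt((1.0 + noise_sd_a**2 / k) * (1.0 + noise_sd_b**2))


def simulate_coregulation(config: CoregSimConfig) -> PoolingTrajectory:
    """Simulate the co-regulation toy model and pool genes cumulatively.

    Per repetition: C ~ N(0,1) per sample, A_i = C + eps_i with
    eps ~ N(0, noise_sd_a^2), B = -C + delta with delta ~ N(0, noise_sd_b^2);
    B is correlated (Pearson) against the cumulative sum of A genes taken
    in a random order (fresh order per repetition by default).
    """
    rng = np.random.default_rng(config.seed)
    n, g = config.n_samples, config.n_genes
    corrs = np.empty((config.n_reps, g))
    order = rng.permutation(g)
    for rep in range(config.n_reps):
        C = rng.normal(0.0, 1.0, size=n)
        A = C[:, None] + rng.normal(0.0, config.noise_sd_a, size=(n, g))
        B = -C + rng.normal(0.0, config.noise_sd_b, size=n)
        if config.reorder_per_rep:
            order = rng.permutation(g)
        cum = np.cumsum(A[:, order], axis=1)
        if config.noise_sd_a == 0 and config.noise_sd_b == 0:
            corrs[rep] = -1.0  # B = -C and pooled A = k*C exactly
        else:
            corrs[rep] = _corr_columns(B, cum, method="pearson")
    return PoolingTrajectory(correlations=corrs, orderings=[], method="pearson")


def trajectory_summary(traj: PoolingTrajectory) -> pd.DataFrame:
    """Per-pool-size quantiles plus a monotonic-strengthening statistic.

    The monotonicity statistic is the Spearman correlation of the median
    absolute correlation against pool size; a constant trajectory yields
    0 with the ``degenerate`` flag set.
    """
    c = traj.correlations
    if c.shape[0] < 1:
        raise ValueError("trajectory has no iterations")
    med = np.median(c, axis=0)
    q25 = np.quantile(c, 0.25, axis=0)
    q75 = np.quantile(c, 0.75, axis=0)
    out = pd.DataFrame(
        {
            "pool_size": np.arange(1, c.shape[1] + 1),
            "median": med,
            "q25": q25,
            "q75": q75,
        }
    )
    abs_med = np.abs(med)
    if np.ptp(abs_med) == 0 or c.shape[1] < 2:
        out.attrs["monotonicity"] = 0.0
        out.attrs["degenerate"] = True
    else:
        rho, _ = stats.spearmanr(abs_med, np.arange(1, c.shape[1] + 1))
        out.attrs["monotonicity"] = float(rho)
        out.attrs["degenerate"] = False
    return out
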