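"""Relative reciprocal relationship scores.

A gene (or pooled gene set, inserted into the genome-wide distribution as
one extra pseudo-gene) is ranked by anticorrelation within the other
member's genome-wide correlation distribution; the score is the sum of
the two squared ranks, so weak reciprocity is penalised: ranks (1, 200)
score worse than ranks (10, 10).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import correlate_feature_vs_genes
from .datatypes import ExpressionMatrix, GeneSet
from .preprocess import pool_gene_set

__all__ = [
    "ReciprocalScore",
    "rank_percentile",
    "genomewide_rank",
    "relative_reciprocal_score",
    "reciprocal_top_fraction",
    "matched_pair_comparison",
    "score_vs_covariate",
]

POOLED_PSEUDOGENE = "__pooled__"


@dataclass
class ReciprocalScore:
    name_a: str
    name_b: str
    rank_a_in_b: int
    rank_b_in_a: int
    n_genes_a: int
    n_genes_b: int

    @property
    def percentile_a(self) -> float:
        return rank_percentile(self.rank_a_in_b, self.n_genes_b)

    @property
    def percentile_b(self) -> float:
        return rank_percentile(self.rank_b_in_a, self.n_genes_a)

    @property
    def score(self) -> int:
        return self.rank_a_in_b**2 + self.rank_b_in_a**2


def rank_percentile(rank: int, n: int) -> float:
    """Percentile position of a rank in a distribution of size n (100*rank/n)."""
    if not 1 <= rank <= n:
        raise ValueError(f"rank {rank} outside 1..{n}")
    return 100.0 * rank / n


def _distribution_for(
    query_vector: pd.Series,
    expr: ExpressionMatrix | pd.DataFrame,
    target_name: str,
    pooled: Optional[pd.Series],
    method: str,
    exclude_members: Optional[list[str]] = None,
) -> tuple[int, float, int]:
    """Rank of ``target_name`` in the query's genome-wide correlation
    distribution (ascending correlation, 1 = most anticorrelated)."""
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    if exclude_members:
        df = df.drop(index=[g for g in exclude_members if g in df.index])
    if pooled is not None:
        df = pd.concat([df, pooled.rename(POOLED_PSEUDOGENE).to_frame().T])
    res = correlate_feature_vs_genes(query_vector, df, method=method)
    if target_name not in res.table.index:
        raise KeyError(f"target {target_name!r} absent from the distribution")
    rank = int(res.table.loc[target_name, "rank"])
    n = len(res.table)
    return rank, rank_percentile(rank, n), n


def genomewide_rank(
    target: str | GeneSet,
    query: str,
    expr: ExpressionMatrix | pd.DataFrame,
    method: str = "spearman",
    exclude_members: bool = False,
) -> tuple[int, float, int]:
    """Rank of ``target`` within ``query``'s genome-wide anticorrelation
    distribution.

    When ``target`` is a gene set its pooled per-sample sum is inserted
    into the distribution as one additional pseudo-gene; constituent
    genes stay in the distribution unless ``exclude_members`` is set.
    Returns ``(rank, percentile, n)`` with rank 1 = most anticorrelated.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    query_vec = df.loc[query]
    if isinstance(target, GeneSet):
        pooled = pool_gene_set(df, target)
        return _distribution_for(
            query_vec,
            df,
            POOLED_PSEUDOGENE,
            pooled,
            method,
            exclude_members=target.members if exclude_members else None,
        )
    return _distribution_for(query_vec, df, target, None, method)


def relative_reciprocal_score(
    a: str | GeneSet,
    b: str,
    expr: ExpressionMatrix | pd.DataFrame,
    method: str = "spearman",
    exclude_members: bool = False,
) -> ReciprocalScore:
    """Sum of squared reciprocal anticorrelation ranks (lower = stronger)."""
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    rank_a, _, n_b = genomewide_rank(a, b, df, method, exclude_members)
    if isinstance(a, GeneSet):
        pooled = pool_gene_set(df, a)
        dist = df
        if exclude_members:
            dist = dist.drop(index=[g for g in a.members if g in dist.index])
        rank_b, _, n_a = _distribution_for(pooled, dist, b, None, method)
        name_a = a.name
    else:
        rank_b, _, n_a = _distribution_for(df.loc[a], df, b, None, method)
        name_a = a
    return ReciprocalScore(
        name_a=name_a,
        name_b=b,
        rank_a_in_b=rank_a,
        rank_b_in_a=rank_b,
        n_genes_a=n_a,
        n_genes_b=n_b,
    )


def reciprocal_top_fraction(score: ReciprocalScore, fraction: float = 0.025) -> bool:
    """True iff both percentiles fall within the top ``fraction`` (<=)."""
    if not 0 < fraction < 1:
        raise ValueError("fraction must lie in (0, 1)")
    cut = 100.0 * fraction
    return score.percentile_a <= cut and score.percentile_b <= cut


def matched_pair_comparison(
    scores_a: pd.Series,
    scores_b: pd.Series,
    seed: int = 0,
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank test on 1:1 matched score pairs.

    The two series are keyed by a pairing identifier (e.g. donor).
    Duplicate keys on either side are reduced to one entry chosen at
    random with ``seed``; unmatched keys are dropped.  Needs >= 5 pairs.
    """
    rng = np.random.default_rng(seed)

    def dedupe(s: pd.Series) -> pd.Series:
        if not s.index.has_duplicates:
            return s
        keep = {}
        for key in s.index.unique():
            vals = s.loc[[key]]
            keep[key] = vals.iloc[rng.integers(len(vals))]
        return pd.Series(keep)

    a = dedupe(scores_a)
    b = dedupe(scores_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 5:
        raise ValueError(f"only {len(shared)} matched pairs; need >= 5")
    x = a.loc[shared].to_numpy(dtype=float)
    y = b.loc[shared].to_numpy(dtype=float)
    if np.all(x == y):
        return 0.0, 1.0
    try:
        stat, p = stats.wilcoxon(x, y, zero_method="wilcox", method="exact")
    except ValueError:
        stat, p = stats.wilcoxon(
            x, y, zero_method="wilcox", method="approx", correction=True
        )
    return float(stat), float(p)


def score_vs_covariate(
    scores: pd.Series,
    covariate: pd.Series,
    log_score: bool = True,
) -> tuple[float, float]:
    """OLS of a covariate on (log-)score across cohorts; returns (R^2, p)."""
    shared = scores.index.intersection(covariate.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 cohorts")
    y = covariate.loc[shared].to_numpy(dtype=float)
    x = scores.loc[shared].to_numpy(dtype=float)
    if np.ptp(y) == 0:
        raise ValueError("constant covariate")
    if log_score:
        x = np.log(x)
    slope, intercept, r, p, se = stats.linregress(x, y)
    return float(r**2), float(p)
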