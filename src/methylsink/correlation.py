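"""Correlation machinery.

Single-cohort feature-vs-genome correlations, rank-sampled cross-cohort
Spearman correlations, metabolite-gene association with group Z-scoring,
first-order partial correlation, Benjamini-Hochberg FDR, and thresholded
co-expression networks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations, permutations
from typing import Mapping, Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ExpressionMatrix, GeneSet
from .preprocess import zscore_by_group

__all__ = [
    "CorrelationResult",
    "CoexpressionNetwork",
    "correlate_feature_vs_genes",
    "pan_cohort_correlation",
    "metabolite_gene_correlations",
    "partial_correlation",
    "fdr_bh",
    "build_coexpression_network",
    "network_similarity",
]


@dataclass
class CorrelationResult:
    """Per-feature correlations with p, BH-FDR q and anticorrelation rank."""

    table: pd.DataFrame  # columns: r, p, q, rank
    method: str
    n: int

    def to_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index_label="feature")


def fdr_bh(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, capped at 1.

    NaN entries are ignored (returned as NaN) and do not count toward m.
    """
    p = np.asarray(pvalues, dtype=float)
    out = np.full(p.shape, np.nan)
    flat = p.ravel()
    ok = np.isfinite(flat)
    vals = flat[ok]
    if ((vals < 0) | (vals > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = vals.size
    if m:
        order = np.argsort(vals, kind="mergesort")
        ranked = vals[order] * m / np.arange(1, m + 1)
        q = np.minimum.accumulate(ranked[::-1])[::-1]
        q = np.minimum(q, 1.0)
        adj = np.empty(m)
        adj[order] = q
        out_flat = out.ravel()
        out_flat[ok] = adj
        out = out_flat.reshape(p.shape)
    return out


def _pearson_vs_matrix(f: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Pearson r of vector ``f`` against every row of ``X`` (vectorized)."""
    fc = f - f.mean()
    Xc = X - X.mean(axis=1, keepdims=True)
    fnorm = np.sqrt((fc**2).sum())
    xnorm = np.sqrt((Xc**2).sum(axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        r = (Xc @ fc) / (fnorm * xnorm)
    r[xnorm == 0] = np.nan
    return np.clip(r, -1.0, 1.0)


def _corr_pvalues(r: np.ndarray, n: int) -> np.ndarray:
    """Two-sided p via the t approximation, df = n - 2."""
    with np.errstate(invalid="ignore", divide="ignore"):
        t = r * np.sqrt((n - 2) / (1.0 - r**2))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p[np.isclose(np.abs(r), 1.0)] = 0.0
    return p


def exact_perm_pvalue(x, y, method: str = "pearson") -> float:
    """Exact two-sided permutation p-value by full enumeration (n < 10)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n >= 10:
        raise ValueError("exact permutation p only supported for n < 10")
    if method == "spearman":
        x = stats.rankdata(x)
        y = stats.rankdata(y)
    obs = abs(np.corrcoef(x, y)[0, 1])
    count = 0
    total = 0
    for perm in permutations(range(n)):
        r = abs(np.corrcoef(x, y[list(perm)])[0, 1])
        count += r >= obs - 1e-12
        total += 1
    return count / total


def _anticorrelation_rank(r: pd.Series) -> pd.Series:
    """1 = most negative correlation; ties broken by feature ID."""
    order = sorted(r.index, key=lambda g: (r[g] if np.isfinite(r[g]) else np.inf, g))
    return pd.Series(np.arange(1, len(order) + 1), index=order).reindex(r.index)


def correlate_feature_vs_genes(
    feature: pd.Series,
    expr: ExpressionMatrix | pd.DataFrame,
    method: str = "spearman",
) -> CorrelationResult:
    """Correlate a per-sample feature against every gene.

    Returns per-gene correlation, two-sided p (t approximation), BH q and
    the anticorrelation rank (1 = most negative).  Genes with constant
    expression are reported as missing; a constant feature is an error.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    feature = feature.reindex(df.columns)
    if feature.isna().any():
        raise ValueError("feature missing values for some samples")
    f = feature.to_numpy(dtype=float)
    n = f.size
    if n < 4:
        raise ValueError("need >= 4 paired observations")
    if np.ptp(f) == 0:
        raise ValueError("feature is constant; correlation undefined")
    X = df.to_numpy(dtype=float)
    if method == "spearman":
        f = stats.rankdata(f)
        X = stats.rankdata(X, axis=1)
    elif method != "pearson":
        raise ValueError(f"unknown method {method!r}")
    r = _pearson_vs_matrix(f, X)
    p = _corr_pvalues(r, n)
    q = fdr_bh(p)
    table = pd.DataFrame({"r": r, "p": p, "q": q}, index=df.index)
    table["rank"] = _anticorrelation_rank(table["r"])
    return CorrelationResult(table=table, method=method, n=n)


def pan_cohort_correlation(
    expr_by_cohort: Mapping[str, pd.DataFrame],
    target: str | Mapping[str, pd.Series],
    n_per_cohort: int,
    n_iter: int = 100,
    seed: int = 0,
    with_replacement: bool = False,
    undersized: str = "all",
) -> pd.Series:
    """Rank-sampled cross-cohort Spearman correlation, per-gene median.

    Each iteration samples ``n_per_cohort`` samples from every cohort
    (without replacement by default), ranks each gene within the sampled
    subset per cohort, concatenates ranks across cohorts and computes the
    Spearman correlation of every gene's concatenated ranks against the
    target's.  The per-gene median over ``n_iter`` iterations is returned.

    ``target`` is either a gene ID present in every cohort matrix or a
    mapping of cohort -> per-sample pooled vector.  Cohorts smaller than
    ``n_per_cohort`` use all of their samples when ``undersized='all'``,
    are dropped with ``'skip'``, or raise with ``'error'``.
    """
    if not expr_by_cohort:
        raise ValueError("no cohorts supplied")
    rng = np.random.default_rng(seed)
    cohorts = sorted(expr_by_cohort)
    genes = None
    mats: dict[str, np.ndarray] = {}
    targets: dict[str, np.ndarray] = {}
    admitted = []
    for c in cohorts:
        df = expr_by_cohort[c]
        if genes is None:
            genes = df.index
        elif not df.index.equals(genes):
            raise ValueError("cohort matrices must share a common gene index")
        n_avail = df.shape[1]
        if n_avail < n_per_cohort and not with_replacement:
            if undersized == "error":
                raise ValueError(
                    f"cohort {c!r} has {n_avail} samples < {n_per_cohort}"
                )
            if undersized == "skip":
                continue
        mats[c] = df.to_numpy(dtype=float)
        if isinstance(target, str):
            targets[c] = df.loc[target].to_numpy(dtype=float)
        else:
            targets[c] = pd.Series(target[c]).reindex(df.columns).to_numpy(dtype=float)
        admitted.append(c)
    if not admitted:
        raise ValueError("no admitted cohorts")

    medians = np.empty((n_iter, len(genes)))
    for it in range(n_iter):
        rank_blocks = []
        target_blocks = []
        for c in admitted:
            n_avail = mats[c].shape[1]
            k = min(n_per_cohort, n_avail) if not with_replacement else n_per_cohort
            idx = rng.choice(n_avail, size=k, replace=with_replacement)
            sub = mats[c][:, idx]
            rank_blocks.append(stats.rankdata(sub, axis=1))
            target_blocks.append(stats.rankdata(targets[c][idx]))
        R = np.concatenate(rank_blocks, axis=1)
        tvec = np.concatenate(target_blocks)
        # Spearman = Pearson on the concatenated within-cohort ranks
        rho = _pearson_vs_matrix(stats.rankdata(tvec), stats.rankdata(R, axis=1))
        medians[it] = rho
    return pd.Series(np.nanmedian(medians, axis=0), index=genes, name="median_rho")


def metabolite_gene_correlations(
    metab: pd.DataFrame,
    expr: ExpressionMatrix | pd.DataFrame,
    group: pd.Series,
    gene_sets: Optional[list[GeneSet]] = None,
) -> tuple[pd.DataFrame, Optional[pd.DataFrame]]:
    """Group-Z-scored Pearson correlations of metabolites against genes.

    Both matrices are Z-scored within each group (log10 first for
    expression), Z-scores pooled across groups, and each (metabolite,
    gene) pair correlated with Pearson; BH-FDR is applied across genes
    within each metabolite.  When gene sets are supplied, a per-set
    summary equal to the geometric mean of the members' FDR is returned
    per metabolite.
    """
    edf = expr.values if isinstance(expr, ExpressionMatrix) else expr
    shared = edf.columns.intersection(metab.columns)
    if len(shared) == 0:
        raise ValueError("no shared samples between expression and metabolites")
    ez = zscore_by_group(edf[shared], group, log10_first=True)
    mz = zscore_by_group(metab[shared], group, log10_first=False)

    rows = []
    for m in mz.index:
        mv = mz.loc[m].to_numpy(dtype=float)
        ok_m = np.isfinite(mv)
        X = ez.to_numpy(dtype=float)[:, ok_m]
        f = mv[ok_m]
        valid = np.isfinite(X).all(axis=1)
        r = np.full(len(ez.index), np.nan)
        r[valid] = _pearson_vs_matrix(f, X[valid])
        p = np.full_like(r, np.nan)
        p[valid] = _corr_pvalues(r[valid], int(ok_m.sum()))
        q = fdr_bh(p)
        rows.append(
            pd.DataFrame(
                {"metabolite": m, "gene": ez.index, "r": r, "p": p, "q": q}
            )
        )
    pairs = pd.concat(rows, ignore_index=True)

    set_summary = None
    if gene_sets:
        recs = []
        for gs in gene_sets:
            sub = pairs[pairs["gene"].isin(gs.members)]
            gm = sub.groupby("metabolite")["q"].apply(
                lambda v: float(np.exp(np.mean(np.log(np.clip(v.dropna(), 1e-300, None)))))
                if v.notna().any()
                else np.nan
            )
            recs.append(pd.DataFrame({"gene_set": gs.name, "geom_mean_fdr": gm}))
        set_summary = pd.concat(recs).reset_index()
    return pairs, set_summary


def partial_correlation(x, y, z) -> float:
    """First-order partial correlation of x and y controlling for z."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    z = np.asarray(z, dtype=float)
    ok = np.isfinite(x) & np.isfinite(y) & np.isfinite(z)
    if ok.sum() < 5:
        raise ValueError("need >= 5 complete (x, y, z) triples")
    x, y, z = x[ok], y[ok], z[ok]
    r_xy = np.corrcoef(x, y)[0, 1]
    r_xz = np.corrcoef(x, z)[0, 1]
    r_yz = np.corrcoef(y, z)[0, 1]
    if np.isclose(abs(r_xz), 1.0) or np.isclose(abs(r_yz), 1.0):
        raise ValueError("control variable collinear with x or y")
    return float((r_xy - r_xz * r_yz) / np.sqrt((1 - r_xz**2) * (1 - r_yz**2)))


@dataclass
class CoexpressionNetwork:
    """Undirected thresholded co-expression network."""

    nodes: list[str]
    edges: dict[frozenset, float] = field(default_factory=dict)
    threshold: float = 0.0

    def degree(self) -> pd.Series:
        deg = {n: 0 for n in self.nodes}
        for pair in self.edges:
            for n in pair:
                deg[n] += 1
        return pd.Series(deg, name="degree")

    def to_networkx(self):
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for pair, w in self.edges.items():
            a, b = sorted(pair)
            g.add_edge(a, b, weight=w)
        return g

    def to_edge_table(self) -> pd.DataFrame:
        recs = [
            {"gene_a": min(p), "gene_b": max(p), "weight": w}
            for p, w in self.edges.items()
        ]
        return pd.DataFrame(recs, columns=["gene_a", "gene_b", "weight"]).sort_values(
            ["gene_a", "gene_b"], ignore_index=True
        )


def build_coexpression_network(
    expr: ExpressionMatrix | pd.DataFrame,
    gene_set: GeneSet,
    threshold: float = 0.2,
    method: str = "spearman",
) -> CoexpressionNetwork:
    """Pairwise correlations among set members, keeping |rho| >= threshold."""
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    gene_set.require_in(df.index)
    if len(gene_set) < 2:
        raise ValueError("need >= 2 set members to build a network")
    sub = df.loc[gene_set.members]
    const = sub.std(axis=1) == 0
    if const.any():
        warnings.warn(
            f"excluding constant genes: {sub.index[const].tolist()}", stacklevel=2
        )
        sub = sub.loc[~const]
    X = sub.to_numpy(dtype=float)
    if method == "spearman":
        X = stats.rankdata(X, axis=1)
    corr = np.corrcoef(X)
    nodes = sub.index.tolist()
    edges = {}
    for i, j in combinations(range(len(nodes)), 2):
        w = float(corr[i, j])
        if abs(w) >= threshold:
            edges[frozenset((nodes[i], nodes[j]))] = w
    return CoexpressionNetwork(nodes=nodes, edges=edges, threshold=threshold)


def network_similarity(
    a: CoexpressionNetwork, b: CoexpressionNetwork
) -> tuple[float, float]:
    """Jaccard index on edge sets and Pearson over union edge weights."""
    ea, eb = set(a.edges), set(b.edges)
    union = ea | eb
    if not union:
        raise ValueError("both edge sets empty; Jaccard undefined")
    jaccard = len(ea & eb) / len(union)
    pairs = sorted(union, key=lambda p: tuple(sorted(p)))
    wa = np.array([a.edges.get(p, 0.0) for p in pairs])
    wb = np.array([b.edges.get(p, 0.0) for p in pairs])
    if len(pairs) < 2 or np.ptp(wa) == 0 or np.ptp(wb) == 0:
        weight_r = np.nan
    else:
        weight_r = float(np.corrcoef(wa, wb)[0, 1])
    return jaccard, weight_r
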