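"""Genomic regions, peak-support filtering, and locus-wise signal models.

Coordinates are 0-based half-open throughout (BED native).  Locus models
explain per-region mean log2 fold-change-over-input signal by a
per-sample predictor plus cohort fixed effects (optionally a tissue x
predictor interaction, optionally a donor random intercept fitted by
REML); empirical nulls repeat the identical model with random
gold-standard genes and average the resulting t-values per region.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import DimensionError, ExpressionMatrix, GeneSet, SignalMatrix, make_regions

__all__ = [
    "LocusModelResult",
    "make_promoters",
    "region_peak_overlap",
    "filter_regions_by_peak_support",
    "filter_by_signal_above_input",
    "bin_regions_by_mean_signal",
    "sum_overlapping_peak_widths",
    "fit_locus_models",
    "null_tvalues",
    "compare_to_null",
    "fit_negative_binomial_glm",
    "peak_tss_distance",
    "group_compare_distances",
]


def make_promoters(
    genes: pd.DataFrame,
    upstream: int = 2000,
    downstream: int = 200,
) -> pd.DataFrame:
    """Promoter windows around each gene's TSS, clipped at zero.

    ``genes`` needs columns ``chrom``, ``strand``, ``tss`` and an index
    (or ``id`` column) of gene IDs.  Plus-strand promoters span
    [TSS - upstream, TSS + downstream); minus-strand windows are
    mirrored.  Unknown strands are treated as ``+`` with a warning.
    """
    if (genes["tss"] < 0).any():
        raise ValueError("TSS must be non-negative")
    ids = genes["id"].tolist() if "id" in genes.columns else genes.index.tolist()
    strand = genes["strand"].astype(str).to_numpy()
    unknown = ~np.isin(strand, ["+", "-"])
    if unknown.any():
        warnings.warn(
            f"{int(unknown.sum())} genes with unknown strand treated as '+'",
            stacklevel=2,
        )
        strand = np.where(unknown, "+", strand)
    tss = genes["tss"].to_numpy(dtype=np.int64)
    plus = strand == "+"
    start = np.where(plus, tss - upstream, tss - downstream)
    end = np.where(plus, tss + downstream, tss + upstream)
    start = np.maximum(start, 0)
    return make_regions(
        chrom=genes["chrom"].tolist(),
        start=start,
        end=end,
        strand=list(strand),
        ids=ids,
        region_class=["promoter"] * len(genes),
    )


def region_peak_overlap(regions: pd.DataFrame, peaks: pd.DataFrame) -> np.ndarray:
    """Boolean per region: overlapped by any peak (shared base, half-open)."""
    out = np.zeros(len(regions), dtype=bool)
    if len(peaks) == 0:
        return out
    for chrom, pk in peaks.groupby("chrom"):
        mask = regions["chrom"].to_numpy() == chrom
        if not mask.any():
            continue
        rs = regions.loc[mask, "start"].to_numpy()
        re_ = regions.loc[mask, "end"].to_numpy()
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        hit = (rs[:, None] < pe[None, :]) & (re_[:, None] > ps[None, :])
        out[mask] = hit.any(axis=1)
    return out


def filter_regions_by_peak_support(
    regions: pd.DataFrame,
    peak_sets: Mapping[str, pd.DataFrame],
    min_fraction: float,
) -> pd.DataFrame:
    """Keep regions overlapped by >= 1 peak in >= min_fraction of samples."""
    if not peak_sets:
        raise ValueError("no peak sets supplied")
    support = np.zeros(len(regions), dtype=int)
    for _, peaks in peak_sets.items():
        support += region_peak_overlap(regions, peaks)
    frac = support / len(peak_sets)
    kept = regions.loc[frac >= min_fraction - 1e-12].reset_index(drop=True)
    return kept


def filter_by_signal_above_input(signal: SignalMatrix) -> SignalMatrix:
    """Drop regions whose cross-sample mean log2FC is <= 0."""
    means = signal.values.mean(axis=1)
    kept = signal.values.loc[means > 0]
    if kept.empty:
        warnings.warn("no regions with mean signal above input", stacklevel=2)
    return SignalMatrix(values=kept, mark=signal.mark, metadata=signal.metadata)


def bin_regions_by_mean_signal(signal: SignalMatrix, n_bins: int) -> pd.Series:
    """Quantile bins of cross-sample mean signal, equal counts +/- 1.

    Bin 0 is the lowest-signal bin.  Ties at bin boundaries are broken
    deterministically by region ID.
    """
    if n_bins < 2:
        raise ValueError("n_bins must be >= 2")
    if len(signal.values) < n_bins:
        raise ValueError("fewer regions than bins")
    means = signal.values.mean(axis=1)
    ordered = sorted(means.index, key=lambda rid: (means[rid], rid))
    labels = pd.Series(0, index=means.index, dtype=int)
    for b, chunk in enumerate(np.array_split(np.asarray(ordered, dtype=object), n_bins)):
        labels.loc[list(chunk)] = b
    return labels


def sum_overlapping_peak_widths(
    regions: pd.DataFrame, peaks: pd.DataFrame
) -> pd.Series:
    """Per region, the summed full widths of all overlapping peaks.

    The entire peak width (end - start) counts, not only the overlapping
    part; regions with no overlapping peak get 0.
    """
    out = pd.Series(0, index=pd.Index(regions["id"], name="id"), dtype=int)
    if len(peaks) == 0:
        return out
    for chrom, pk in peaks.groupby("chrom"):
        sub = regions[regions["chrom"] == chrom]
        if sub.empty:
            continue
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        widths = pe - ps
        for rid, rs, re_ in zip(sub["id"], sub["start"], sub["end"]):
            hit = (rs < pe) & (re_ > ps)
            out.loc[rid] = int(widths[hit].sum())
    return out


@dataclass
class LocusModelResult:
    """Per-region predictor t-values, optionally paired with a null."""

    tvalues: pd.Series
    slopes: Optional[pd.Series] = None
    null_mean_tvalues: Optional[pd.Series] = None
    n_samples: int = 0
    model: str = "ols"


def _ols_design(
    samples: pd.Index,
    predictor: pd.Series,
    cohort: Optional[pd.Series],
    interaction: bool,
) -> tuple[np.ndarray, int]:
    """Design matrix; returns (X, index of the predictor main-effect column)."""
    x = predictor.reindex(samples).to_numpy(dtype=float)
    cols = [np.ones(len(samples)), x]
    if cohort is not None:
        c = cohort.reindex(samples)
        dummies = pd.get_dummies(c, drop_first=True, dtype=float)
        for col in dummies.columns:
            cols.append(dummies[col].to_numpy())
        if interaction:
            for col in dummies.columns:
                cols.append(dummies[col].to_numpy() * x)
    X = np.column_stack(cols)
    return X, 1


def _ols_tvalues_all_loci(X: np.ndarray, Y: np.ndarray, j: int) -> tuple[np.ndarray, np.ndarray]:
    """t-value and slope of column j for every response column of Y."""
    n, p = X.shape
    if n <= p:
        raise ValueError("not enough samples for the design")
    xtx_inv = np.linalg.pinv(X.T @ X)
    B = xtx_inv @ X.T @ Y  # p x L
    resid = Y - X @ B
    dof = n - p
    sigma2 = (resid**2).sum(axis=0) / dof
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    with np.errstate(invalid="ignore", divide="ignore"):
        t = B[j] / se
    return t, B[j]


def fit_locus_models(
    signal: SignalMatrix,
    predictor: pd.Series,
    cohort: Optional[pd.Series] = None,
    interaction: bool = False,
    random_intercept: Optional[pd.Series] = None,
    min_cohort_size: int = 3,
) -> LocusModelResult:
    """Per-region t-value of the predictor coefficient explaining signal.

    Cohorts with fewer than ``min_cohort_size`` samples are dropped.  With
    a non-trivial donor grouping, each locus is fitted as a linear mixed
    model by REML; otherwise a single vectorized OLS solve covers all
    loci.  Rank-deficient loci are reported as missing, not fatal.
    """
    samples = signal.sample_ids
    missing = samples.difference(predictor.index)
    if len(missing):
        raise DimensionError(f"predictor missing for samples: {missing.tolist()[:5]}")
    if cohort is not None:
        counts = cohort.reindex(samples).value_counts()
        good = counts.index[counts >= min_cohort_size]
        keep = samples[cohort.reindex(samples).isin(good)]
        if len(keep) < len(samples):
            samples = keep
        cohort = cohort.reindex(samples)
    Y = signal.values[samples].to_numpy(dtype=float).T  # samples x regions
    X, j = _ols_design(samples, predictor, cohort, interaction)

    donors = None
    if random_intercept is not None:
        donors = random_intercept.reindex(samples)
        if donors.nunique() == len(donors):
            donors = None  # trivial grouping reduces to OLS

    regions = signal.region_ids
    if donors is None:
        t, slopes = _ols_tvalues_all_loci(X, Y, j)
        return LocusModelResult(
            tvalues=pd.Series(t, index=regions, name="t"),
            slopes=pd.Series(slopes, index=regions, name="slope"),
            n_samples=len(samples),
            model="ols",
        )

    import statsmodels.api as sm

    tvals = np.full(len(regions), np.nan)
    slopes = np.full(len(regions), np.nan)
    for i in range(len(regions)):
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = sm.MixedLM(Y[:, i], X, groups=donors).fit(reml=True)
            tvals[i] = fit.tvalues[j]
            slopes[i] = fit.params[j]
        except (np.linalg.LinAlgError, ValueError):
            continue
    return LocusModelResult(
        tvalues=pd.Series(tvals, index=regions, name="t"),
        slopes=pd.Series(slopes, index=regions, name="slope"),
        n_samples=len(samples),
        model="mixed",
    )


def null_tvalues(
    signal: SignalMatrix,
    expr: ExpressionMatrix | pd.DataFrame,
    n_random: int = 1000,
    exclusions: Optional[GeneSet] = None,
    seed: int = 0,
    cohort: Optional[pd.Series] = None,
    interaction: bool = False,
    random_intercept: Optional[pd.Series] = None,
    min_cohort_size: int = 3,
) -> pd.Series:
    """Per-region mean t-value over ``n_random`` random predictor genes.

    Genes are sampled (seeded, without replacement) from the expression
    matrix after removing the exclusion set, and each is pushed through
    the identical locus model.
    """
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    pool = df.index
    if exclusions is not None:
        pool = pool.difference(exclusions.members)
    if len(pool) < n_random:
        raise ValueError(
            f"gold-standard pool ({len(pool)}) smaller than n_random ({n_random})"
        )
    rng = np.random.default_rng(seed)
    chosen = rng.choice(np.asarray(pool, dtype=object), size=n_random, replace=False)
    total = np.zeros(len(signal.region_ids))
    count = np.zeros(len(signal.region_ids))
    for g in chosen:
        res = fit_locus_models(
            signal,
            df.loc[g].astype(float),
            cohort=cohort,
            interaction=interaction,
            random_intercept=random_intercept,
            min_cohort_size=min_cohort_size,
        )
        t = res.tvalues.to_numpy()
        ok = np.isfinite(t)
        total[ok] += t[ok]
        count[ok] += 1
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_t = total / count
    return pd.Series(mean_t, index=signal.region_ids, name="null_mean_t")


def compare_to_null(
    observed: pd.Series, null: pd.Series
) -> tuple[float, float]:
    """Two-sided paired Wilcoxon signed-rank of observed vs null t-values.

    Zero differences are dropped; the exact distribution is used for
    n <= 25 (falling back to the normal approximation with continuity
    correction if ties prevent it).  All-zero differences give p = 1.
    """
    shared = observed.index.intersection(null.index)
    x = observed.loc[shared].to_numpy(dtype=float)
    y = null.loc[shared].to_numpy(dtype=float)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if x.size < 5:
        raise ValueError("need >= 5 aligned regions")
    d = x - y
    nz = d != 0
    if not nz.any():
        return 0.0, 1.0
    method = "exact" if nz.sum() <= 25 else "approx"
    try:
        stat, p = stats.wilcoxon(x, y, zero_method="wilcox", method=method)
    except ValueError:
        stat, p = stats.wilcoxon(
            x, y, zero_method="wilcox", method="approx", correction=True
        )
    return float(stat), float(p)


def fit_negative_binomial_glm(
    counts: Sequence[int] | np.ndarray,
    predictors: Optional[pd.DataFrame | np.ndarray] = None,
) -> pd.DataFrame:
    """Log-link negative-binomial regression with ML-estimated dispersion.

    Returns a coefficient table (coef, se, z, p) with the dispersion
    ``alpha`` and the model family in ``attrs``.  On non-convergence the
    fit falls back to Poisson, flagged via ``attrs['family']``.
    """
    import statsmodels.api as sm

    y = np.asarray(counts, dtype=float)
    if predictors is None:
        X = np.ones((y.size, 1))
        names = ["intercept"]
    else:
        P = np.asarray(predictors, dtype=float)
        if P.ndim == 1:
            P = P[:, None]
        X = np.column_stack([np.ones(y.size), P])
        if isinstance(predictors, pd.DataFrame):
            names = ["intercept"] + list(predictors.columns)
        else:
            names = ["intercept"] + [f"x{i + 1}" for i in range(P.shape[1])]
    if y.size < X.shape[1] + 3:
        raise ValueError("need >= p + 3 samples for p predictors")

    family = "negative_binomial"
    alpha = np.nan
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model = sm.NegativeBinomial(y, X)
            fit = model.fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("NB fit did not converge")
        params = fit.params[: X.shape[1]]
        bse = fit.bse[: X.shape[1]]
        alpha = float(fit.params[-1])
    except Exception:
        family = "poisson_fallback"
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.GLM(y, X, family=sm.families.Poisson()).fit()
        params = fit.params
        bse = fit.bse
    with np.errstate(invalid="ignore", divide="ignore"):
        z = params / bse
    p = 2 * stats.norm.sf(np.abs(z))
    table = pd.DataFrame(
        {"coef": params, "se": bse, "z": z, "p": p}, index=names
    )
    table.attrs["family"] = family
    table.attrs["alpha"] = alpha
    return table


def peak_tss_distance(
    genes: pd.DataFrame, peaks: pd.DataFrame
) -> pd.Series:
    """Signed distance from each gene's TSS to the nearest peak.

    0 when a peak spans the TSS; positive downstream and negative
    upstream relative to the gene's strand.  Genes on chromosomes absent
    from the peak set get a missing distance.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks supplied")
    ids = genes["id"].tolist() if "id" in genes.columns else genes.index.tolist()
    out = pd.Series(np.nan, index=pd.Index(ids, name="id"), dtype=float)
    by_chrom = {c: pk for c, pk in peaks.groupby("chrom")}
    for gid, chrom, strand, tss in zip(
        ids, genes["chrom"], genes["strand"], genes["tss"]
    ):
        pk = by_chrom.get(chrom)
        if pk is None:
            continue
        ps = pk["start"].to_numpy()
        pe = pk["end"].to_numpy()
        inside = (ps <= tss) & (tss < pe)
        if inside.any():
            out.loc[gid] = 0.0
            continue
        # signed genomic offset to the nearest peak edge
        d_right = ps - tss  # positive where peak starts after the TSS
        d_left = pe - 1 - tss  # negative where peak ends before the TSS
        candidates = np.where(ps > tss, d_right, d_left)
        best = candidates[np.argmin(np.abs(candidates))]
        out.loc[gid] = float(best if strand != "-" else -best)
    return out


def group_compare_distances(
    distances_a: pd.Series, distances_b: pd.Series
) -> tuple[float, float]:
    """Two-sided Mann-Whitney rank-sum test between two distance groups."""
    a = distances_a.dropna().to_numpy(dtype=float)
    b = distances_b.dropna().to_numpy(dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty group")
    if a.size == b.size and np.array_equal(np.sort(a), np.sort(b)):
        return float(a.size * b.size / 2), 1.0
    stat, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return float(stat), float(p)
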