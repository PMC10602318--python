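"""Normalization, transformation, filtering, residualization and pooling.

Everything here runs before any correlation analysis: median-ratio
normalization of raw counts, gold-standard expressed-gene filtering,
group-wise Z-scoring and rank-percentile transforms, covariate
residualization (optionally with a donor random intercept or a spline
covariate), and summation of gene-set member pseudocounts.
"""

from __future__ import annotations

import warnings
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    CountMatrix,
    ExpressionMatrix,
    GeneSet,
    NormalizationError,
)

__all__ = [
    "mrn_normalize",
    "filter_gold_standard",
    "zscore_by_group",
    "rank_percentile_by_group",
    "residualize",
    "pool_gene_set",
    "admit_cohorts",
]


def mrn_normalize(counts: CountMatrix) -> ExpressionMatrix:
    """Median-ratio normalization of raw counts to pseudocounts.

    Per-gene geometric means are computed over samples using only genes
    with no zero count anywhere; each sample's size factor is the median
    over those genes of count / geometric mean, and pseudocounts are
    counts divided by the sample's size factor.
    """
    mat = counts.counts.to_numpy(dtype=float)
    if mat.shape[1] < 2:
        raise NormalizationError("median-ratio normalization needs >= 2 samples")
    zero_free = (mat > 0).all(axis=1)
    if not zero_free.any():
        raise NormalizationError(
            "no gene with all-positive counts; cannot estimate size factors"
        )
    log_geomean = np.mean(np.log(mat[zero_free]), axis=1)
    log_ratios = np.log(mat[zero_free]) - log_geomean[:, None]
    size_factors = np.exp(np.median(log_ratios, axis=0))
    values = pd.DataFrame(
        mat / size_factors[None, :],
        index=counts.counts.index,
        columns=counts.counts.columns,
    )
    sf = pd.Series(size_factors, index=counts.counts.columns, name="size_factor")
    return ExpressionMatrix(
        values=values,
        transform="pseudocount",
        size_factors=sf,
        metadata=counts.metadata,
    )


def filter_gold_standard(
    expr: ExpressionMatrix, tpm: ExpressionMatrix, threshold: float = 5.0
) -> GeneSet:
    """Genes expressed above ``threshold`` TPM in every sample (strict >)."""
    if threshold < 0:
        raise ValueError("threshold must be non-negative")
    common = expr.values.index.intersection(tpm.values.index)
    keep = tpm.values.loc[common]
    mask = (keep.to_numpy() > threshold).all(axis=1)
    members = common[mask].tolist()
    if not members:
        raise ValueError("no gene passes the gold-standard filter")
    return GeneSet(name=f"gold_standard_tpm_gt_{threshold:g}", members=members)


def _group_blocks(samples: pd.Index, group: pd.Series) -> dict:
    group = group.reindex(samples)
    if group.isna().any():
        missing = samples[group.isna()].tolist()
        raise KeyError(f"samples without a group label: {missing[:5]}")
    return {g: samples[group.to_numpy() == g] for g in pd.unique(group)}


def zscore_by_group(
    values: pd.DataFrame | ExpressionMatrix,
    group: pd.Series,
    log10_first: bool = False,
    min_group_size: int = 3,
) -> pd.DataFrame:
    """Standardize each feature within each sample group.

    With ``log10_first``, features containing a non-positive value inside
    a group are set to missing for that group (logging zero is undefined;
    upstream analyses restrict to universally expressed genes instead of
    offsetting).  Constant-within-group features also become missing
    rather than infinite.
    """
    df = values.values if isinstance(values, ExpressionMatrix) else values
    out = pd.DataFrame(np.nan, index=df.index, columns=df.columns, dtype=float)
    for label, cols in _group_blocks(df.columns, group).items():
        if len(cols) < min_group_size:
            raise ValueError(
                f"group {label!r} has {len(cols)} samples; need >= {min_group_size}"
            )
        block = df[cols].to_numpy(dtype=float)
        if log10_first:
            bad = (block <= 0).any(axis=1)
            if bad.any():
                warnings.warn(
                    f"{int(bad.sum())} features with non-positive values excluded "
                    f"from log10 Z-scores in group {label!r}",
                    stacklevel=2,
                )
            block = np.where(block > 0, block, np.nan)
            block = np.log10(block)
            block[bad] = np.nan
        mean = np.nanmean(block, axis=1, keepdims=True)
        sd = np.nanstd(block, axis=1, ddof=1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            z = (block - mean) / sd
        z[np.broadcast_to(sd == 0, z.shape)] = np.nan
        out.loc[:, cols] = z
    return out


def rank_percentile_by_group(
    values: pd.DataFrame | ExpressionMatrix, group: pd.Series
) -> pd.DataFrame:
    """Within-group average ranks divided by group size; range (0, 1]."""
    df = values.values if isinstance(values, ExpressionMatrix) else values
    out = pd.DataFrame(np.nan, index=df.index, columns=df.columns, dtype=float)
    for label, cols in _group_blocks(df.columns, group).items():
        if len(cols) == 0:
            raise ValueError(f"group {label!r} is empty")
        block = df[cols].to_numpy(dtype=float)
        ranks = stats.rankdata(block, axis=1, method="average")
        out.loc[:, cols] = ranks / block.shape[1]
    return out


def _spline_basis(x: np.ndarray, df: int) -> np.ndarray:
    from patsy import dmatrix

    return np.asarray(dmatrix("bs(x, df=df) - 1", {"x": x, "df": df}))


def _encode_design(
    metadata: pd.DataFrame,
    fixed_covariates: Sequence[str],
    spline_covariate: Optional[tuple[str, int]] = None,
) -> tuple[np.ndarray, list[str]]:
    cols: list[np.ndarray] = [np.ones(len(metadata))]
    names: list[str] = ["intercept"]
    for cov in fixed_covariates:
        col = metadata[cov]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            dummies = pd.get_dummies(col, prefix=cov, drop_first=True, dtype=float)
            cols.extend(dummies.to_numpy().T)
            names.extend(dummies.columns.tolist())
        else:
            cols.append(col.to_numpy(dtype=float))
            names.append(cov)
    if spline_covariate is not None:
        name, df_spline = spline_covariate
        basis = _spline_basis(metadata[name].to_numpy(dtype=float), df_spline)
        cols.extend(basis.T)
        names.extend([f"{name}_spline{i + 1}" for i in range(basis.shape[1])])
    X = np.column_stack(cols)
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        # QR flags columns that are linear combinations of earlier ones
        _, r = np.linalg.qr(X)
        aliased = [names[j] for j in range(X.shape[1]) if abs(r[j, j]) < 1e-8]
        raise ValueError(f"rank-deficient design; aliased covariates: {aliased}")
    return X, names


def residualize(
    expr: ExpressionMatrix | pd.DataFrame,
    fixed_covariates: Sequence[str],
    metadata: Optional[pd.DataFrame] = None,
    random_intercept: Optional[str] = None,
    spline_covariate: Optional[tuple[str, int]] = None,
    return_variance_components: bool = False,
):
    """Per-feature residuals against sample covariates.

    Fixed covariates (categoricals dummy-coded) are removed by ordinary
    least squares; if ``random_intercept`` names a grouping column (e.g.
    donor) each feature is fitted as a mixed model by REML instead.  A
    spline covariate is expanded to a B-spline basis with the stated
    degrees of freedom.
    """
    if isinstance(expr, ExpressionMatrix):
        df = expr.values
        metadata = metadata if metadata is not None else expr.metadata
    else:
        df = expr
    if metadata is None:
        raise ValueError("sample metadata required for residualization")
    metadata = metadata.loc[df.columns]
    X, _ = _encode_design(metadata, fixed_covariates, spline_covariate)
    Y = df.to_numpy(dtype=float).T  # samples x features

    groups = None
    if random_intercept is not None:
        groups = metadata[random_intercept]
        if groups.nunique() == len(groups):
            groups = None  # one sample per donor: reduces to OLS

    var_comps = None
    if groups is None:
        beta, *_ = np.linalg.lstsq(X, Y, rcond=None)
        resid = Y - X @ beta
    else:
        import statsmodels.api as sm

        resid = np.empty_like(Y)
        var_comps = np.empty((Y.shape[1], 2))
        group_vals = np.asarray(groups)
        for j in range(Y.shape[1]):
            model = sm.MixedLM(Y[:, j], X, groups=groups)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                fit = model.fit(reml=True)
            # conditional residuals: subtract the BLUP of each group's intercept
            marginal = Y[:, j] - X @ np.asarray(fit.fe_params)
            blups = {g: float(np.asarray(b)[0]) for g, b in fit.random_effects.items()}
            resid[:, j] = marginal - np.array([blups[g] for g in group_vals])
            var_comps[j] = [float(np.asarray(fit.cov_re)[0, 0]), float(fit.scale)]
    resid_df = pd.DataFrame(resid.T, index=df.index, columns=df.columns)
    if return_variance_components:
        vc = (
            pd.DataFrame(
                var_comps, index=df.index, columns=["group_var", "resid_var"]
            )
            if var_comps is not None
            else None
        )
        return resid_df, vc
    return resid_df


def pool_gene_set(
    expr: ExpressionMatrix | pd.DataFrame,
    gene_set: GeneSet,
    on_missing: str = "error",
) -> pd.Series:
    """Per-sample sum of the set members' pseudocounts (order-invariant)."""
    df = expr.values if isinstance(expr, ExpressionMatrix) else expr
    missing = sorted(set(gene_set.members) - set(df.index))
    members = gene_set.members
    if missing:
        if on_missing == "error":
            raise KeyError(
                f"gene set {gene_set.name!r} members missing from matrix: {missing}"
            )
        if on_missing == "drop":
            warnings.warn(
                f"dropping {len(missing)} missing members of {gene_set.name!r}",
                stacklevel=2,
            )
            members = [m for m in members if m not in set(missing)]
            if not members:
                raise KeyError(f"all members of {gene_set.name!r} missing")
        else:
            raise ValueError(f"on_missing must be 'error' or 'drop', got {on_missing!r}")
    pooled = df.loc[members].sum(axis=0)
    pooled.name = gene_set.name
    return pooled


def admit_cohorts(
    metadata: pd.DataFrame,
    min_samples: int,
    cohort_col: str = "cohort",
) -> list[str]:
    """Cohort labels with at least ``min_samples`` samples."""
    counts = metadata[cohort_col].value_counts()
    return sorted(counts.index[counts >= min_samples].tolist())
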