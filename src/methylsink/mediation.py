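"""Mutation-status classification, resampled comparisons and nested models.

Distinguishes gene-regulatory architectures linking a mutated regulator,
a pooled gene module and a counterpart gene: if the module mediates the
regulator's effect on the counterpart, adding module expression to the
model abrogates (attenuates) the mutation-status coefficient for the
counterpart but not vice versa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .correlation import fdr_bh
from .datatypes import GeneSet

__all__ = [
    "MutationStatus",
    "NestedModelResult",
    "classify_mutants",
    "resampled_group_medians",
    "nested_rb_models",
    "classify_architecture",
    "tf_enrichment",
    "two_way_anova",
]

DEFAULT_CONSEQUENCE_CLASSES = (
    "missense_mutation",
    "nonsense_mutation",
    "frame_shift_ins",
    "in_frame_del",
    "frame_shift_del",
)


@dataclass
class MutationStatus:
    """Per-sample mutant/wildtype/unknown flags for one gene."""

    status: pd.Series  # values in {"mutant", "wildtype", "unknown"}
    gene: str
    classes: tuple[str, ...]

    def is_mutant(self) -> pd.Series:
        return self.status == "mutant"


def classify_mutants(
    calls: pd.DataFrame,
    gene: str,
    classes: Sequence[str] = DEFAULT_CONSEQUENCE_CLASSES,
    samples: Optional[Sequence[str]] = None,
) -> MutationStatus:
    """Classify samples by qualifying mutation calls in ``gene``.

    A sample is ``mutant`` with >= 1 call in ``gene`` whose consequence is
    in ``classes``; ``wildtype`` if it has calls in other genes but no
    qualifying call in ``gene``; samples with no calls at all (or only
    non-qualifying calls in ``gene`` and nothing elsewhere) are
    ``unknown``, never wildtype.
    """
    required = {"sample", "gene", "consequence"}
    if calls.empty:
        raise ValueError("empty mutation-call table")
    if not required <= set(calls.columns):
        raise ValueError(f"calls table needs columns {sorted(required)}")
    class_set = {c.lower() for c in classes}
    in_gene = calls["gene"] == gene
    qualifying = in_gene & calls["consequence"].str.lower().isin(class_set)
    mutants = set(calls.loc[qualifying, "sample"])
    elsewhere = set(calls.loc[~in_gene, "sample"])
    universe = (
        pd.Index(samples)
        if samples is not None
        else pd.Index(sorted(set(calls["sample"])))
    )
    status = pd.Series("unknown", index=universe, dtype=object, name="status")
    status[status.index.isin(elsewhere)] = "wildtype"
    status[status.index.isin(mutants)] = "mutant"
    return MutationStatus(status=status, gene=gene, classes=tuple(classes))


def _admitted_cohorts(
    status: pd.Series, cohort: pd.Series, n_per_group: int
) -> list:
    tab = pd.crosstab(cohort, status)
    ok = []
    for c in tab.index:
        if (
            tab.loc[c].get("mutant", 0) >= n_per_group
            and tab.loc[c].get("wildtype", 0) >= n_per_group
        ):
            ok.append(c)
    return sorted(ok)


def resampled_group_medians(
    pct_expr: pd.Series,
    status: pd.Series,
    cohort: pd.Series,
    n_per_group: int = 10,
    n_iter: int = 1000,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Cross-cohort resampled median rank-percentiles, mutant vs wildtype.

    Per iteration, ``n_per_group`` mutant and wildtype samples are drawn
    from every admitted cohort, pooled across cohorts, and the per-group
    median percentile recorded.  Returns the two median distributions
    plus a two-sample t statistic and p over the 1,000 iteration medians
    (as specified upstream; note the iterations share samples, so this
    test pseudo-replicates -- compare across outer seeds for an honest
    error rate).
    """
    idx = pct_expr.index
    status = status.reindex(idx)
    cohort = cohort.reindex(idx)
    admitted = _admitted_cohorts(status, cohort, n_per_group)
    if not admitted:
        raise ValueError("no cohort with enough samples in both groups")
    rng = np.random.default_rng(seed)
    pools = {
        (c, g): np.sort(pct_expr[(cohort == c) & (status == g)].to_numpy(dtype=float))
        for c in admitted
        for g in ("mutant", "wildtype")
    }  # sorted so draws are invariant to input sample order
    med = {"mutant": np.empty(n_iter), "wildtype": np.empty(n_iter)}
    for it in range(n_iter):
        for g in ("mutant", "wildtype"):
            drawn = [
                rng.choice(pools[(c, g)], size=n_per_group, replace=False)
                for c in admitted
            ]
            med[g][it] = np.median(np.concatenate(drawn))
    dist = pd.DataFrame(med)
    if n_iter < 2 or (dist.std() == 0).all():
        return dist, float("nan"), float("nan")
    t, p = stats.ttest_ind(med["mutant"], med["wildtype"])
    return dist, float(t), float(p)


@dataclass
class NestedModelResult:
    """Status t-values from the four nested fits plus attenuation ratios.

    ``t_module_marginal`` / ``t_module_adjusted``: module ~ status
    (without / with counterpart expression); likewise for the
    counterpart.  Attenuation = 1 - |t_adjusted| / |t_marginal|.
    """

    t_module_marginal: float
    t_module_adjusted: float
    t_counterpart_marginal: float
    t_counterpart_adjusted: float
    n_samples: int

    @property
    def module_attenuation(self) -> float:
        return 1.0 - abs(self.t_module_adjusted) / abs(self.t_module_marginal)

    @property
    def counterpart_attenuation(self) -> float:
        return 1.0 - abs(self.t_counterpart_adjusted) / abs(
            self.t_counterpart_marginal
        )


def _ols_tvalue(y: np.ndarray, X: np.ndarray, j: int) -> float:
    n, p = X.shape
    xtx_inv = np.linalg.pinv(X.T @ X)
    beta = xtx_inv @ X.T @ y
    resid = y - X @ beta
    sigma2 = (resid**2).sum() / (n - p)
    se = np.sqrt(sigma2 * xtx_inv[j, j])
    return float(beta[j] / se)


def nested_rb_models(
    module_pct: pd.Series,
    counterpart_pct: pd.Series,
    status: pd.Series,
    cohort: pd.Series,
    n_per_group: int = 10,
    n_iter: int = 200,
    seed: int = 0,
) -> NestedModelResult:
    """Nested least-squares fits on pooled mutant/wildtype resamples.

    Per iteration, ``n_per_group`` mutant and wildtype samples per
    admitted cohort are pooled and four models fitted: module ~ status,
    module ~ status + counterpart, counterpart ~ status, and
    counterpart ~ status + module.  The reported t-value per model is
    the median over iterations.
    """
    idx = module_pct.index
    counterpart_pct = counterpart_pct.reindex(idx)
    status = status.reindex(idx)
    cohort = cohort.reindex(idx)
    admitted = _admitted_cohorts(status, cohort, n_per_group)
    if not admitted:
        raise ValueError("no cohort with enough samples in both groups")
    rng = np.random.default_rng(seed)
    members = {
        (c, g): np.sort(idx[(cohort == c) & (status == g)].to_numpy(dtype=object))
        for c in admitted
        for g in ("mutant", "wildtype")
    }
    ts = np.empty((n_iter, 4))
    n_pool = 2 * n_per_group * len(admitted)
    for it in range(n_iter):
        chosen = np.concatenate(
            [
                rng.choice(members[(c, g)], size=n_per_group, replace=False)
                for c in admitted
                for g in ("mutant", "wildtype")
            ]
        )
        m = module_pct.loc[chosen].to_numpy(dtype=float)
        cp = counterpart_pct.loc[chosen].to_numpy(dtype=float)
        s = (status.loc[chosen] == "mutant").to_numpy(dtype=float)
        if np.ptp(m) == 0 or np.ptp(cp) == 0:
            raise ValueError("collinear or constant inputs")
        ones = np.ones_like(s)
        X_marg = np.column_stack([ones, s])
        ts[it, 0] = _ols_tvalue(m, X_marg, 1)
        ts[it, 1] = _ols_tvalue(m, np.column_stack([ones, s, cp]), 1)
        ts[it, 2] = _ols_tvalue(cp, X_marg, 1)
        ts[it, 3] = _ols_tvalue(cp, np.column_stack([ones, s, m]), 1)
    med = np.median(ts, axis=0)
    return NestedModelResult(
        t_module_marginal=med[0],
        t_module_adjusted=med[1],
        t_counterpart_marginal=med[2],
        t_counterpart_adjusted=med[3],
        n_samples=n_pool,
    )


def classify_architecture(
    result: NestedModelResult, margin: float = 0.3
) -> str:
    """Label the regulatory architecture from the attenuation signature.

    ``chain``: the module mediates the status effect on the counterpart
    (counterpart attenuates, module does not); ``reverse_chain``: the
    mirror image; ``independent_arms``: neither coefficient attenuates
    appreciably when the other variable enters the model.
    """
    att_m = result.module_attenuation
    att_c = result.counterpart_attenuation
    if att_c - att_m > margin:
        return "chain"
    if att_m - att_c > margin:
        return "reverse_chain"
    return "independent_arms"


def tf_enrichment(
    bound_sets: Mapping[str, Sequence[str]],
    query: GeneSet,
    universe: Sequence[str],
) -> pd.DataFrame:
    """Fisher's exact enrichment of a gene set among each TF's bound genes.

    Returns per TF: the 2x2 table counts, the sample odds ratio (Haldane
    0.5 correction on zero cells), the conditional-MLE odds ratio, the
    two-sided hypergeometric p and BH q.
    """
    uni = set(universe)
    if not uni:
        raise ValueError("empty universe")
    qset = set(query.members)
    if not qset <= uni:
        raise ValueError("query gene set must be a subset of the universe")
    recs = []
    for tf in sorted(bound_sets):
        bound = set(bound_sets[tf]) & uni
        a = len(bound & qset)  # bound, in set
        b = len(bound - qset)  # bound, out of set
        c = len(qset - bound)  # unbound, in set
        d = len(uni - bound - qset)  # unbound, out of set
        table = np.array([[a, b], [c, d]])
        _, p = stats.fisher_exact(table, alternative="two-sided")
        if 0 in (a, b, c, d):
            sample_or = ((a + 0.5) * (d + 0.5)) / ((b + 0.5) * (c + 0.5))
        else:
            sample_or = (a * d) / (b * c)
        cmle_or = stats.contingency.odds_ratio(table, kind="conditional").statistic
        recs.append(
            {
                "tf": tf,
                "bound_in_set": a,
                "bound_out_set": b,
                "unbound_in_set": c,
                "unbound_out_set": d,
                "odds_ratio": float(sample_or),
                "cmle_odds_ratio": float(cmle_or),
                "p": float(p),
            }
        )
    out = pd.DataFrame(recs).set_index("tf")
    out["q"] = fdr_bh(out["p"].to_numpy())
    return out


def two_way_anova(
    y: pd.Series | np.ndarray,
    factor_a: Sequence,
    factor_b: Sequence,
) -> pd.DataFrame:
    """Additive two-way ANOVA with type-II sums of squares.

    Suited to unbalanced designs; aliased (perfectly confounded) factors
    raise.  A constant response returns F = 0, p = 1 for both factors.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame(
        {
            "y": np.asarray(y, dtype=float),
            "a": pd.Categorical(factor_a),
            "b": pd.Categorical(factor_b),
        }
    )
    for name in ("a", "b"):
        if df[name].nunique() < 2:
            raise ValueError(f"factor {name!r} needs >= 2 levels")
    n_a, n_b = df["a"].nunique(), df["b"].nunique()
    expected_rank = 1 + (n_a - 1) + (n_b - 1)
    from patsy import dmatrix

    X = np.asarray(dmatrix("C(a) + C(b)", df))
    if np.linalg.matrix_rank(X) < expected_rank:
        raise ValueError("factors are aliased (perfectly confounded)")
    if len(df) - expected_rank < 1:
        raise ValueError("no residual degrees of freedom")
    if np.ptp(df["y"].to_numpy()) == 0:
        return pd.DataFrame(
            {"F": [0.0, 0.0], "p": [1.0, 1.0], "df": [n_a - 1, n_b - 1]},
            index=["a", "b"],
        )
    fit = smf.ols("y ~ C(a) + C(b)", data=df).fit()
    tab = sm.stats.anova_lm(fit, typ=2)
    out = pd.DataFrame(
        {
            "F": tab.loc[["C(a)", "C(b)"], "F"].to_numpy(),
            "p": tab.loc[["C(a)", "C(b)"], "PR(>F)"].to_numpy(),
            "df": tab.loc[["C(a)", "C(b)"], "df"].to_numpy(),
        },
        index=["a", "b"],
    )
    return out
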