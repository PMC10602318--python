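"""Synthetic multi-cohort data with planted statistical structure.

Generates negative-binomial count matrices in which a latent per-sample
regulator drives a module of co-regulated genes, a "sink" gene whose
log-mean couples (negatively, by default) to the z-score of the module's
summed pseudocounts, a metabolite tracking sink activity, donor and
covariate structure, mutation status shifting the regulator, and
per-locus chromatin signal coupled to sink expression.  Ground truth is
returned for parameter-recovery tests.

All randomness flows from ``numpy.random.default_rng`` seeded with
``(seed, stream_offset)`` pairs, so every generator is deterministic
under a fixed seed and the sub-streams are independent by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np
import pandas as pd

from .datatypes import ConfigurationError, CountMatrix, DimensionError, SignalMatrix

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_cohort",
    "simulate_chip_signal",
    "simulate_architecture",
    "SINK_GENE",
]

SINK_GENE = "SINK"
_STREAMS = {
    "structure": 1,
    "baseline": 2,
    "regulator": 3,
    "counts": 4,
    "metabolite": 5,
    "chip": 6,
}


@dataclass
class SimulationConfig:
    """Knobs of the generative model; see module docstring for the roles."""

    n_cohorts: int = 3
    samples_per_cohort: int = 100
    n_genes: int = 2000
    n_hmt: int = 38
    regulator_sd: float = 1.0
    hmt_loading_mean: float = 0.5
    hmt_loading_sd: float = 0.1
    sink_coupling: float = -1.0
    metabolite_coupling: float = 1.0
    nb_dispersion: float = 0.05
    library_size_sd: float = 0.2
    covariate_effects: Mapping[str, float] = field(default_factory=dict)
    mutation_fraction: float = 0.0
    mutation_regulator_shift: float = 0.0
    chip_effect_mean: float = -1.0
    chip_effect_sd: float = 0.2
    chip_noise_sd: float = 0.5
    chip_donor_sd: float = 0.0
    n_loci: int = 100
    max_samples_per_donor: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        positive = (
            "n_cohorts",
            "samples_per_cohort",
            "n_genes",
            "n_hmt",
            "n_loci",
            "max_samples_per_donor",
        )
        for name in positive:
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be a positive integer")
        if self.n_hmt + 1 > self.n_genes:
            raise ConfigurationError("n_genes must exceed n_hmt + 1 (sink gene)")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.regulator_sd < 0:
            raise ConfigurationError("regulator_sd must be non-negative")
        if not 0.0 <= self.mutation_fraction <= 1.0:
            raise ConfigurationError("mutation_fraction must lie in [0, 1]")
        if self.library_size_sd < 0:
            raise ConfigurationError("library_size_sd must be non-negative")

    def rng(self, stream: str) -> np.random.Generator:
        return np.random.default_rng([self.seed, _STREAMS[stream]])


@dataclass
class SyntheticTruth:
    """Planted parameters and latent variables, retrievable by seed."""

    regulator_values: pd.Series
    hmt_loadings: pd.Series
    sink_coupling: float
    mutation_status: pd.Series
    sink_zscore: pd.Series
    locus_betas: Optional[pd.Series] = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "regulator": self.regulator_values,
                "mutant": self.mutation_status.astype(int),
                "sink_z": self.sink_zscore,
            }
        )


def _nb_draw(
    rng: np.random.Generator, mean: np.ndarray, dispersion: float
) -> np.ndarray:
    """NB with var = mu + dispersion * mu^2 (log-link convention)."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def simulate_cohort(
    config: SimulationConfig,
) -> tuple[CountMatrix, pd.DataFrame, SyntheticTruth]:
    """Generate counts, metabolites and ground truth for all cohorts.

    Counts are negative-binomial around log-linear means: gene baselines
    plus ``a_i * R`` for module genes, plus ``b * z(total module
    pseudocounts)`` for the sink gene, plus covariate and library-size
    effects.  The metabolite tracks the sink's within-cohort z-score.
    """
    n_samples = config.n_cohorts * config.samples_per_cohort
    g = config.n_genes

    rng_struct = config.rng("structure")
    sample_ids = [f"S{i:04d}" for i in range(n_samples)]
    cohorts = np.repeat(
        [f"cohort{c}" for c in range(config.n_cohorts)], config.samples_per_cohort
    )
    # donors contribute 1..max_samples_per_donor samples, possibly across cohorts
    donor_ids: list[str] = []
    d = 0
    while len(donor_ids) < n_samples:
        k = int(rng_struct.integers(1, config.max_samples_per_donor + 1))
        donor_ids.extend([f"D{d:04d}"] * k)
        d += 1
    donors = np.array(donor_ids[:n_samples])
    mutant = rng_struct.random(n_samples) < config.mutation_fraction

    covariates = {}
    for name in config.covariate_effects:
        covariates[name] = rng_struct.normal(0.0, 1.0, size=n_samples)

    rng_base = config.rng("baseline")
    hmt_genes = [f"HMT{i:03d}" for i in range(config.n_hmt)]
    other_genes = [f"G{i:05d}" for i in range(g - config.n_hmt - 1)]
    gene_ids = hmt_genes + [SINK_GENE] + other_genes
    log_baseline = rng_base.uniform(np.log(50.0), np.log(2000.0), size=g)
    baseline = pd.Series(log_baseline, index=gene_ids)
    loadings = rng_base.normal(
        config.hmt_loading_mean, config.hmt_loading_sd, size=config.n_hmt
    )

    rng_reg = config.rng("regulator")
    R = rng_reg.normal(0.0, config.regulator_sd, size=n_samples)
    R = R + np.where(mutant, config.mutation_regulator_shift, 0.0)

    rng_counts = config.rng("counts")
    lib = np.exp(rng_counts.normal(0.0, config.library_size_sd, size=n_samples))
    cov_term = np.zeros(n_samples)
    for name, effect in config.covariate_effects.items():
        cov_term = cov_term + effect * covariates[name]

    log_mu = np.tile(baseline.to_numpy()[:, None], (1, n_samples))
    for i in range(config.n_hmt):
        log_mu[i] += loadings[i] * R
    log_mu += cov_term[None, :]
    mu = np.exp(log_mu) * lib[None, :]

    counts = np.empty((g, n_samples), dtype=np.int64)
    non_sink = [i for i, gid in enumerate(gene_ids) if gid != SINK_GENE]
    sink_idx = gene_ids.index(SINK_GENE)
    counts[non_sink] = _nb_draw(rng_counts, mu[non_sink], config.nb_dispersion)

    # sink log-mean couples to the z-score of summed module pseudocounts,
    # so its effect size is scale-free
    hmt_total = (counts[: config.n_hmt] / lib[None, :]).sum(axis=0)
    z_hmt = (hmt_total - hmt_total.mean()) / hmt_total.std()
    log_mu_sink = baseline.iloc[sink_idx] + config.sink_coupling * z_hmt + cov_term
    mu_sink = np.exp(log_mu_sink) * lib
    counts[sink_idx] = _nb_draw(rng_counts, mu_sink, config.nb_dispersion)

    metadata = pd.DataFrame(
        {"cohort": cohorts, "donor": donors, "mutation_status": mutant},
        index=pd.Index(sample_ids, name="sample"),
    )
    for name, vals in covariates.items():
        metadata[name] = vals
    count_df = pd.DataFrame(counts, index=gene_ids, columns=sample_ids)
    cm = CountMatrix(counts=count_df, metadata=metadata)

    # metabolite tracks the sink's within-cohort z-score
    rng_met = config.rng("metabolite")
    sink_pseudo = counts[sink_idx] / lib
    sink_z = np.empty(n_samples)
    for c in np.unique(cohorts):
        m = cohorts == c
        sd = sink_pseudo[m].std()
        sink_z[m] = (sink_pseudo[m] - sink_pseudo[m].mean()) / (sd if sd > 0 else 1.0)
    metab_vals = config.metabolite_coupling * sink_z + rng_met.normal(
        0.0, 1.0, size=n_samples
    )
    metabolites = pd.DataFrame(
        {"MET_SINK": metab_vals}, index=pd.Index(sample_ids, name="sample")
    ).T

    truth = SyntheticTruth(
        regulator_values=pd.Series(R, index=sample_ids, name="regulator"),
        hmt_loadings=pd.Series(loadings, index=hmt_genes, name="loading"),
        sink_coupling=config.sink_coupling,
        mutation_status=pd.Series(mutant, index=sample_ids, name="mutant"),
        sink_zscore=pd.Series(sink_z, index=sample_ids, name="sink_z"),
    )
    return cm, metabolites, truth


LOCUS_SPAN = 2000
LOCUS_WIDTH = 1000


def simulate_chip_signal(
    truth: SyntheticTruth,
    config: SimulationConfig,
    donors: Optional[pd.Series] = None,
) -> tuple[SignalMatrix, dict[str, pd.DataFrame]]:
    """Per-locus signal coupled to sink expression, plus per-sample peaks.

    Signal at locus l in sample s is ``mu_l + beta_l * z_s + donor_s +
    noise`` with ``beta_l ~ N(chip_effect_mean, chip_effect_sd)``.  Peak
    presence per (locus, sample) is Bernoulli with probability increasing
    in the realised signal; loci live on a toy chromosome at
    ``[l * 2000, l * 2000 + 1000)``.
    """
    samples = truth.sink_zscore.index
    if len(samples) != len(truth.regulator_values):
        raise DimensionError("truth sample sets are inconsistent")
    n = len(samples)
    L = config.n_loci
    rng = config.rng("chip")
    z = truth.sink_zscore.to_numpy(dtype=float)

    betas = rng.normal(config.chip_effect_mean, config.chip_effect_sd, size=L)
    mu_l = rng.normal(1.0, 0.3, size=L)
    if donors is not None:
        donors = donors.reindex(samples)
        if donors.isna().any():
            raise DimensionError("donor labels missing for some truth samples")
        uniq = pd.unique(donors)
        per_donor = dict(
            zip(uniq, rng.normal(0.0, config.chip_donor_sd, size=len(uniq)))
        )
        donor_effect = donors.map(per_donor).to_numpy(dtype=float)
    else:
        donor_effect = rng.normal(0.0, config.chip_donor_sd, size=n)
    noise = rng.normal(0.0, config.chip_noise_sd, size=(L, n))
    signal = mu_l[:, None] + betas[:, None] * z[None, :] + donor_effect[None, :] + noise

    locus_ids = [f"locus{i:04d}" for i in range(L)]
    sig_df = pd.DataFrame(signal, index=locus_ids, columns=samples)
    sm = SignalMatrix(values=sig_df, mark="synthetic")

    # peak presence probability rises with signal (logistic link)
    prob = 1.0 / (1.0 + np.exp(-(signal - np.median(signal))))
    present = rng.random(size=(L, n)) < prob
    starts = np.arange(L) * LOCUS_SPAN
    peak_sets = {}
    for jx, s in enumerate(samples):
        rows = np.where(present[:, jx])[0]
        peak_sets[s] = pd.DataFrame(
            {
                "chrom": "chrS",
                "start": starts[rows],
                "end": starts[rows] + LOCUS_WIDTH,
            }
        )
    truth.locus_betas = pd.Series(betas, index=locus_ids, name="beta")
    return sm, peak_sets


def simulate_architecture(
    architecture: str,
    n_cohorts: int = 10,
    samples_per_cohort: int = 60,
    mutant_fraction: float = 0.4,
    status_effect: float = 0.25,
    link_effect: float = 0.8,
    noise_sd: float = 0.15,
    link_noise_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Generate rank-percentile-scale module/counterpart data under a
    known regulatory architecture.

    ``chain``: status -> module -> counterpart (no direct arm);
    ``reverse_chain``: status -> counterpart -> module;
    ``independent_arms``: status affects both directly and independently.
    Returns a per-sample frame with module, counterpart, status, cohort.
    """
    if architecture not in ("chain", "reverse_chain", "independent_arms"):
        raise ConfigurationError(f"unknown architecture {architecture!r}")
    rng = np.random.default_rng([seed, 7])
    n = n_cohorts * samples_per_cohort
    cohort = np.repeat([f"cohort{c}" for c in range(n_cohorts)], samples_per_cohort)
    status = rng.random(n) < mutant_fraction
    s = status.astype(float)
    if architecture == "chain":
        module = status_effect * s + rng.normal(0, noise_sd, n)
        counterpart = -link_effect * module + rng.normal(0, link_noise_sd, n)
    elif architecture == "reverse_chain":
        counterpart = -status_effect * s + rng.normal(0, noise_sd, n)
        module = -link_effect * counterpart + rng.normal(0, link_noise_sd, n)
    else:
        module = status_effect * s + rng.normal(0, noise_sd, n)
        counterpart = -status_effect * s + rng.normal(0, noise_sd, n)
    return pd.DataFrame(
        {
            "module": module,
            "counterpart": counterpart,
            "status": np.where(status, "mutant", "wildtype"),
            "cohort": cohort,
        },
        index=pd.Index([f"S{i:04d}" for i in range(n)], name="sample"),
    )
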