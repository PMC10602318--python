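# methylsink

Reusable pipeline for detecting reciprocal expression coupling between the
summed expression of a co-regulated gene module (e.g. histone
methyltransferases) and a "methyl-sink" counterpart gene across
multi-cohort expression data. The package implements:

- **preprocess** — median-ratio normalization to pseudocounts,
  gold-standard expressed-gene filtering, group-wise Z-score and
  rank-percentile transforms, covariate residualization (OLS, donor
  random intercept by REML, spline covariates), gene-set pooling.
- **correlation** — feature-vs-genome correlations with BH-FDR and
  anticorrelation ranks, rank-sampled cross-cohort Spearman correlation,
  metabolite–gene association with per-set geometric-mean FDR, partial
  correlation, thresholded co-expression networks and network similarity
  (Jaccard / edge-weight Pearson).
- **reciprocal** — genome-wide anticorrelation ranking with pooled
  pseudo-gene insertion, the relative reciprocal relationship score
  (sum of squared reciprocal ranks; lower = stronger), top-fraction
  flags, matched-pair Wilcoxon comparisons, score-vs-covariate
  regression.
- **pooling** — pooling trajectories (target vs cumulative pooled sums
  under random orderings) and a co-regulation toy simulator with its
  analytic closed-form oracle.
- **chromatin** — promoter windows, peak-support and
  signal-above-input filters, signal binning, summed overlapping peak
  widths, locus-wise signal-by-expression models (vectorized OLS or
  mixed models) with empirical random-gene nulls and paired Wilcoxon
  comparison, negative-binomial GLMs, peak-to-TSS distances.
- **mediation** — mutation-status classification from call tables,
  resampled cross-cohort median comparisons, nested linear models with
  attenuation signatures to discriminate regulatory architectures,
  Fisher TF-binding enrichment, additive two-way ANOVA (type-II SS).
- **synthetic** — a first-class generator planting the assumed
  statistical structure (latent regulator driving a module,
  negatively-coupled sink gene, tracking metabolite, donor/covariate
  structure, mutation shifts, per-locus chromatin signal) with ground
  truth for parameter-recovery tests.

## CLI

```sh
methylsink simulate --config cfg.yaml --out simdir --seed 1
methylsink normalize --counts counts.tsv --metadata meta.tsv --out pseudo.tsv
methylsink transform --matrix pseudo.tsv --metadata meta.tsv --method rank-percentile --out pct.tsv
methylsink correlate --matrix pseudo.tsv --feature GENE --out corr.tsv
methylsink reciprocal --matrix pseudo.tsv --gene-set module.txt --gene SINK --out score.tsv
methylsink pooling --matrix pseudo.tsv --gene-set module.txt --target SINK --out traj.tsv
methylsink coregsim --n-genes 40 --n-samples 500 --n-reps 1000 --out coreg.tsv
methylsink network --matrix pct.tsv --gene-set module.txt --threshold 0.2 --out edges.tsv
methylsink chip-model --signal chip.tsv --matrix pseudo.tsv --metadata meta.tsv \
    --predictor SINK --null-n 1000 --out tvalues.tsv
methylsink rb-mediation --module mod.tsv --counterpart cp.tsv --calls calls.tsv \
    --metadata meta.tsv --out nested.tsv
methylsink tf-enrich --bound bound.tsv --gene-set module.txt --universe genes.txt --out enrich.tsv
```

All matrices are TSV with feature IDs in the first column and sample IDs
in the header; peaks/regions are BED (0-based half-open).

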