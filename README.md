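# mutscape

Large-scale variation in the human germ-line de novo mutation (DNM) rate:
windowed gamma-Poisson rate models, equilibrium GC-content inference, and
the biased gene conversion slope test.

Trio sequencing yields catalogues of tens of thousands of DNMs — direct
observations of the mutation process, free of the fixation biases that
confound divergence-based rate estimates. This package implements, as a
tested reusable pipeline, the windowed analyses such catalogues support:

* **Rate distribution.** The genome is tiled with non-overlapping windows
  (10 kb – 10 Mb). The rate in window *j* is α·ū, with ū the mean rate per
  site and α a gamma multiplier with mean 1 and shape *k*; counts are
  Poisson with mean α·ū·*l*, so window counts are negative binomial. The
  headline statistic is the coefficient of variation CV = 1/√k of the rate
  distribution, fitted by maximum likelihood with profile-likelihood CIs,
  with goodness-of-fit, multi-scale CV scaling (a log CV vs log width slope
  of −0.5 is the pure-aggregation null), and nested-scale ANOVA.
* **Mutation categories.** DNMs are strand-collapsed into 9 categories
  (CpG C>T / C>A / C>G; non-CpG C>T, T>C, C>A, T>G, C<>G, T<>A), each
  counted against its own site class (CpG, non-CpG strong, weak).
* **Expected correlations.** Observed correlations between noisy windowed
  densities are compared against Monte-Carlo expectations under shared-rate
  models: common-distribution simulations between categories or datasets,
  expected DNM–divergence/diversity correlations, model-evaluation
  simulations, and the explainable-variance ceiling.
* **Equilibrium GC content.** With S>W rate μ(1−f_e) and W>S rate μ·f_e, a
  window at GC content *f* has expected S>W fraction
  x = f(1−f_e) / [f(1−f_e) + (1−f)f_e]. A truncated-normal mixture of
  binomial likelihoods is maximised over (mean f_e, σ) to ask whether the
  mutation *pattern* varies enough to generate GC-content (isochore)
  variation; a 9-category sequence-evolution simulator (CpG context aware)
  provides the complementary spectrum-based equilibrium.
* **gBGC slope test.** Per strong/weak class, the slope of normalized DNM
  density on recombination rate is compared with the normalized
  substitution (or SNP) density slope by window bootstrap. GC-biased gene
  conversion predicts substitutions rising faster than DNMs with
  recombination for W>S and slower for S>W; selection, ancestral
  coalescence, and regression artifacts predict distinct patterns, decoded
  by `classify_signature`.
* **Covariates.** Pearson correlations of DNM density with genomic
  features, PCA of the feature table, forward stepwise regression,
  quadratic-in-GC ascertainment correction, and a paternal-age
  slope-equality test.
* **Synthetic studies.** `mutscape.synthetic_data` generates a complete
  study — toy genome, windows, gamma rate multipliers, DNMs, substitutions,
  SNPs, recombination map, covariates — with its ground truth recorded, so
  every stage is testable closed-loop.

## Worked example

The `analysis/` scripts run the full pipeline on a synthetic study
(written under `scratch/`, summary tables under `results/`):

```
python analysis/01_simulate_study.py
python analysis/02_rate_distribution.py
```

prints

```
study: 100 windows of 50,000 bp, 3945 DNMs, 119598 substitutions, bgc_strength=0.0 -> scratch/study
all categories: CV = 0.205 (95% CI 0.162-0.254), goodness of fit p = 0.707 ...
aggregation null: slope of log CV on log width = -0.496 +- 0.010 (expectation -0.5; ...)
```

The fitted CV of 0.205 recovers the generator's truth of 0.18 within its
CI: the per-window mutation rate varies modestly (a CV of 0.18 means ~90%
of windows lie within 30% of the mean rate). The −0.496 slope is the
aggregation null: when all coarse variation is aggregated fine-scale
variation, CV falls as width^−1/2.

```
python analysis/05_divergence_diversity.py
```

prints (fixation-biased study, generator `bgc_strength = 0.5`)

```
S>W: DNM slope -0.006+-0.012, substitution slope -0.265+-0.022, P(DNM > sub) = 1.00
W>S: DNM slope -0.018+-0.019, substitution slope 0.699+-0.009, P(DNM > sub) = 0.00
S<>S&W<>W: DNM slope -0.019+-0.020, substitution slope -0.009+-0.009, P(DNM > sub) = 0.22
signature: gBGC
```

Substitutions rise with recombination for W>S changes and fall for S>W
while DNMs do neither and the GC-conserving class shows no difference —
the gBGC fixation-bias signature, correctly recovered from a generator
with the bias switched on.

A `mutscape` console command exposes the same steps on files
(`mutscape simulate`, `tabulate`, `fitdist`, `expected-corr`,
`gc-equilibrium`, `evolve`, `bgc-test`, `covariates`); see
`mutscape --help`.

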