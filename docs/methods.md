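# Methods

## The gamma-Poisson window model

Counts of DNMs in window *j* are modelled as Poisson with mean
α_j · ū · l_j, where l_j is the window's offset (non-ambiguous sites, or
the summed callable trios when provided) and the multipliers α_j are
i.i.d. gamma with mean 1 and shape *k*. Marginally each count is negative
binomial with mean ū·l_j and shape *k*; scipy's `nbinom` supplies the pmf
(parameterised as n = k, p = k/(k + mean)). The dispersion summary is
CV = 1/√k.

ū is fixed at its moment estimate Σc/Σl during the shape fit — the joint
MLE of ū is numerically indistinguishable from the moment estimate in
this model, and fixing it makes the optimisation a 1-D problem over
log k, bracketed on [10⁻³, 10⁶] with a bounded scalar minimiser
(tolerance 10⁻¹⁰ in log k). A joint fit remains available via
`fix_mean=False`. The log likelihood is unimodal in log k but not
globally concave (it approaches the Poisson asymptote from below), so
the optimiser result is also checked against both bracket ends.

95% CIs for the CV are by profile likelihood (Δ2·logL = χ²₁,₀.₉₅ = 3.84),
root-found with Brent's method on each side of the MLE. When the profile
is monotone up to the Poisson limit the lower CV bound is truncated at 0:
"CI includes 0" is then the statement that pure Poisson sampling is not
rejected.

Per-category fits use the category's own site class as the offset (CpG
transitions against CpG sites, and so on). Note that the *summed* count
across categories against total sites is over-dispersed even when the α_j
are constant, because window base composition varies and CpG sites are an
order of magnitude hotter; closed-loop Poisson-limit checks therefore run
per category.

**Goodness of fit.** Windows are binned by count; expected bin totals are
the fitted NB pmf summed over the per-window offsets, with adjacent bins
merged (left to right, remainder folded into the last bin) until every
expected count is ≥ 5; df = bins − 2.

**CV scaling.** Independent fits per window width, then OLS of log CV on
log width. If coarse-scale variation were nothing but aggregated
fine-scale variation the slope would be −0.5 (the CV of a mean of m
i.i.d. variables is CV/√m); shallower slopes indicate variation that
small scales cannot explain. Widths whose fitted shape sits at the upper
bracket (CV ≈ 0) are excluded and flagged. `iid_aggregation_profile`
packages the null experiment (10,000 fine windows, CV 0.5, Poisson mean
100 per fine window, aggregation ×10 and ×100) used by the acceptance
script; at these sizes the slope estimate carries a Monte-Carlo sd of
about 0.01.

**Nested-scale ANOVA.** One-way `f_oneway` on fine-window rates
(count/offset) grouped by coarse window, the direct test for variation at
a coarse scale beyond what fine-scale variation explains. The degenerate
all-equal input returns F = 0 by convention.

## Expected correlations under sampling error

With a few dozen DNMs per window, sampling noise caps every attainable
correlation well below 1, so observed correlations are compared with
Monte-Carlo expectations rather than with 1.

* `simulate_common_distribution`: both categories share one gamma
  distribution (shape from the mean of the two independently fitted CVs —
  a plug-in that inherits the downward bias of CV estimates at low
  counts) and perfectly correlated rates; one gamma draw per window, two
  Poisson counts scaled so each category's expected total equals its
  observed total; Pearson r between per-site densities. 100 simulations
  by default.
* `expected_correlation_given_rates`: DNMs are generated with per-window
  expectation proportional to a reference count vector (substitutions or
  SNPs), treated as error-free, normalised to the observed DNM total;
  1,000 simulations by default.
* `explainable_variance_ceiling`: true rates drawn from the fitted gamma,
  Poisson DNMs generated, r² of density against truth — the upper bound
  on variance any genomic predictor could explain.
* `simulate_under_rate_model`: same machinery with an external model's
  per-window mean rate, for evaluating published per-site/7-mer rate
  models aggregated per window.

Pearson correlation on per-site densities throughout; correlations
against a zero-variance vector are defined as 0. All procedures take a
seed and return the full simulated r vector.

## Equilibrium GC content

Writing the S>W rate per strong site as μ(1−f_e) and the W>S rate per
weak site as μ·f_e, the expected S>W fraction among GC-changing mutations
in a window of GC content f is x(f_e, f) = f(1−f_e)/[f(1−f_e)+(1−f)f_e].
Letting f_e ~ Normal(mean, σ) truncated to (0,1), the window likelihood
is the mixture ∫N·Binom(i; n, x(f_e, f))df_e / ∫N df_e, summed in log
over windows.

Numerics: fixed-order Gauss–Legendre on (0,1), 200 nodes by default
(doubling the order moves the total log likelihood by < 10⁻⁶ on test
fixtures; 64 nodes suffice for replicate studies and are used in the
heavier coverage tests). Below σ = 10⁻⁶ the mixture collapses to the
plain binomial at mean f_e, evaluated exactly — a normal of width below
the node spacing cannot be resolved by quadrature, and the boundary model
is the scientifically meaningful σ = 0 hypothesis. Optimisation:
Nelder–Mead over (logit f_e, log σ) from two σ starting points, raced
against an explicit σ = 0 boundary fit; CIs by profile likelihood with
the inner parameter re-optimised at every profile point. The σ lower
bound is 0 whenever the boundary lies within the 95% drop.

S/W assignment of the 9 categories: S>W = {CpG C>T, CpG C>A, C>T, C>A};
W>S = {T>C, T>G}; GC-conserving = {CpG C>G, C<>G, T<>A} (C>G at CpG is
S>S, so it conserves GC).

Caveat inherited from the model: all strong sites are treated alike, so
CpG hypermutability inflates the apparent S>W rate and biases the fitted
mean f_e downward on data with a CpG-elevated spectrum. The σ inference
(is there *variation* in the pattern?) is robust to this; the absolute
equilibrium is better estimated by the spectrum route below.

**Spectrum route.** `estimate_spectrum` pools category counts over
windows grouped by current GC (rates undefined, not zero, where a bin has
no sites of a class). `evolve_to_equilibrium` then evolves a sequence
under the 9 rates with CpG context re-evaluated as composition changes,
in two cross-validating modes: a deterministic integrator of circular
dinucleotide frequencies (16-state composition vector; the trinucleotide
context needed for CpG status is closed with the Markov approximation
p(abc) = p(ab)p(bc)/p(b), and the symmetric two-dinucleotide update
preserves marginal consistency), and a stochastic simulator of a circular
sequence (10⁵ sites by default, ≥ 10³ required; per-sweep mutation
probabilities scaled so the busiest site mutates with probability 0.05).
Convergence: deterministic mode stops when GC moves < 10⁻⁴ across a
100-iteration span; the stochastic mode requires two consecutive stable
spans at a noise-aware tolerance (max(tol, 3·√(0.25/L))), then averages
500 freshly generated equilibrium sweeps. The two modes agree within
0.005 GC on CpG-elevated spectra; with CpG rates equal to non-CpG rates
the per-site process is context-free and both reproduce the two-state
closed form v/(u+v) exactly.

**Mutability-index calibration.** Integer per-site scores are binned in
consecutive groups of 10 starting from the first score with at least one
DNM; log(DNMs/sites) per bin is regressed on the site-weighted mean
score, giving predict(MI) = exp(a + b·MI). Bins without DNMs are dropped
(logged); with exactly two bins the line interpolates them.

## The gBGC slope test

Per strong/weak class, the per-window event density (class counts over
the class's site total: strong sites for S>W, weak for W>S, all for
GC-conserving) and the recombination rate are each divided by their
means; OLS slopes of DNM density and of substitution (or SNP) density on
normalized recombination are then directly comparable, and exactly
invariant to rescaling either input. Significance: windows are resampled
with replacement (100 replicates by default, as a bootstrap over Mb
regions), the same resample applied to every class and both quantities,
means re-normalised within each replicate (the un-renormalised variant
differs only at second order but would leak the resample's mean shift
into the slope); the statistic is the proportion of replicates with DNM
slope above the reference slope, exact ties counting 0.5 and degenerate
replicates (constant recombination or empty class) counting 0.5 as
uninformative.

`classify_signature` decodes the three proportions at level α (default
0.05): reference above DNM for W>S and below for S>W with a quiet
GC-conserving class → gBGC; DNM above reference everywhere → selection;
reference above DNM everywhere → ancestral coalescence; all classes
significant with uniformly shallower reference slopes → regression
artifact; anything else inconclusive. Note the GC-conserving class is an
exact null under gBGC, so its bootstrap proportion is approximately
uniform across studies: single-study classifications will miss the quiet
middle about 2α of the time, which is a property of the test, not of an
implementation.

## Covariate analysis

Pearson r with a t-transform p-value per feature (constant features
flagged, no multiple-testing correction by default, Benjamini–Hochberg
behind a flag upstream of the caller); PCA on z-scored features
(scikit-learn); forward stepwise OLS where the candidate with the
smallest partial-F p-value enters while p < p_enter (0.05), with the
partial F computed from the residual-sum-of-squares improvement —
coefficient t-tests under a pseudoinverse would spuriously admit exactly
collinear candidates — ties breaking to the lower feature index, no
removal step, and coefficients reported standardized; quadratic-in-GC
OLS whose residuals strip GC-dependent ascertainment before downstream
correlation; and a two-cohort slope-equality z-test on densities
normalised to mean 1 so cohort size drops out.

## The synthetic study generator

A pure function of `SyntheticConfig` (every generator draws from a
dedicated stream spawned from the config seed). It emulates: window GC
content ~ Normal(0.41, 0.04) with i.i.d. bases at that composition (so
CpG density follows dinucleotide sampling); gamma rate multipliers with
CV 0.18; a CpG-elevated 9-category spectrum whose W>S rates are
calibrated so the implied equilibrium GC is ~0.32, consistent with the
configured mean f_e; ~40 DNMs per window placed uniformly on eligible
sites of each category's class (the density regime of the largest trio
datasets at the Mb scale); substitutions (~1,200/window, diploid-genome
divergence regime) and SNPs (~3,100/window) generated from the *same*
per-window expectations times a class-asymmetric fixation factor
4B/(1−e^(−4B)) with B = bgc_strength × normalized recombination rate,
positive for W>S, negated for S>W, absent for GC-conserving classes (the
standard diffusion fixation-bias form; the direction of the bias is what
matters and the choice is isolated in one function, `fixation_factor`);
SNPs see the bias diluted by half, as segregating variants have felt it
for less time; a mean-1 lognormal recombination map (log-sd 1); and
covariates loaded on the standardized log rate multiplier plus unit
Gaussian noise. Per-window f_e variation (fe_sd > 0) rescales S>W rates
by (1−f_e)/(1−mean) and W>S by f_e/mean, the multiplicative form implied
by writing the rates as μ(1−f_e) and μf_e.

What it does *not* emulate: spatial autocorrelation of rates between
neighbouring windows, linked selection or coalescence-time variation
(the ancestral-coalescence branch of the signature decoder is exercised
only with fabricated inputs), sequencing-callability structure, spectrum
differences between cohorts, and real isochore-scale GC structure.
Passing closed-loop tests therefore demonstrates correctness of the
estimators under the model's own assumptions, not robustness to these
real-data complications.

Default sizes are desk-scale (2 chromosomes × 2–2.5 Mb, 40–250 windows,
≤ 10⁴ DNMs per study); the statistical regime (counts per window, CVs,
divergence densities) matches the large-study setting, so test
conclusions transfer at the level of per-window information content, not
genome-wide precision.

## Problem sizes in the test and acceptance runs

Parameter-recovery tests use 2,000–2,500 windows; the GC-equilibrium
coverage study runs 50 replicates per σ value at 400 windows × ~50
GC-changing DNMs with 64 quadrature nodes; the gBGC power/null studies
use 20 seeded 250-window studies with 100 bootstrap replicates each; the
aggregation-null slope uses 10,000 fine windows. The full suite runs in
a few minutes on one core.
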