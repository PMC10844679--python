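# Methods

## Peak model

Tailing chromatographic peaks are modeled as exponentially modified
Gaussians: the convolution of a Gaussian N(μ, σ²) describing column
dispersion with an exponential decay of rate λ describing extra-column
tailing. μ and σ are in minutes, λ in 1/min; the distribution mean is
μ + 1/λ and the variance σ² + 1/λ². Some chromatography literature
parameterizes the tail by its time constant τ = 1/λ; `selenospec` uses
the rate throughout, and silently swapping the two is the classic error
the docstrings warn about.

The closed-form density overflows in floating point once λ²σ²/2 exceeds
a few hundred, although the density itself is moderate. All evaluation
therefore runs in log space through the scaled complementary error
function: with u = (x−μ)/σ and v = λσ,

log EMG(x) = log(λ/2) − u²/2 + log erfcx((v−u)/√2),

which is algebraically identical to the printed form, and for
erfcx arguments below −25 the asymptotic log erfcx(t) = t² + log 2 keeps
the far tail finite. Agreement with a 40-digit arbitrary-precision
transcription of the closed form is 1e−10 relative wherever the latter
does not overflow (tested). The peak apex (the reported "elution time")
has no closed form; it lies strictly between μ and μ + 1/λ — the
log-density slope is positive at μ and negative at the mean — and is
found by bounded scalar maximization to 1e−8 min.

## From traces to likelihoods

A chromatogram (strictly increasing retention-time grid, nonnegative
counts-per-second intensities) is converted to a discrete probability
distribution over its time bins. The bin probabilities are the
(optionally baseline-corrected, optionally windowed) intensities
normalized to one; the summed intensity acts as the effective number of
ion-count observations. Two deliberate choices:

* **Baseline** defaults to "none" (the most literal reading of
  profile-to-distribution conversion); "min-subtract" is available and
  recorded in provenance.
* **Effective sample size cap** (default 5000): raw summed cps can reach
  10⁶, and used directly as a multinomial count it would make weight
  posteriors implausibly tight given un-modeled drift and shape error.
  The cap down-weights all bins proportionally and is recorded in the
  result. The synthetic benchmarks use 5000-count traces, so for them
  the cap is inactive.

All fitting likelihoods are of the weighted form Σ_b c_b · log p(x_b)
with c_b the per-bin effective counts — the multinomial log-likelihood
up to a constant, without materializing pseudo-observations. Because
the data are *binned* counts and peak σ can be as small as one bin width
(0.05 min), the per-bin density is Simpson-averaged over the bin (edges
and center) rather than evaluated at the center; center-point evaluation
produces a measurable σ bias (~0.7 posterior SD at σ = bin width). The
synthetic generator computes its bin probabilities the same way, so the
generator and the likelihood describe the same sampling process.

## Posterior sampling

All posteriors are low-dimensional (3–5 parameters), so sampling uses an
affine-invariant ensemble sampler (emcee) with differential-evolution
moves (80% DE, 20% DE-snooker), which on these tight correlated
posteriors mix several times faster than the stretch move. Defaults: 32
walkers, 1500 adaptation steps discarded, 3000 retained steps
(96 000 draws). Walkers are treated as chains for split-R̂ and bulk ESS
(arviz); a fit with max R̂ > 1.01 warns or raises depending on policy
("strict" is the default in the pipeline and exits nonzero). Every
summary records mean, SD, central 94% interval (3rd–97th percentile),
R̂, ESS and the full sampler settings.

## Calibration of standards

Per-compound uniform priors: μ over the fitted window, σ in
(10⁻³, window span], λ in (10⁻², 10³] min⁻¹, all overridable and echoed
into the output. Walkers start from a method-of-moments estimate (tail
time constant from the third central moment). The calibrated library
stores posterior means as the fixed plug-in peak shapes, with the full
posterior summaries and a content hash used for provenance downstream.
The Se panel is exactly (GSSeSG, MSA, selenite, DMSeO); panels are
configurable, and the trimethylated species is deliberately not a panel
member because the quantified mixtures contain the four standards above.

On 5000-count synthetic standards, marginal 94% intervals attain
nominal coverage when truths are drawn from the fitting prior (measured
95%/92.5%/97.5% for μ/σ/λ over 40 replicates). The joint event "all
three parameters inside their marginal 94% intervals simultaneously"
has probability ≈ 0.85, close to the 0.94³ independence bound — a
property of marginal intervals, not a defect of the fit.

## Mixture deconvolution

Component shapes are plug-in point estimates from calibration and are
not re-sampled: the two-stage design matches how the standard library is
meant to be reused across reaction mixtures. The latent per-observation
species label is marginalized analytically, giving the mixture
likelihood Σₖ ωₖ·EMG(x; θₖ); sampling runs on the (K−1)-dimensional
additive-log-ratio transform of the simplex, where the Dirichlet(α)
prior plus transform Jacobian reduce to Σₖ αₖ log ωₖ. With the default
α = (1,1,1,1) the prior is uniform over the simplex; a prior-only mode
(likelihood dropped) reproduces the Dirichlet mean 0.25 per compound and
isolates prior from likelihood influence. Per-bin responsibilities are
computed post hoc by averaging the label posteriors over ~500 thinned
weight draws. M₀ is the GSSeSG + selenite weight summed per draw, so its
mean ± SD are exact functionals of the weight posterior.

Group comparisons use a two-sided two-sample *t* test. The default
policy is Welch (no equal-variance assumption); "student" and
"f-gated" (Student when an F test of variance equality has p ≥ 0.05)
are available, and the test actually applied is always recorded.

## Michaelis–Menten kinetics

The initializer minimizes the sum-of-squares loss with L-BFGS-B from a
4-point log-grid of K_M starts (the loss valley flattens as K_M → ∞, so
single starts can stall) followed by a Nelder–Mead polish; on noiseless
data it recovers generating parameters to ~1e−8 relative. All-zero
rates leave the loss flat in K_M; a configured fallback is returned with
an explicit flag instead of a crash.

The Bayesian model follows the Normal-prior/Gamma-precision structure:
K_M ~ N(μ_K, λ_K⁻¹), V_max ~ N(μ_V, λ_V⁻¹), v₀ ~ N(v(S₀), ε⁻¹), with
gamma hyperpriors on λ_K, λ_V, ε and prior means from the initializer.
Marginally each location prior is Student-t with 2·shape degrees of
freedom and scale √(rate/shape). Default hyperparameters: shape 2 for
all three precisions; the λ_K and λ_V rates auto-scale to
shape·max(μ, 1)² so the marginal prior scale equals the initializer
estimate itself — wide enough that the likelihood dominates and
intervals stay calibrated (measured: 94% intervals cover the generating
K_M in 48/50 seeded wild-type-like replicates, posterior-mean relative
bias 2.8%) — while ε keeps a fixed weak Gamma(2, 0.1) because the
residuals identify it. K_M and V_max are sampled on the natural scale
under their Gaussian priors; proposals violating positivity are
rejected, their frequency logged, and the fit flagged above 1%.

**N.D. rule.** K_M is reported "not determined" when any of: posterior
CV of K_M exceeds 1; the 94% posterior interval is ≥ 90% as wide as the
prior's own 94% interval (the data added nothing); or posterior-mean
V_max falls below 1 nmol/min·mg (no measurable activity). The
triggering rule is recorded in the fit.

## Synthetic data

The chromatogram generator draws binned counts either as one
multinomial draw of N total ions over the mixture bin probabilities
(default; total conserved exactly) or as independent Poisson counts
with the same means — cps data are count-like, and both options are
explicit because no single noise model is canonical. The default grid
is 0–25 min at 0.05 min, bracketing the panel's elution landmarks
(GSSeSG near 13.8 min, selenite near 16.2 min); specs whose components
are not covered by window ± (5σ + 5/λ) are rejected. The kinetics
generator evaluates the Michaelis–Menten curve on the eight-point
substrate ladder (0, 10, 100, 250, 500, 1000, 1500, 2500 μM), adds
Gaussian noise (default SD 5% of V_max, 3 replicates) and truncates at
zero. All randomness flows from a single spec seed via SeedSequence
spawning, one child stream per logical draw.

What the generators do *not* emulate — and hence what passing recovery
tests cannot show about real data: retention-time drift between
standards and samples, baseline structure, detector saturation and
column overload peak shapes, spectral interferences on the ⁸²Se channel,
and any upstream error in converting chemiluminescence to initial rates.

## Problem sizes

The verification suite runs desk-scale problems chosen to give each
statistical check real power at interactive cost: 5000-count
chromatograms (the capped effective n), 10-replicate calibration
recovery, 50-replicate kinetics coverage at reduced sampler budgets
(800/1500 steps, verified to give the same posterior means as the full
budget), and single full-budget fits elsewhere.

## Known limitations

* Component shapes are not re-fit inside mixtures, so a retention-time
  shift between calibration and sample biases weights toward whichever
  component absorbs the shifted mass; the co-elution tests quantify the
  related uncertainty growth but not systematic drift.
* Weights are proportions of the Se signal, not absolute concentrations.
* The N.D. rule and the gamma hyperprior defaults are this package's
  own operationalizations of reporting conventions that are usually
  left implicit; both are configurable and echoed into every output.
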