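# Methods

This note documents the models the package implements, the choices made
where the design was genuinely open, and what the synthetic-data tests do
and do not demonstrate.

## Study design being modelled

The package targets individual-based monitoring of spotted hyena
(*Crocuta crocuta*) clans: observers photograph and identify individuals
at dens, kills and resting sites, accumulating a sightings table (who,
when, where) and an individuals table (sex, birth date, collaring,
known death if any).  The analysis window is June 2010 – November 2019,
binned into 57 two-month occasions for survival and into monthly bins
within each wet (December–April, 5 bins) and dry (May–November, 7 bins)
season for abundance.  December is labelled with the following year's wet
season (wet-2011 = Dec 2010 – Apr 2011).

Age classes are cub (< 1 y), subadult (1–3 y) and adult (≥ 3 y), with
boundaries assigned upward (exactly 1 y is a subadult).  The class used
for the survival transition from occasion *t* to *t+1* is the class at the
midpoint of occasion *t*; a cub crossing its first birthday mid-interval
therefore transitions at the occasion boundary.  The midpoint convention
minimises boundary misclassification within a 2-month bin, and the
simulator applies the same convention so that simulated truth is exactly
comparable to model output.

## Survival: Cormack–Jolly–Seber with detection heterogeneity

For individual *i* with first detection at occasion *f*, the model
conditions on that first detection and describes later detections via

* apparent 2-month survival φ(age, sex) between occasions — 9 cells
  (3 ages × F/M/U); "apparent" means mortality and permanent emigration
  are confounded;
* detection probability p_i = logit⁻¹(μ_p + ε_i) per occasion, with
  ε_i ~ Normal(0, σ_p²) capturing stable between-individual differences
  in observability.

The likelihood of a history is computed by a two-state (alive/dead)
forward recursion that marginalises the death time exactly; the
individual effect ε_i is integrated out with Gauss–Hermite quadrature
(20 nodes by default; accurate to ~1e-8 at σ_p ≈ 0.8, and the node count
is a knob for wider mixing distributions).  Marginalising ε keeps the
posterior dimension at the hyperparameters (11 with all cells present),
which samples far more reliably at practical chain lengths than a scheme
that carries ~600 latent ε_i.

Priors are uninformative: each φ cell ~ U(0,1), logit⁻¹(μ_p) ~ U(0,1),
σ_p ~ U(0, 10) (bounds config-exposed).  Sampling uses a component-wise
random-walk Metropolis: each φ cell is updated alone — re-evaluating only
the individuals whose age-sex path touches that cell, via cached
per-individual log-likelihoods — and (μ_p, σ_p) are updated as a block.
A Laplace approximation (posterior mode + finite-difference Hessian)
seeds starting points and proposal scales; scales adapt to standard
acceptance targets during burn-in and are then frozen.  Defaults are
3 chains × 5000 kept iterations after 500 burn-in; convergence is checked
with rank-normalised split R-hat (flagged above 1.1, never silently) and
bulk ESS, computed by ArviZ.

Annualisation: non-cub cells use φ_annual = φ_2mo⁶.  Cubs are first
detectable at a mean age of 2.41 months (den emergence), so their
estimated rate applies only to the remaining 9.59 months of the first
year: exponent (12 − 2.41)/2 = 4.795.  Annual summaries are computed per
posterior draw and then summarised, preserving interval coverage.

Two verification analyses mirror the monitoring protocol:

* **Den-based cub mortality.** Cubs at communal dens are assumed always
  detected, so a cub never seen after its first birthday is counted dead.
  Among individuals first detected as cubs whose first birthday falls
  inside the study window, the headline rate divides never-resighted by
  resighted (the convention that reproduces the published figure); the
  variant dividing by all eligible cubs is reported alongside, labelled.
* **Collaring contrast.** The model is refit with a binary effect of
  radio-collaring on adult survival (logit scale, weak Normal(0, 2.5)
  prior); "no effect" is declared when the 95% credible interval spans
  zero.

Individuals with a recorded death are excluded before fitting (a joint
recovery/recapture likelihood would otherwise be needed); the exclusion
count is logged.

## Abundance: closed models with data augmentation

Within each season the population is assumed closed.  The observed
capture matrix is augmented with all-zero pseudo-histories to M = ⌈3 ×
n_obs⌉ rows (factor configurable); each row has an inclusion indicator
w ~ Bernoulli(ψ) and N = Σw.  Two detection models are fit: M0 (one
shared p) and Mh (logit-normal individual heterogeneity).  Both the
indicators and the individual effects are marginalised out of the
likelihood — the row likelihood depends only on the capture count, so the
whole dataset reduces to a capture-frequency table — leaving 2–3
hyperparameters for the adaptive random-walk Metropolis sampler.
Posterior draws of N are reconstructed exactly per draw as
N = n_obs + Binomial(M − n_obs, q) with q = ψ·P(all-zero|included) /
(ψ·P(all-zero|included) + 1 − ψ).  If the upper 2.5% of N draws reach M,
the fit is flagged and a larger augmentation factor advised.

Model comparison uses DIC = D̄ + pD with pD = D̄ − D(θ̄) (plug-in at the
posterior mean of the hyperparameters; latent indicators and individual
effects are inside neither the deviance nor the plug-in — this focus is a
convention the package fixes and documents, since either choice is
defensible).  Differences above 10 are treated as decisive.

## Density: kernel utilization distributions

The seasonal study area Â is the area of the 90th-percentile isopleth of
a bivariate Gaussian kernel utilization distribution over all sighting
locations of the individuals in that season's abundance estimate;
duplicate locations are retained because they carry real utilization
weight.  Coordinates are planar kilometres throughout (any geographic
input must be locally projected upstream).

Numerics: points are binned onto a regular grid (default 400 × 400) and
convolved with an isotropic Gaussian of sd *h*; the default bandwidth is
the reference (ad-hoc normal) rule h = √((var x + var y)/2) · n^(−1/6).
The grid pads the point bounding box by 4·h so that ≥ 99.9% of kernel
mass is captured (3·h padding loses ~1.1% of a kernel's mass and inflates
the 90% isopleth by ~4.5% after renormalisation; 4·h keeps the bias below
0.2%).  The isopleth area is the count of highest-density cells whose
cumulated mass reaches the level, times the cell area; halving the cell
size changes the area by < 1% in the test suite, which is the practical
check that the binned approximation is adequate.  A surface that captured
less kernel mass than the requested level raises an error advising larger
padding.

Density is D̂ = N̂/Â computed per posterior draw, so the credible
interval propagates exactly.  Wet seasons with too few locations for a
sound area estimate (the early-study situation) are imputed with the
arithmetic mean of the remaining wet-season areas and flagged
`imputed_mean_wet` in every output.

## Synthetic data

The generator is an agent-based simulator of a clan-structured
population with known truth, used for recovery tests:

* ~11 clans on a planar grid, ~18 initial members each, staggered entry
  over 2010–2019; recruitment is a free knob (default 5.5 cubs per clan
  per year — chosen so the number of ever-detected individuals lands near
  the real study's ~660; fecundity is not an estimate);
* per-step survival is the annual rate to the power 1/6, applied by age
  class (at the occasion midpoint) and true sex; default annual rates
  0.76/0.75 (cub F/M), 0.99 (subadult), 0.86 (adult);
* detection per 2-month occasion with p_i = logit⁻¹(μ_p + ε_i),
  μ_p = logit(0.575), σ_p = 0.8; cubs become detectable at 2.41 months;
* in fully-wet months only the 6 core clans are surveyed, and sighting
  coordinates are drawn around the clan centre with a season-specific
  spread (`range_sd_dry` = 3 km, `range_sd_wet` = 2 km, optionally
  contracted further);
* sex is revealed with probability 1 − exp(−k · detections) (k = 0.12),
  so rarely seen animals stay unsexed; a `random` mode reveals sex
  independently of detections;
* a death is "known" (recorded in the individuals table) with small
  probability (0.02), emulating the rarity of recovered carcasses;
  births are pulsed uniformly through the year.

**What passing tests show, and what they do not.**  Calibration
(coverage) experiments run the well-specified branch of the generator:
all clans surveyed year-round and sex assigned at random.  Under those
conditions 95% credible intervals cover the true survival rates at
nominal rates, which validates likelihood, sampler and summaries.  The
default branch deliberately violates the model the way the real study
does — detection-linked sexing loads poorly-detectable (and
shorter-lived) animals into the unknown-sex class, and the wet-season
clan restriction makes detection occasion-dependent.  The package's
qualitative tests reproduce the consequences (unknown-class detection
deficit; slightly optimistic sexed-cub survival), but no test certifies
the magnitude of those biases in real data.  The generator contains no
dominance hierarchies, dispersal, or inter-clan structure, and closure
violations within seasons are whatever the demography produces.

## Problem sizes used in the test suite

Recovery experiments use ~600-individual populations over the full
57-occasion grid with 3 chains × 1500 kept draws after 300 burn-in and
12 quadrature nodes (the likelihood agrees with the 20-node rule to
~1e-6 at these σ); closed-model experiments use N = 200 with 2–7
occasions.  These sizes match the real study's scale for survival and
are a scaled-down analogue for the per-season abundance fits.
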