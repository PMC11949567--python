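# hyenademog

Mark–recapture demography for spotted hyena (*Crocuta crocuta*) sighting
data: age- and sex-specific annual apparent survival from a Bayesian
Cormack–Jolly–Seber (CJS) model with individual detection heterogeneity,
seasonal abundance from closed capture–recapture models with data
augmentation and DIC model choice, and seasonal density from
kernel-utilization-distribution (KUD) study areas.  Written for
individual-based carnivore monitoring programmes that accumulate
photographic resightings of known animals, and shipped with an
agent-based population simulator with known ground truth.

## The models

**Survival.**  Detections are binned into 2-month occasions.  For each
individual the CJS likelihood conditions on first detection and
marginalises the latent alive/dead path by forward recursion:

- φ(age, sex): apparent 2-month survival, with age ∈ {cub, subadult,
  adult} (boundaries at 1 and 3 years) and sex ∈ {F, M, U};
- p_i = logit⁻¹(μ_p + ε_i), ε_i ~ N(0, σ_p²): per-occasion detection
  with logit-normal individual heterogeneity, integrated out by
  Gauss–Hermite quadrature.

Annual survival is φ⁶ for subadults and adults; cubs, first detectable
at a mean age of 2.41 months, are annualised as φ^4.795.  Priors are
uniform; sampling is component-wise adaptive Metropolis with
Laplace-seeded proposals; convergence is reported via rank-normalised
split R-hat and ESS.

**Abundance.**  Within each wet (Dec–Apr, 5 monthly occasions) or dry
(May–Nov, 7) season, closed models M0 (shared p) and Mh (logit-normal
heterogeneity) are fit by parameter-expanded data augmentation: N = Σw_i
with w_i ~ Bernoulli(ψ) over observed plus all-zero pseudo-histories.
Models are compared by DIC (ΔDIC > 10 decisive).

**Density.**  D̂ = N̂/Â per posterior draw, where Â is the area of the
90th-percentile isopleth of a Gaussian KUD over that season's sighting
locations (planar km; reference bandwidth by default).

## Worked example

```python
import numpy as np
from hyenademog import (SimConfig, simulate_population, build_cjs_history,
                        build_seasonal_histories, fit_cjs, fit_closed,
                        fit_kud, isopleth_area, density)
from hyenademog.cjs import McmcConfig

# a clan-structured population with known truth (adult phi = 0.86/yr)
ind, sig, state = simulate_population(SimConfig(seed=1, n_core_clans=None,
                                                sex_assignment_mode="random"))
hist = build_cjs_history(sig, ind, state.grid)
fit = fit_cjs(hist, McmcConfig(n_chains=3, n_iter=1500, n_burnin=300, seed=2))
print(fit.survival_table()[["age_class", "sex", "phi_annual_mean",
                            "phi_annual_lo", "phi_annual_hi"]]
      .to_string(index=False, float_format="%.2f"))

w = [w for w in build_seasonal_histories(sig) if w.season == "dry"][0]
nfit = fit_closed(w, model="Mh",
                  mcmc=McmcConfig(n_chains=3, n_iter=1500, n_burnin=300, seed=3))
area = isopleth_area(fit_kud(np.column_stack([w.x, w.y])), 0.90)
est = density(nfit, area, meta={"season": w.season, "year": w.year})
print(f"{w.season}-{w.year}: N = {est.n_median:.0f} "
      f"({est.n_lo:.0f}-{est.n_hi:.0f}), A = {est.area_km2:.0f} km2, "
      f"D = {est.d_median:.2f}/km2")
```

Output (seed 1):

```
age_class sex  phi_annual_mean  phi_annual_lo  phi_annual_hi
    adult   F             0.86           0.83           0.89
    adult   M             0.89           0.86           0.91
    adult   U             0.86           0.84           0.89
      cub   F             0.83           0.76           0.89
      cub   M             0.83           0.76           0.88
      cub   U             0.81           0.74           0.87
 subadult   F             0.98           0.96           1.00
 subadult   M             0.99           0.97           1.00
 subadult   U             0.99           0.97           1.00
dry-2010: N = 202 (192-224), A = 1073 km2, D = 0.19/km2
```

The survival table recovers the simulator's truth: 0.86 adult and 0.99
subadult annual survival, and for cubs — whose rate is annualised only
over the post-emergence 9.59 months of the first year — the expected
value 0.75^(4.795/6) ≈ 0.80.  The abundance estimate corrects the
observed count for imperfect detection, and density divides it by the
90% isopleth area of that season's sighting locations.

A thin CLI mirrors the stages: `hyenademog simulate | build | fit-cjs |
fit-closed | density | all`, each writing CSV/JSON outputs plus a
provenance block (seed, config hash) under `--outdir`.

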