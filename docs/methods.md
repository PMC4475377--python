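# Methods

## Model

`treevigor` couples two individual-based demographic submodels through a
shared likelihood.

**Growth.**  The modeled quantity is $y = \log(\mathrm{AGR}+1)$, with AGR
the annualized diameter increment in mm yr⁻¹ computed from consecutive
census diameters (cm) as $\mathrm{AGR} = 10\,(D_t - D_{t-1})/\Delta t$.
The expectation is hump-shaped in diameter (lognormal in $D$): maximum
log-growth $G_{\max}$ is attained at $D = \theta_5\cdot\mathrm{DBH95}$
and falls off with the squared log-distance from that optimum, scaled by
a width $K = \theta_6\cdot\mathrm{WD}$ (denser-wooded species have
flatter trajectories; an alternative power-law link $K = \theta_6^{\mathrm{WD}}$
is configurable, since available community-level evidence does not
discriminate the two).  $G_{\max}$ is linear in four species traits
(DBH95, WD, Hmax, δ13C), in the verbatim units of the community trait
table (DBH95 in m, Hmax in the table's dm convention, WD in g cm⁻³,
δ13C in ‰).  Residuals are iid Gaussian per tree and interval with sd
$\sigma$ (the seventh growth parameter).

**Vigor.**  The mortality covariate for interval $(k-1,k]$ is the growth
residual of the *previous* interval, observed minus expected on the
modeled log scale.  The death interval itself has no final diameter, so
a contemporaneous residual would be undefined for the trees that matter
most.  A tree's first interval has no lagged growth; its vigor is set to
0 (the residual's prior mean) and the interval flagged — an alternative
mode drops such intervals from the mortality factor entirely.  An
alternative raw-AGR-difference vigor is deliberately not offered: the
residual-on-modeled-scale definition is the one with a clean generative
interpretation (the vigor is exactly the growth-model error).

**Mortality.**  Discrete-time logistic over census intervals (10 yr by
default).  The linear predictor combines the vigor term, two
ontogenetic-trajectory covariates, and four traits (Hmax, Ortho, WD,
Tough).  The ontogeny basis is injectable; the default pair
$f_1(x)=x$, $f_2(x)=1/x$ of the relative diameter $x = D/\mathrm{DBH95}$
yields a U-shaped mortality trajectory when both coefficients are
positive (suppression of small trees, senescence near the species
maximum) — a monomial pair $(x, x^2)$ cannot.  No separate intercept is
used by default; baseline mortality is absorbed by the ontogeny terms
(an intercept can be supplied as a fixed offset).  A helper converts
interval probabilities to annual rates, $1-(1-p)^{1/\Delta t}$, for
reporting only.

**Joint likelihood.**  Survivors contribute
$\sum_t [\log f(D_t\mid D_{t-1}) + \log(1-p_t)]$; a tree dying in
$(k-1,k]$ contributes the same factors up to $k-1$ plus $\log p_k$ and no
growth factor for the death interval.  The survival factors $(1-p_t)$
before death are included (standard discrete-time survival).  The
$D$-scale Jacobian of the log(AGR+1) transform is parameter-free and
omitted — a constant shift that cancels from every posterior ratio.  All
computation is in log space; impossible outcomes under degenerate
parameters yield −∞ rather than exceptions.  Intervals whose growth is
unobservable (missing diameter) contribute the mortality factor only;
negative observed increments are clamped to zero before the log
transform (field shrinkage is treated as measurement noise), logged,
and kept in the growth likelihood as zero-growth observations.

## Inference

Componentwise random-walk Metropolis-Hastings with a conjugate
inverse-gamma Gibbs draw for $\sigma^2$
($\mathrm{IG}(a_0+n/2,\, b_0+\mathrm{SSR}/2)$).  The sampler exploits
the likelihood's structure: mortality-coefficient updates touch only the
Bernoulli component, growth-coefficient updates recompute both (the
residuals propagate into the mortality predictor through vigor).  Fixed
sweep order: θ1..θ6, Gibbs σ, β0..β6, then selection indicators.

*Priors* (unstated in the source material; standard weakly-informative
defaults, all configurable): Normal(0, 10²) on every coefficient, with
θ5 and θ6 truncated positive by proposal rejection;
InverseGamma(0.001, 0.001) on σ²; independent Bernoulli(0.5) on each
inclusion indicator.

*Two phases.*  Chains start from uniform draws in a sane box
(coefficients in [−3, 3], θ5 in [0.3, 1.5], θ6 in [1, 8], σ in
[0.2, 2]), retried up to 100 times if the likelihood is non-finite.
Phase 1 (default 2000 iterations) adapts each proposal sd every 100
iterations by a factor of 2 toward an acceptance band of [0.2, 0.5]
("satisfying staying rate"); phase 2 (default 3500) runs with frozen
proposals to preserve detailed balance, and only its draws past the
burn-in (1000), thinned (10), are retained.  Because adaptation moves on
a factor-2 ladder, realized acceptance rates can sit marginally outside
the band edges; the test suite allows a small margin for this
quantization.  Multiple chains (desk default 4; the full-scale design
used 100) run from independent streams and are pooled after burn-in.

*Selection.*  Kuo-Mallick binary indicators over eight candidates: the
four growth traits (θ1..θ4) and four mortality traits (β3..β6).  Each
indicator is drawn from its Bernoulli full conditional comparing the
likelihood with the term in and out at the coefficient's current value;
an excluded coefficient is refreshed from its prior so it can re-enter.
A predictor is retained when its pooled inclusion frequency reaches 0.8
— the empirical break observed between non-selected (≈0.4) and selected
(≥0.8) predictors in the reference community analysis.

## Synthetic communities

The simulator generates the study design the model was built for:
17,151 trees by default (10,000 in the recovery experiment below),
3 censuses 10 years apart, 335 species with traits drawn uniformly from
the observed community ranges (DBH95 ∈ [0.13, 1.11] m, Hmax ∈ [0.8, 5.6]
dm, WD ∈ [0.28, 0.91] g cm⁻³, Tough ∈ [0.22, 11.4] N, δ13C ∈ [−3.61,
−2.62] ‰, Ortho ~ Bernoulli(0.5)).  The default generating parameter
vector uses the community-level posterior medians of the reference
analysis with the stem-orientation effect set to zero (it was not
selected there), and σ = 0.5 on the log(AGR+1) scale — the reference
residual scale is not interpretable as printed, so the generator fixes
its own (recovery targets are always self-consistent with the generating
value).  Initial diameters are lognormal (median 15 cm, log-sd 0.6)
truncated to [10 cm, species maximum]: the inventory design only follows
stems above 10 cm DBH.  Trees are assigned to species uniformly; there
is no spatial structure, recruitment, or climate forcing.

Per interval and per alive tree the simulator draws a log-growth
$\mu(D)+\varepsilon$, updates the diameter, and draws death with the
lagged-vigor mortality model (first interval: vigor 0, as in inference).
The vigor it feeds to the mortality submodel is computed from the
clamped observed growth exactly as inference computes it, so the
mortality process is well-specified under recovery; the growth density
is mildly misspecified for the few clamped observations (≲0.1% under
defaults).  Three vigor regimes are available — redrawn each interval
(`iid`, the inference model's own assumption), constant per tree, or
AR(1) with stationary sd σ — the latter two as simulator-only scenarios
for studying temporal dependence; inference always assumes iid.

What passing recovery tests do *not* show: robustness to observation
error on diameters, to trait uncertainty (a hook accepts per-individual
trait overrides, but no uncertainty is propagated by default), to
irregular census intervals, or to growth processes outside the
hump-shaped family.  Real census data differ in all four ways.

## The recovery experiment

`scripts/acceptance.py` simulates one 10,000-tree community, fits with
one chain (2,000 adaptive + 4,000 frozen iterations, burn-in 1,000,
thinning 10, ~300 retained draws) and reports posterior medians of β0,
θ1, θ5, β5, β6, then reruns with all eight candidates under selection
and reports the inclusion frequency of the absent Ortho effect.  Sizes
were chosen so the whole script runs in a few minutes on one CPU with
the vectorized likelihood.

A design limitation worth stating: with 3 censuses only the second
interval carries a vigor covariate (~8,000 at-risk trees, ~600 deaths),
so the sampling sd of the β0 estimator is ≈0.09 — about 20% of the
coefficient itself.  Monte Carlo over independent communities confirms
the estimator is centred on the generating value and that the posterior
median tracks each realization's MLE to within Monte Carlo error; any
single community can nonetheless miss the generating β0 by more than
15%.  Recovery of the growth parameters and of β5/β6 is an order of
magnitude tighter.

## Numerical choices

- Diameters are cm in files, AGR in mm yr⁻¹, DBH95 in m; each conversion
  goes through a single helper module.
- Census intervals are indexed from 0; interval $k$ means $(k-1, k]$.
- Duplicate (tree, census) records, diameters on dead records, and
  records after death are hard errors; single-record trees and irregular
  spacing flag the tree unusable with a reason.
- Bernoulli log-likelihoods use the log-sigmoid
  ($-\log(1+e^{-\eta})$) form; Gaussian terms use cached sums of
  squares; η = ±∞ gives −∞, never an exception.
- The Gibbs σ draw uses σ² = b/Gamma(a); with no growth observations it
  falls back to the prior (logged).
- Selection indicators are initialized at 1 so strong predictors are
  never trapped out by an early prior excursion of their coefficient.
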