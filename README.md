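# treevigor

Joint Bayesian modelling of tropical tree growth and mortality, coupled
through **tree vigor** — the individual residual of a trait-based growth
model used as a covariate of a logistic mortality model, with both
submodels inferred simultaneously from longitudinal census data.

## The scientific problem

Trees growing less than expected tend to die sooner, but "expected" must
discount both the species' ecological strategy (pioneers grow fast, shade
tolerants slowly) and the tree's ontogenetic stage (growth peaks at
intermediate diameters).  `treevigor` implements a joint individual-based
model for decadal census data from hyperdiverse tropical forests such as
Paracou (French Guiana):

**Growth.**  For a tree of diameter $D$ (cm) in species $s$, the
log-transformed annual diameter increment is Gaussian,

$$\log(\mathrm{AGR}+1) \sim \mathcal N\big(\mu_s(D),\, \sigma^2\big),
\qquad
\mu_s(D) = G_{\max,s}\,
\exp\!\left[-\tfrac12\left(\frac{\log\big(D/(\theta_5\,\mathrm{DBH95}_s)\big)}
{\theta_6\,\mathrm{WD}_s}\right)^{\!2}\right],$$

a hump-shaped curve peaking at a fixed fraction $\theta_5$ of the species
maximum diameter, with maximum log-growth linear in four functional
traits, $G_{\max,s} = \theta_1\mathrm{DBH95}_s + \theta_2\mathrm{WD}_s +
\theta_3 H_{\max,s} + \theta_4\,\delta^{13}C_s$.

**Vigor.**  $v_{i,t} = \text{observed} - \text{expected}$ log growth:
negative when a tree underperforms its species/size expectation.

**Mortality.**  Per census interval, death is Bernoulli with

$$\mathrm{logit}\, p_{i,s,t} = \beta_0 v_{i,t-1} + \beta_1 x + \beta_2/x
+ \beta_3 H_{\max,s} + \beta_4\mathrm{Ortho}_s + \beta_5\mathrm{WD}_s
+ \beta_6\mathrm{Tough}_s,$$

where $x = D/\mathrm{DBH95}_s$ is the ontogenetic stage ($x$ and $1/x$
give the classic U-shaped mortality trajectory).

**Joint likelihood.**  A survivor contributes a growth density and a
survival factor per interval; a tree dying in $(k-1,k]$ contributes the
factors up to $k-1$ and the death probability $p_k$ (no growth factor for
the death interval).  Inference is componentwise random-walk
Metropolis-Hastings with a conjugate inverse-gamma Gibbs step for
$\sigma^2$, and Kuo-Mallick binary-indicator selection over eight
candidate trait predictors.  Because the field data behind the model are
not redistributable, the package ships a forward census simulator so
that the whole pipeline is validated by parameter recovery.

## Worked example

```python
from treevigor import JointGrowthMortalityModel, McmcConfig, SimConfig, simulate_census

sim = simulate_census(SimConfig(n_trees=3000), seed=11)   # ground-truthed community
model = JointGrowthMortalityModel(sim.census, sim.traits)
res = model.fit(McmcConfig(n_chains=1, n_iter_phase1=800, n_iter_phase2=1200,
                           burn_in=400, thinning=5), seed=5)
print(res.summary())
```

```
Joint growth-mortality model (MH-within-Gibbs)
==========================================================
trees: 3000   growth obs: 4567   mortality obs: 5388
chains: 1   retained draws: 160   selection: off
----------------------------------------------------------
   param     median         q5        q95   incl
  theta1     2.4579     2.4195     2.5093
  theta2    -0.3661    -0.4187    -0.3003
  theta3     0.0436     0.0368     0.0512
  theta4    -0.3803    -0.3948    -0.3665
  theta5     0.7689     0.7252     0.8322
  theta6     4.8606     4.6169     5.1258
   sigma     0.4936     0.4838     0.5021
   beta0    -0.3277    -0.5926    -0.0798
   beta1     0.0523    -0.4259     0.4487
   beta2     0.4985     0.4479     0.5619
   beta3    -0.4183    -0.4617    -0.3581
   beta5    -0.9449    -1.3978    -0.4262
   beta6    -0.3099    -0.3364    -0.2809
==========================================================
```

The community was generated with $\theta_1 = 2.43$, $\theta_5 = 0.767$,
$\sigma = 0.5$, $\beta_0 = -0.403$, $\beta_5 = -0.951$,
$\beta_6 = -0.327$: every posterior median lands on its generating value
within the posterior spread.  The negative median for $\beta_0$ says a
tree growing one log-unit above expectation multiplies its odds of dying
by $e^{-0.40} \approx 0.67$.  Diagnostics hang off the results object:
`res.pseudo_r2()` (adjusted McFadden against the intercept-only null),
`res.vigor_calibration()` (observed vs. resimulated death rates across
ten vigor bins with a 90% simulation band), and
`res.response_surfaces()` (death probability over ontogenetic stage per
trait profile and vigor level).

The same pipeline is scriptable: `treevigor simulate | fit | select |
evaluate | calibrate` (see `treevigor --help`).

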