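"""Model and Results facade for the joint growth-mortality model.

Usage mirrors the modelling packages of the statistics ecosystem: build a
:class:`JointGrowthMortalityModel` from a census and a trait table, call
:meth:`~JointGrowthMortalityModel.fit` (optionally with variable
selection), and read estimates, credibility intervals, inclusion
frequencies and diagnostics off the returned
:class:`JointModelResults`.

>>> from treevigor import JointGrowthMortalityModel, SimConfig, simulate_census
>>> sim = simulate_census(SimConfig(n_trees=500), seed=7)
>>> model = JointGrowthMortalityModel(sim.census, sim.traits)
>>> res = model.fit(seed=7)
>>> print(res.summary())                                   # doctest: +SKIP
"""

from __future__ import annotations

from dataclasses import replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .core import (
    CANDIDATE_PREDICTORS,
    CensusTable,
    JointParams,
    census_from_frame,
    read_census,
    read_traits,
)
from .evaluate import (
    mcfadden_pseudo_r2,
    mortality_response_surfaces,
    null_mortality_loglik,
    vigor_calibration,
)
from .likelihood import JointData, LoglikComponents
from .mcmc import McmcConfig, McmcRun, run_chains
from .mortality import OntogenyBasis

INCLUSION_THRESHOLD = 0.8


class JointGrowthMortalityModel:
    """Joint individual-based model of tree growth and mortality.

    Growth: log(AGR+1) is Gaussian around a hump-shaped, trait-driven
    expectation.  Mortality: discrete-time logistic over census intervals,
    with the lagged growth residual (tree vigor) as an individual
    covariate.  Both submodels share one likelihood and are inferred
    simultaneously by MCMC.

    Parameters
    ----------
    census : CensusTable
        Validated longitudinal census.
    traits : pandas.DataFrame
        Species trait table indexed by species_id.
    ontogeny_basis : OntogenyBasis, optional
        Two-function basis of the ontogenetic mortality trajectory
        (default x, 1/x).
    width_link : {"linear", "power"}
        Link from wood density to the growth-curve width.
    first_interval_vigor : {"zero", "drop"}
        Handling of intervals with no lagged growth.
    intercept : bool
        Add a separate mortality intercept (off by default; baseline
        mortality is absorbed by the ontogeny terms).
    individual_traits : pandas.DataFrame, optional
        Per-tree trait overrides (hook for trait-uncertainty samples).
    """

    def __init__(self, census: CensusTable, traits: pd.DataFrame, *,
                 ontogeny_basis: Optional[OntogenyBasis] = None,
                 width_link: str = "linear",
                 first_interval_vigor: str = "zero",
                 intercept: bool = False,
                 individual_traits: Optional[pd.DataFrame] = None):
        self.census = census
        self.traits = traits
        self.intercept = intercept
        self.data = JointData.from_census(
            census, traits, basis=ontogeny_basis, width_link=width_link,
            first_interval_vigor=first_interval_vigor,
            individual_traits=individual_traits)

    @classmethod
    def from_tables(cls, census_df: pd.DataFrame, traits_df: pd.DataFrame,
                    interval_years: float = 10.0, **kwargs) -> "JointGrowthMortalityModel":
        """Build from raw dataframes (validates the census)."""
        census = census_from_frame(census_df, interval_years)
        traits = traits_df.set_index("species_id") if "species_id" in traits_df.columns else traits_df
        return cls(census, traits, **kwargs)

    @classmethod
    def from_files(cls, census_path, traits_path, interval_years: float = 10.0,
                   **kwargs) -> "JointGrowthMortalityModel":
        return cls(read_census(census_path, interval_years),
                   read_traits(traits_path), **kwargs)

    # -- likelihood surface -------------------------------------------------

    def loglike(self, params: JointParams) -> float:
        """Joint log-likelihood at ``params``."""
        return self.data.loglik(params).total

    def loglike_components(self, params: JointParams) -> LoglikComponents:
        """(total, growth, mortality) log-likelihood components."""
        return self.data.loglik(params)

    # -- fitting ------------------------------------------------------------

    def fit(self, config: Optional[McmcConfig] = None, *, seed=0,
            select: Optional[Sequence[str]] = None) -> "JointModelResults":
        """Run the MH-within-Gibbs sampler and summarize the posterior.

        ``select`` activates Kuo-Mallick indicator selection over the
        named candidate predictors (``"all"`` for all eight).  Without
        selection the stem-orientation term (beta4) is excluded, matching
        the final model structure; pass a config with
        ``gamma_init={"beta4": 1}`` to force it in.
        """
        cfg = config or McmcConfig()
        if select is not None:
            chosen = tuple(CANDIDATE_PREDICTORS) if select == "all" else tuple(select)
            cfg = replace(cfg, select=chosen)
        if self.intercept and "intercept" not in cfg.fixed:
            raise NotImplementedError("sampling a free mortality intercept is not supported; "
                                      "fix it via McmcConfig.fixed['intercept']")
        run = run_chains(self.data, cfg, seed)
        return JointModelResults(self, run)

    def select(self, config: Optional[McmcConfig] = None, *, seed=0) -> "JointModelResults":
        """Fit with all eight candidate predictors under selection."""
        return self.fit(config, seed=seed, select="all")


class JointModelResults:
    """Posterior summaries and diagnostics of a fitted joint model."""

    def __init__(self, model: JointGrowthMortalityModel, run: McmcRun):
        self.model = model
        self.run = run
        self.draws = run.draws
        self.summary_frame = run.summary
        self.acceptance = run.acceptance
        self.config = run.config

    # -- estimates ----------------------------------------------------------

    @property
    def medians(self) -> pd.Series:
        return self.summary_frame["median"]

    @property
    def inclusion_frequencies(self) -> pd.Series:
        f = self.summary_frame["inclusion_freq"].dropna()
        f.name = "inclusion_freq"
        return f

    @property
    def params(self) -> JointParams:
        """Posterior-median parameter vector.

        Selected predictors keep gamma = 1 iff their pooled inclusion
        frequency reaches the retention threshold (0.8); indicators not
        under selection keep their fitted configuration.
        """
        values = self.medians.to_dict()
        params = JointParams.from_mapping(values)
        gamma = self.config.initial_gamma()
        for name in self.config.select:
            freq = self.summary_frame.loc[name, "inclusion_freq"]
            gamma[name] = int(freq >= INCLUSION_THRESHOLD)
        return params.replace(gamma=gamma)

    def conf_int(self, alpha: float = 0.10) -> pd.DataFrame:
        """Central posterior credibility intervals (90% by default)."""
        lo, hi = alpha / 2, 1 - alpha / 2
        names = self.summary_frame.index
        out = pd.DataFrame({
            "lower": [float(np.quantile(self.draws[n], lo)) for n in names],
            "upper": [float(np.quantile(self.draws[n], hi)) for n in names],
        }, index=names)
        return out

    def summary(self) -> str:
        """Human-readable fit summary (medians, 90% CI, inclusion)."""
        d = self.model.data
        lines = [
            "Joint growth-mortality model (MH-within-Gibbs)",
            "=" * 58,
            f"trees: {d.n_trees}   growth obs: {d.n_growth}   "
            f"mortality obs: {d.n_mortality}",
            f"chains: {self.config.n_chains}   retained draws: {len(self.draws)}   "
            f"selection: {', '.join(self.config.select) or 'off'}",
            "-" * 58,
            f"{'param':>8} {'median':>10} {'q5':>10} {'q95':>10} {'incl':>6}",
        ]
        for name, row in self.summary_frame.iterrows():
            incl = "" if np.isnan(row["inclusion_freq"]) else f"{row['inclusion_freq']:.2f}"
            lines.append(f"{name:>8} {row['median']:>10.4f} {row['q5']:>10.4f} "
                         f"{row['q95']:>10.4f} {incl:>6}")
        lines.append("=" * 58)
        return "\n".join(lines)

    # -- diagnostics --------------------------------------------------------

    def mortality_loglik(self, params: Optional[JointParams] = None) -> float:
        """Bernoulli mortality component at ``params`` (default: medians)."""
        return self.model.loglike_components(params or self.params).mortality

    def pseudo_r2(self, adjusted: bool = True,
                  params: Optional[JointParams] = None) -> float:
        """McFadden pseudo-R2 of the mortality component vs. the
        intercept-only null, adjusted by the number of sampled mortality
        parameters by default."""
        lnl = self.mortality_loglik(params)
        lnl0 = null_mortality_loglik(self.model.data.m_died)
        k = self.n_mortality_params() if adjusted else 0
        return mcfadden_pseudo_r2(lnl, lnl0, k)

    def n_mortality_params(self) -> int:
        params = self.params
        fixed_zero = {n for n, v in self.config.fixed.items() if v == 0.0}
        return sum(
            1 for n in ("beta0", "beta1", "beta2", "beta3", "beta4", "beta5", "beta6")
            if n not in fixed_zero and params.gamma.get(n, 1) == 1
        )

    def vigor_calibration(self, n_bins: int = 10, n_sims: int = 100,
                          seed=0) -> pd.DataFrame:
        """Vigor-binned observed vs. resimulated mortality (see
        :func:`treevigor.evaluate.vigor_calibration`)."""
        return vigor_calibration(self.model.data, self.params,
                                 n_bins=n_bins, n_sims=n_sims, seed=seed)

    def response_surfaces(self, **kwargs) -> pd.DataFrame:
        """Mortality response curves over ontogenetic stage (per trait
        profile and vigor level)."""
        kwargs.setdefault("basis", self.model.data.basis)
        return mortality_response_surfaces(self.params, **kwargs)

    # -- persistence and plotting ------------------------------------------

    def save_draws(self, path) -> None:
        self.draws.to_csv(path, index=False)

    def plot_trace(self, names: Optional[Sequence[str]] = None, ax=None):
        """Trace plots of retained draws (one panel per parameter)."""
        import matplotlib.pyplot as plt

        names = list(names or [n for n in ("theta1", "theta5", "sigma", "beta0")
                               if n in self.draws.columns])
        fig, axes = plt.subplots(len(names), 1, figsize=(8, 2 * len(names)),
                                 sharex=True, squeeze=False)
        for axis, name in zip(axes.ravel(), names):
            for _, grp in self.draws.groupby("chain"):
                axis.plot(grp[name].to_numpy(), lw=0.6)
            axis.set_ylabel(name)
        axes.ravel()[-1].set_xlabel("retained draw")
        fig.tight_layout()
        return fig

    def plot_calibration(self, table: Optional[pd.DataFrame] = None, ax=None):
        """Observed vs. predicted death rate across vigor bins."""
        import matplotlib.pyplot as plt

        table = table if table is not None else self.vigor_calibration()
        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.errorbar(table["observed_rate"], table["predicted_rate"],
                    yerr=[table["predicted_rate"] - table["predicted_q5"],
                          table["predicted_q95"] - table["predicted_rate"]],
                    fmt="o")
        lim = max(table[["observed_rate", "predicted_q95"]].to_numpy().max(), 0.01)
        ax.plot([0, lim], [0, lim], "k--", lw=0.8)
        ax.set_xlabel("observed death rate")
        ax.set_ylabel("predicted death rate (90% band)")
        return ax
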