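"""Joint likelihood assembly: branch structure, additivity, vectorized path."""

import math

import pytest

from treevigor import (
    GrowthParams,
    JointData,
    JointParams,
    MortalityParams,
    TraitVector,
    build_trajectories,
    census_from_frame,
    compute_vigor,
    growth_logdensity,
    mortality_linear_predictor,
    mortality_probability,
    total_loglik,
    tree_loglik,
)
from treevigor.likelihood import TreeTrajectory, tree_loglik_components

TRAITS = TraitVector(dbh95=0.5, hmax=3.0, ortho=0, wd=0.6, tough=5.0, d13c=-3.0)


def joint_params(**over):
    base = dict(theta1=2.43, theta2=-0.384, theta3=0.0318, theta4=-0.403,
                theta5=0.767, theta6=4.81, sigma=0.5,
                beta0=-0.403, beta1=0.140, beta2=0.502, beta3=-0.414,
                beta4=0.0, beta5=-0.951, beta6=-0.327)
    base.update(over)
    return JointParams(**base)


def survivor(dbhs, tid="a"):
    return TreeTrajectory(tree_id=tid, traits=TRAITS,
                          time_indices=list(range(len(dbhs))),
                          dbhs=list(dbhs),
                          statuses=["alive"] * len(dbhs))


def dead_tree(dbhs, death_at, tid="d"):
    times = list(range(len(dbhs) + 1))
    return TreeTrajectory(tree_id=tid, traits=TRAITS,
                          time_indices=times,
                          dbhs=list(dbhs) + [None],
                          statuses=["alive"] * len(dbhs) + ["dead"],
                          death_interval=death_at)


def manual_loglik(traj, params):
    """Independent re-derivation of the branch formulas from the module
    primitives: growth density and survival for every completed interval,
    the death probability for the death interval (no growth factor)."""
    gp = GrowthParams.from_joint(params)
    mp = MortalityParams.from_joint(params)
    total = 0.0
    dbhs = traj.dbhs
    n_int = len(traj.time_indices) - 1
    for k in range(1, n_int + 1):
        is_death = traj.death_interval == traj.time_indices[k]
        if k >= 2:
            y_prev = math.log1p(max(10 * (dbhs[k - 1] - dbhs[k - 2]) / 10.0, 0))
            from treevigor import predict_log_growth
            v = compute_vigor(y_prev, predict_log_growth(dbhs[k - 2], TRAITS, gp))
        else:
            v = 0.0
        p = mortality_probability(mortality_linear_predictor(v, dbhs[k - 1], TRAITS, mp))
        if is_death:
            total += math.log(p)
        else:
            y = math.log1p(max(10 * (dbhs[k] - dbhs[k - 1]) / 10.0, 0))
            total += growth_logdensity(y, dbhs[k - 1], TRAITS, gp) + math.log1p(-p)
    return total


class TestBranchStructure:
    def test_survivor_branch_matches_manual_product(self):
        traj = survivor([15.0, 16.2, 17.1])
        params = joint_params()
        assert tree_loglik(traj, params, interval_years=10.0) == pytest.approx(
            manual_loglik(traj, params), abs=1e-10)

    def test_death_branch_matches_manual_product(self):
        traj = dead_tree([15.0, 16.2], death_at=2)
        params = joint_params()
        assert tree_loglik(traj, params, interval_years=10.0) == pytest.approx(
            manual_loglik(traj, params), abs=1e-10)

    def test_death_interval_has_no_growth_factor(self):
        """A first-interval death contributes log p only: the growth
        component is exactly zero."""
        traj = dead_tree([15.0], death_at=1)
        c = tree_loglik_components(traj, joint_params(), interval_years=10.0)
        assert c.growth == 0.0
        p = mortality_probability(mortality_linear_predictor(
            0.0, 15.0, TRAITS, MortalityParams.from_joint(joint_params())))
        assert c.total == pytest.approx(math.log(p), abs=1e-12)

    def test_survival_factors_vanish_when_p_zero(self):
        """With an overwhelmingly negative linear predictor the survivor
        log-likelihood is the sum of growth densities alone."""
        params = joint_params(beta0=0, beta1=0, beta2=0, beta3=-1000.0,
                              beta5=0, beta6=0)
        traj = survivor([15.0, 16.2, 17.1])
        c = tree_loglik_components(traj, params, interval_years=10.0)
        assert c.mortality == 0.0
        assert c.total == pytest.approx(c.growth)

    def test_impossible_outcome_gives_minus_inf_not_exception(self):
        """p exactly 0 (eta = -inf) with a death observed returns -inf."""
        params = joint_params(beta0=0, beta1=0, beta2=0, beta3=0,
                              beta5=0, beta6=0)
        params.intercept = -math.inf
        traj = dead_tree([15.0], death_at=1)
        assert tree_loglik(traj, params, interval_years=10.0) == -math.inf


class TestTotalLoglik:
    def test_additivity_and_exchangeability(self):
        params = joint_params()
        t1 = survivor([15.0, 16.2, 17.1], "a")
        t2 = survivor([15.0, 16.2, 17.1], "b")
        t3 = dead_tree([20.0, 21.0], 2, "c")
        single = tree_loglik(t1, params, interval_years=10.0)
        assert total_loglik([t1, t2], params, interval_years=10.0).total == pytest.approx(
            2 * single, rel=1e-12)
        a = total_loglik([t1, t2, t3], params, interval_years=10.0)
        b = total_loglik([t3, t1, t2], params, interval_years=10.0)
        assert a.total == pytest.approx(b.total, rel=1e-14)

    def test_vectorized_matches_naive_loop_on_fixture(self, small_sim):
        """50-tree oracle: the vectorized design equals a per-tree loop."""
        ids = small_sim.census.frame["tree_id"].unique()[:50]
        sub = small_sim.census.frame[small_sim.census.frame["tree_id"].isin(ids)]
        census = census_from_frame(sub, 10.0)
        params = joint_params()
        data = JointData.from_census(census, small_sim.traits)
        fast = total_loglik(data, params)
        slow = total_loglik(build_trajectories(census, small_sim.traits),
                            params, interval_years=10.0)
        assert fast.total == pytest.approx(slow.total, rel=1e-10)
        assert fast.growth == pytest.approx(slow.growth, rel=1e-10)
        assert fast.mortality == pytest.approx(slow.mortality, rel=1e-10)

    def test_update_scoping_rule(self, small_model):
        """Mortality-coefficient perturbations leave the growth component
        bit-identical; growth-coefficient perturbations propagate to both
        components through the vigor covariate."""
        params = joint_params()
        base = small_model.loglike_components(params)
        for name in ("beta0", "beta2", "beta5"):
            pert = small_model.loglike_components(
                params.replace(**{name: getattr(params, name) + 0.37}))
            assert pert.growth == base.growth  # bit-identical
            assert pert.mortality != base.mortality
        for name in ("theta1", "theta5", "theta6"):
            pert = small_model.loglike_components(
                params.replace(**{name: getattr(params, name) + 0.05}))
            assert pert.growth != base.growth
            assert pert.mortality != base.mortality

    def test_first_interval_drop_mode(self, small_sim):
        data_zero = JointData.from_census(small_sim.census, small_sim.traits)
        data_drop = JointData.from_census(small_sim.census, small_sim.traits,
                                          first_interval_vigor="drop")
        n_first = int((data_zero.m_vidx < 0).sum())
        assert n_first > 0
        assert data_drop.n_mortality == data_zero.n_mortality - n_first
        assert (data_drop.m_vidx >= 0).all()
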