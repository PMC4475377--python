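"""Census/trait I-O, validation rules and growth-observation arithmetic."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treevigor import (
    CensusParseError,
    JointParams,
    ParameterError,
    TraitVector,
    census_from_frame,
    compute_growth_observations,
    read_census,
    read_traits,
    write_census,
    write_traits,
)
from treevigor.units import annualized_increment_mm, cm_to_mm, m_to_cm


def _census_df(rows):
    return pd.DataFrame(rows, columns=["tree_id", "species_id", "time_index",
                                       "time_years", "dbh_cm", "status"])


class TestCensusValidation:
    def test_minimal_two_record_tree(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("a", "s1", 1, 10.0, 16.2, "alive")])
        census = census_from_frame(df, 10.0)
        assert census.n_trees == 1 and not census.unusable
        obs = compute_growth_observations(census)
        assert len(obs) == 1
        assert obs["agr_mm_yr"].iloc[0] == pytest.approx(1.2)
        assert obs["log_agr1"].iloc[0] == pytest.approx(math.log(2.2), abs=1e-12)

    def test_dbh_on_dead_record_is_error(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("a", "s1", 1, 10.0, 16.0, "dead")])
        with pytest.raises(CensusParseError, match="a"):
            census_from_frame(df, 10.0)

    def test_alive_without_dbh_is_error(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("a", "s1", 1, 10.0, np.nan, "alive")])
        with pytest.raises(CensusParseError):
            census_from_frame(df, 10.0)

    def test_duplicate_record_is_error(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("a", "s1", 0, 0.0, 15.0, "alive")])
        with pytest.raises(CensusParseError, match="duplicate"):
            census_from_frame(df, 10.0)

    def test_record_after_death_is_error(self):
        df = _census_df([("a", "s1", 0, 0.0, None, "dead"),
                         ("a", "s1", 1, 10.0, 15.0, "alive")])
        with pytest.raises(CensusParseError, match="after death"):
            census_from_frame(df, 10.0)

    def test_missing_column_is_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("tree_id,species_id\n1,2\n")
        with pytest.raises(CensusParseError, match="missing columns"):
            read_census(p, 10.0)

    def test_single_record_tree_flagged_unusable(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("b", "s1", 0, 0.0, 12.0, "alive"),
                         ("b", "s1", 1, 10.0, 13.0, "alive")])
        census = census_from_frame(df, 10.0)
        assert census.unusable == {"a": "fewer than 2 census records"}
        assert census.n_usable_trees == 1

    def test_irregular_spacing_flagged(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("a", "s1", 2, 20.0, 16.0, "alive")])
        census = census_from_frame(df, 10.0)
        assert "a" in census.unusable

    def test_roundtrip_synthetic_census(self, small_sim, tmp_path):
        path = tmp_path / "census.csv"
        write_census(small_sim.census, path)
        back = read_census(path, small_sim.census.interval_years)
        pd.testing.assert_frame_equal(back.frame, small_sim.census.frame)
        tpath = tmp_path / "traits.csv"
        write_traits(small_sim.traits, tpath)
        pd.testing.assert_frame_equal(read_traits(tpath), small_sim.traits)


class TestGrowthObservations:
    def test_zero_increment(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("a", "s1", 1, 10.0, 15.0, "alive")])
        obs = compute_growth_observations(census_from_frame(df, 10.0))
        assert obs["agr_mm_yr"].iloc[0] == 0.0
        assert obs["log_agr1"].iloc[0] == 0.0

    def test_shrinkage_clamped_and_counted(self):
        df = _census_df([("a", "s1", 0, 0.0, 15.0, "alive"),
                         ("a", "s1", 1, 10.0, 14.8, "alive")])
        obs = compute_growth_observations(census_from_frame(df, 10.0))
        assert obs["agr_mm_yr"].iloc[0] == 0.0
        assert bool(obs["clamped"].iloc[0])
        assert obs.attrs["n_clamped"] == 1

    def test_one_observation_per_alive_pair(self, small_sim):
        """Brute-force recount of alive->alive consecutive pairs."""
        census = small_sim.census
        obs = compute_growth_observations(census)
        n_pairs = 0
        for _, grp in census.usable_frame().groupby("tree_id"):
            st_ = grp["status"].tolist()
            ti = grp["time_index"].tolist()
            for j in range(1, len(st_)):
                if st_[j - 1] == st_[j] == "alive" and ti[j] - ti[j - 1] == 1:
                    n_pairs += 1
        assert len(obs) == n_pairs


class TestUnitsAndTypes:
    @given(st.floats(5.0, 300.0), st.floats(-0.5, 5.0))
    @settings(max_examples=50, deadline=None)
    def test_increment_is_mm_per_year(self, d0, delta):
        agr = annualized_increment_mm(d0, d0 + delta, 10.0)
        assert agr == pytest.approx(delta, abs=1e-9)  # cm over 10 yr -> mm/yr

    def test_conversions(self):
        assert m_to_cm(0.5) == 50.0
        assert cm_to_mm(1.2) == 12.0

    def test_trait_vector_invariants(self):
        with pytest.raises(ParameterError):
            TraitVector(dbh95=-0.1, hmax=3.0, ortho=0, wd=0.6, tough=5.0, d13c=-3.0)
        with pytest.raises(ParameterError):
            TraitVector(dbh95=0.5, hmax=3.0, ortho=2, wd=0.6, tough=5.0, d13c=-3.0)

    def test_joint_params_gamma_masks_effective_value(self):
        p = JointParams(beta4=1.5)
        p.gamma["beta4"] = 0
        assert p.effective("beta4") == 0.0
        assert p.beta_eff()[4] == 0.0
        with pytest.raises(ParameterError):
            JointParams(sigma=-1.0)

    def test_joint_params_series_roundtrip(self, ref_params):
        s = ref_params.as_series()
        back = JointParams.from_mapping(s.to_dict())
        assert back == ref_params
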