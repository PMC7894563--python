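import numpy as np
import pandas as pd
import pytest

from phenomatch.design import (ModelSpec, build_bivariate_design,
                               build_design, build_diet_design)


def toy_breeding():
    return pd.DataFrame({
        "year": [2000, 2000, 2000, 2001, 2001],
        "nest_id": ["a", "b", "c", "d", "e"],
        "lay_date": [100, 110, 120, 130, 140],
        "n_fledged": [4, 2, 0, 3, 1],
    })


def toy_context():
    return pd.DataFrame({
        "year": [2000, 2001],
        "sst": [5.5, 6.5],
        "sst_prev": [5.0, 5.5],
        "population_size": [1000, 1100],
    })


class TestBreedingDesign:
    def test_relative_column_is_centred(self):
        d = build_design(toy_breeding(), None, ModelSpec("core"))
        rel = d.X[:, d.colnames.index("rel_laydate")]
        np.testing.assert_allclose(rel[:3], [-10, 0, 10])
        np.testing.assert_allclose(rel[3:], [-5, 5])

    def test_centring_sums_to_zero_per_year(self):
        rng = np.random.default_rng(0)
        df = pd.DataFrame({
            "year": np.repeat([1990, 1991, 1995], 50),
            "nest_id": np.arange(150).astype(str),
            "lay_date": rng.integers(80, 180, size=150),
            "n_fledged": rng.integers(0, 5, size=150),
        })
        d = build_design(df, None, ModelSpec("core"))
        rel = d.X[:, d.colnames.index("rel_laydate")]
        for y in (1990, 1991, 1995):
            assert abs(rel[df["year"] == y].sum()) < 1e-9

    def test_core_roster(self):
        d = build_design(toy_breeding(), None, ModelSpec("core"))
        assert d.colnames == ["intercept", "mean_laydate", "rel_laydate",
                              "rel_laydate_sq"]

    def test_year_variant_adds_exactly_two_columns(self):
        core = build_design(toy_breeding(), None, ModelSpec("core"))
        year = build_design(toy_breeding(), None, ModelSpec("year"))
        assert set(year.colnames) - set(core.colnames) == \
            {"year_c", "rel_x_year"}

    @pytest.mark.parametrize("variant,extra", [
        ("sst_current", {"year_c", "sst_c", "rel_x_sst"}),
        ("sst_previous", {"year_c", "sst_prev_c", "rel_x_sst_prev"}),
        ("core_popsize", {"log_popsize"}),
    ])
    def test_covariate_variants(self, variant, extra):
        core = build_design(toy_breeding(), toy_context(),
                            ModelSpec("core"))
        d = build_design(toy_breeding(), toy_context(), ModelSpec(variant))
        assert set(d.colnames) - set(core.colnames) == extra

    def test_missing_context_year_reported(self):
        ctx = toy_context().iloc[:1]
        with pytest.raises(ValueError, match="2001"):
            build_design(toy_breeding(), ctx, ModelSpec("sst_current"))

    def test_fledged_out_of_range_rejected(self):
        bad = toy_breeding()
        bad.loc[2, "n_fledged"] = 5
        with pytest.raises(ValueError, match="0..4"):
            build_design(bad, None, ModelSpec("core"))

    def test_unknown_variant_rejected(self):
        with pytest.raises(ValueError, match="variant"):
            ModelSpec("quadratic_only")

    def test_binomial_response_layout(self):
        d = build_design(toy_breeding(), None, ModelSpec("core"))
        assert (d.family == "binomial").all()
        np.testing.assert_allclose(d.trials, 4.0)
        np.testing.assert_allclose(d.y, [4, 2, 0, 3, 1])


class TestDietDesign:
    def toy(self):
        return pd.DataFrame({
            "year": [2000, 2000, 2001, 2001, 2002, 2002],
            "sample_date": [150, 170, 140, 160, 150, 150],
            "prop_oneplus": [0.9, 0.5, 1.0, 0.3, 0.7, 0.6],
        })

    def test_core_columns_and_centring(self):
        d = build_diet_design(self.toy(), "sandeel_core")
        assert d.colnames == ["intercept", "mean_sample_date",
                              "rel_sample_date"]
        rel = d.X[:, 2]
        np.testing.assert_allclose(rel, [-10, 10, -10, 10, 0, 0])

    def test_year_variant_interaction(self):
        d = build_diet_design(self.toy(), "sandeel_year")
        assert "rel_x_year" in d.colnames
        assert "mean_sample_date" not in d.colnames

    def test_response_is_offset_logit(self):
        from phenomatch.transforms import logit_offset
        d = build_diet_design(self.toy(), "sandeel_core")
        np.testing.assert_allclose(
            d.y, logit_offset(self.toy()["prop_oneplus"].to_numpy()))


class TestBivariateDesign:
    def test_requires_overlap(self):
        breeding = toy_breeding()
        diet = pd.DataFrame({"year": [1980, 1981, 1982],
                             "sample_date": [150, 150, 150],
                             "prop_oneplus": [0.5, 0.5, 0.5]})
        with pytest.raises(ValueError, match="overlap"):
            build_bivariate_design(breeding, diet)

    def test_structure(self):
        breeding = pd.DataFrame({
            "year": np.repeat([2000, 2001, 2002], 3),
            "nest_id": np.arange(9).astype(str),
            "lay_date": [100, 110, 120, 130, 140, 150, 120, 125, 130],
            "n_fledged": [4, 2, 0, 3, 1, 2, 2, 3, 1],
        })
        diet = pd.DataFrame({
            "year": [2000, 2000, 2001, 2002, 2003],
            "sample_date": [150, 160, 170, 150, 160],
            "prop_oneplus": [0.9, 0.5, 1.0, 0.3, 0.7],
        })
        d, info = build_bivariate_design(breeding, diet)
        assert d.re_names == ["B_Sh", "B_Sa", "W_Sh", "W_Sa"]
        # quadratic column present only for breeding-trait rows
        sq = d.X[:, d.colnames.index("sh_rel_laydate_sq")]
        assert np.all(sq[9:] == 0)
        # diet-only year 2003 fell back to its own sample dates
        assert info["fallback_centre_years"] == [2003]
        # diet relative timing centred on the year's mean lay date
        rel_d = d.X[9:, d.colnames.index("sa_rel_laydate")]
        assert rel_d[0] == 150 - 110  # year 2000 mean lay date is 110
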