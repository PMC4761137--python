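"""Indirect standardization and PCA deprivation indices."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from riskmap.standardize import (
    deprivation_indices,
    expected_counts,
    person_years,
    provincial_rates,
)
from riskmap.types import CaseRecord, SchemaError


def case(sex="M", age="60-64", year=2000, i=[0]):
    i[0] += 1
    return CaseRecord(case_id=f"c{i[0]}", site="bladder", behaviour="invasive",
                      sex=sex, age_group=age, year=year, precision="exact",
                      point=(0.0, 0.0))


def pop_frame(rows):
    return pd.DataFrame(rows, columns=["region_id", "census_year", "sex",
                                       "age_group", "count"])


class TestPersonYears:
    def test_count_times_window_years(self):
        pop = pop_frame([("r1", 2001, "M", "60-64", 100)])
        py = person_years(pop, range(1999, 2004))
        assert py["person_years"].iloc[0] == 500.0

    def test_uncovered_year_raises_naming_it(self):
        pop = pop_frame([("r1", 2001, "M", "60-64", 100)])
        with pytest.raises(SchemaError, match="2020"):
            person_years(pop, [2020], census_years=[2001])

    def test_multi_census_matches_year_by_year_sum(self):
        pop = pop_frame([("r1", c, s, a, 50 + 10 * k)
                         for k, c in enumerate([1996, 2001, 2006])
                         for s in ("M", "F") for a in ("60-64", "65-69")])
        years = range(1995, 2009)
        py = person_years(pop, years)
        # brute force: one census lookup per year
        brute = {}
        for y in years:
            c = min([1996, 2001, 2006], key=lambda cc: abs(cc - y))
            sub = pop[pop["census_year"] == c]
            for _, r in sub.iterrows():
                key = (r["region_id"], r["sex"], r["age_group"])
                brute[key] = brute.get(key, 0) + r["count"]
        for _, r in py.iterrows():
            assert r["person_years"] == brute[(r["region_id"], r["sex"],
                                               r["age_group"])]


class TestRatesAndExpected:
    def test_rate_is_cases_over_person_years(self):
        cases = [case(), case()]
        py = pd.DataFrame([("r1", "M", "60-64", 1000.0)],
                          columns=["region_id", "sex", "age_group",
                                   "person_years"])
        rates = provincial_rates(cases, py, sex="M")
        r = rates.set_index(["sex", "age_group"]).loc[("M", "60-64"), "rate"]
        assert r == pytest.approx(0.002)
        assert (rates[rates["age_group"] != "60-64"]["rate"] == 0).all()

    def test_zero_py_with_cases_raises(self):
        py = pd.DataFrame([("r1", "M", "65-69", 1000.0)],
                          columns=["region_id", "sex", "age_group",
                                   "person_years"])
        with pytest.raises(SchemaError):
            provincial_rates([case()], py, sex="M")

    def test_self_standardization_closure(self, small_study):
        """Sum of E_i equals the observed total when rates come from the
        same data."""
        s = small_study
        geo = s["geography"]
        region_to_comm = {}
        for r in geo.fine.regions:
            cid = geo.fine_to_community.get((r.region_id, r.period_validity))
            region_to_comm[r.region_id] = cid or geo.communities.ids()[0]
        E = expected_counts(s["py"], s["rates"], region_to_comm)
        assert E.sum() == pytest.approx(len(s["cases"]), rel=1e-9)
        assert (E > 0).all()

    def test_five_region_fixture_matches_double_loop(self):
        rng = np.random.default_rng(0)
        regions = [f"r{i}" for i in range(5)]
        strata = [("M", "60-64"), ("M", "65-69"), ("F", "60-64")]
        py_rows = [(r, s, a, float(rng.integers(100, 2000)))
                   for r in regions for (s, a) in strata]
        py = pd.DataFrame(py_rows, columns=["region_id", "sex", "age_group",
                                            "person_years"])
        rates = pd.DataFrame([(s, a, rng.uniform(1e-4, 1e-3))
                              for (s, a) in strata],
                             columns=["sex", "age_group", "rate"])
        # pad remaining strata with zero rates
        from riskmap.types import AGE_GROUPS
        extra = [(s, a, 0.0) for s in ("M", "F") for a in AGE_GROUPS
                 if (s, a) not in strata]
        rates = pd.concat([rates, pd.DataFrame(
            extra, columns=["sex", "age_group", "rate"])])
        mapping = {r: ("c0" if i < 2 else "c1") for i, r in enumerate(regions)}
        E = expected_counts(py, rates, mapping)
        brute = {"c0": 0.0, "c1": 0.0}
        rmap = rates.set_index(["sex", "age_group"])["rate"]
        for _, row in py.iterrows():
            brute[mapping[row["region_id"]]] += \
                row["person_years"] * rmap[(row["sex"], row["age_group"])]
        assert E["c0"] == pytest.approx(brute["c0"], rel=1e-12)
        assert E["c1"] == pytest.approx(brute["c1"], rel=1e-12)


def indicator_frame(n=20, seed=0):
    rng = np.random.default_rng(seed)
    f_m, f_s = rng.normal(size=n), rng.normal(size=n)
    return pd.DataFrame({
        "community_id": [f"c{i}" for i in range(n)],
        "no_highschool_pct": 30 + 8 * (0.8 * f_m + 0.4 * rng.normal(size=n)),
        "avg_income": 35_000 - 5_000 * (0.8 * f_m + 0.4 * rng.normal(size=n)),
        "employment_rate": 60 - 6 * (0.8 * f_m + 0.4 * rng.normal(size=n)),
        "sep_div_wid_pct": 12 + 3 * (0.8 * f_s + 0.4 * rng.normal(size=n)),
        "single_parent_pct": 15 + 4 * (0.8 * f_s + 0.4 * rng.normal(size=n)),
        "living_alone_pct": 10 + 3 * (0.8 * f_s + 0.4 * rng.normal(size=n)),
    })


class TestDeprivationIndices:
    def test_scores_centred_and_oriented(self):
        idx = deprivation_indices(indicator_frame())
        assert idx.material.mean() == pytest.approx(0.0, abs=1e-10)
        assert idx.social.mean() == pytest.approx(0.0, abs=1e-10)
        # higher no-highschool should mean more deprived
        df = indicator_frame()
        r = np.corrcoef(idx.material, df["no_highschool_pct"])[0, 1]
        assert r > 0

    def test_identical_rows_give_zero_scores(self):
        df = indicator_frame(5)
        for c in df.columns[1:]:
            df[c] = 1.0
        with pytest.warns(UserWarning):
            idx = deprivation_indices(df)
        assert np.allclose(idx.material, 0.0)
        assert np.allclose(idx.social, 0.0)

    def test_matches_eigendecomposition_oracle(self):
        df = indicator_frame(20, seed=3)
        idx = deprivation_indices(df)
        # independent oracle: numpy eig of the correlation matrix of the
        # sign-adjusted z-scored material indicators
        M = np.column_stack([
            df["no_highschool_pct"], -df["avg_income"], -df["employment_rate"]])
        Z = (M - M.mean(0)) / M.std(0)
        evals, evecs = np.linalg.eig(np.corrcoef(Z.T))
        v = evecs[:, np.argmax(evals)]
        if v.sum() < 0:
            v = -v
        oracle = Z @ v
        oracle -= oracle.mean()
        np.testing.assert_allclose(idx.material.values, oracle, atol=1e-10)

    @given(st.floats(0.1, 50.0), st.floats(-1000.0, 1000.0))
    def test_affine_invariance(self, scale, shift):
        df = indicator_frame(15, seed=7)
        idx0 = deprivation_indices(df)
        df2 = df.copy()
        df2["single_parent_pct"] = df2["single_parent_pct"] * scale + shift
        idx1 = deprivation_indices(df2)
        np.testing.assert_allclose(idx1.social.values, idx0.social.values,
                                   atol=1e-8)
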