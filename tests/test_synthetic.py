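"""Generator properties: geography nesting, population, case simulation,
geocode censoring and covariates."""

import numpy as np
import pytest
from shapely.ops import unary_union

from conftest import small_scenario
from riskmap.synthetic import (
    RiskField,
    Scenario,
    TruthBundle,
    censor_geocodes,
    default_stratum_rates,
    make_covariates,
    make_geography,
    make_population,
    simulate_cases,
)
from riskmap.types import SchemaError


class TestGeography:
    def test_four_communities_tile_the_area(self):
        sc = small_scenario(n_communities=4, n_coarse=2,
                            fine_region_targets={2011: 8})
        geo = make_geography(sc)
        assert len(geo.communities) == 4
        union = unary_union([r.polygon for r in geo.communities.regions])
        area = sc.study_area[0] * sc.study_area[1]
        assert abs(union.area - area) / area < 1e-9

    def test_too_few_communities_rejected(self):
        with pytest.raises(SchemaError):
            small_scenario(n_communities=3)

    def test_fine_regions_nest_in_communities(self, small_geography):
        sc, geo = small_geography
        comm = {r.region_id: r.polygon for r in geo.communities.regions}
        n_checked = 0
        for r in geo.fine.regions:
            cid = geo.fine_to_community.get((r.region_id, r.period_validity))
            if cid is None:
                continue  # grouped early-period region
            pt = r.polygon.representative_point()
            assert comm[cid].buffer(1e-6).contains(pt)
            n_checked += 1
        assert n_checked > 0

    def test_fine_centroid_in_exactly_one_community(self, small_geography):
        sc, geo = small_geography
        polys = [r.polygon for r in geo.communities.regions]
        for r in geo.fine.regions[:50]:
            pt = r.polygon.representative_point()
            hits = sum(p.contains(pt) for p in polys)
            assert hits == 1

    def test_default_scenario_has_311_communities(self):
        geo = make_geography(Scenario(seed=0), include_fine=False)
        assert len(geo.communities) == 311

    def test_deterministic_under_seed(self):
        sc = small_scenario(n_communities=8, fine_region_targets={2011: 20})
        a = make_geography(sc)
        b = make_geography(sc)
        for r1, r2 in zip(a.fine.regions, b.fine.regions):
            assert r1.region_id == r2.region_id
            assert r1.polygon.equals(r2.polygon)


class TestPopulation:
    def test_counts_nonnegative_integers_reproducible(self, small_study):
        pop = small_study["population"]
        assert (pop["count"] >= 0).all()
        assert (pop["count"] == pop["count"].astype(int)).all()
        again = make_population(small_study["scenario"],
                                small_study["geography"])
        assert pop.equals(again)

    def test_subdivision_totals_in_plausible_range(self, small_study):
        pop = small_study["population"]
        sc, geo = small_study["scenario"], small_study["geography"]
        late = pop[pop["census_year"] == 2011]
        totals = late.groupby("region_id")["count"].sum()
        nested = {fid for (fid, per), cid in geo.fine_to_community.items()
                  if cid is not None and per == (2009, 2013)}
        t = totals[totals.index.isin(nested)]
        assert t.between(200, 1400).all()


class TestSimulateCases:
    def test_zero_risk_gives_zero_cases(self, small_study):
        s = small_study
        truth = TruthBundle(risk_field=RiskField(kind="constant", amplitude=0.0))
        cases = simulate_cases(s["scenario"], s["population"], s["geography"],
                               s["grid"], truth, seed=0)
        assert cases == []

    def test_total_count_matches_poisson_expectation(self, small_study):
        s = small_study
        truth = TruthBundle(risk_field=RiskField())
        expected = None
        hits = 0
        n_seeds = 10
        for seed in range(n_seeds):
            cases = simulate_cases(s["scenario"], s["population"],
                                   s["geography"], s["grid"], truth, seed=seed)
            if expected is None:
                # expected total under lambda=1: population x rate x years
                rates = s["scenario"].rates()
                exp = 0.0
                pop = s["population"]
                for c in sorted(pop["census_year"].unique()):
                    yrs = len([t for t in range(1980, 2011) if abs(t - c) <= 2])
                    sub = pop[pop["census_year"] == c]
                    exp += sum(cnt * rates[(sx, ag)] * yrs
                               for cnt, sx, ag in zip(sub["count"], sub["sex"],
                                                      sub["age_group"]))
                expected = exp
            if abs(len(cases) - expected) <= 4 * np.sqrt(expected):
                hits += 1
        assert hits >= 8

    def test_bump_doubles_local_case_density(self, small_study):
        s = small_study
        sc = small_scenario(baseline_rates={
            k: v * 8 for k, v in default_stratum_rates("bladder").items()})
        truth = TruthBundle(risk_field=RiskField(
            kind="one_bump", amplitude=2.0, centers=((40_000.0, 40_000.0),),
            scale_m=25_000.0))
        cases = simulate_cases(sc, s["population"], s["geography"], s["grid"],
                               truth, seed=3)
        assert len(cases) > 3000
        # compare case rate per unit expected inside vs far outside the bump
        from riskmap.localem import build_offset
        offset, _ = build_offset(s["population"], s["rates"],
                                 s["geography"].fine, s["grid"], (1980, 2010))
        mu = offset.expected_counts().sum(axis=0)
        X, Y = s["grid"].centers()
        d2 = (X - 40_000.0) ** 2 + (Y - 40_000.0) ** 2
        inside = d2 < 10_000.0 ** 2
        outside = d2 > 60_000.0 ** 2
        counts = np.zeros(s["grid"].shape)
        for c in cases:
            r, col = s["grid"].cell_of(*c.point)
            counts[r, col] += 1
        ratio = (counts[inside].sum() / mu[inside].sum()) \
            / (counts[outside].sum() / mu[outside].sum())
        assert 1.8 < ratio < 2.2


class TestCensoring:
    def test_all_exact_mix_is_identity(self, small_study):
        s = small_study
        sc = small_scenario(geocode_mix={"recent": (1.0, 0.0, 0.0),
                                         "early": (1.0, 0.0, 0.0)})
        out = censor_geocodes(s["exact_cases"], sc, s["geography"], seed=0)
        assert out == s["exact_cases"]

    def test_counts_and_attributes_preserved(self, small_study):
        s = small_study
        exact, cens = s["exact_cases"], s["cases"]
        assert len(exact) == len(cens)
        for a, b in zip(exact, cens):
            assert (a.case_id, a.site, a.sex, a.year, a.age_group) == \
                (b.case_id, b.site, b.sex, b.year, b.age_group)

    def test_region_sets_contain_true_region(self, small_study):
        s = small_study
        from shapely.geometry import Point
        fine = {(r.region_id, r.period_validity): r.polygon
                for r in s["geography"].fine.regions}
        checked = 0
        for c in s["cases"]:
            if c.precision != "region_set":
                continue
            pt = Point(*c.true_point)
            assert any(fine[(rid, per)].buffer(1e-9).contains(pt)
                       for (rid, per) in fine if rid in c.candidate_regions)
            checked += 1
        assert checked > 10

    def test_empirical_mix_matches_table_proportions(self, small_study):
        s = small_study
        sc = small_scenario(baseline_rates={
            k: v * 24 for k, v in default_stratum_rates("bladder").items()},
            study_years=(1998, 2010))
        truth = TruthBundle(risk_field=RiskField())
        cases = simulate_cases(sc, s["population"], s["geography"], s["grid"],
                               truth, seed=9)
        cens = censor_geocodes(cases, sc, s["geography"], seed=10)
        n = len(cens)
        assert n > 4000
        shares = {p: sum(c.precision == p for c in cens) / n
                  for p in ("exact", "region_set", "coarse")}
        assert abs(shares["exact"] - 0.866) < 0.015
        assert abs(shares["region_set"] - 0.023) < 0.015
        assert abs(shares["coarse"] - 0.111) < 0.015

    def test_invalid_mix_rejected(self):
        with pytest.raises(SchemaError):
            small_scenario(geocode_mix={"recent": (0.9, 0.3, 0.1),
                                        "early": (1.0, 0.0, 0.0)})


class TestCovariates:
    def test_zero_noise_gives_collinear_indicators(self, small_study):
        sc = small_scenario(covariate_noise_sd=0.0)
        df, truth = make_covariates(sc, small_study["geography"].communities, 3)
        r = np.corrcoef(df["no_highschool_pct"], truth.latent_material)[0, 1]
        assert r > 0.999999

    def test_default_loadings_give_correlated_indicators(self, small_study):
        df = small_study["covariates"]
        for a, b in [("no_highschool_pct", "avg_income"),
                     ("sep_div_wid_pct", "living_alone_pct")]:
            assert abs(np.corrcoef(df[a], df[b])[0, 1]) > 0.3

    def test_well_water_within_percent_range(self, small_study):
        w = small_study["covariates"]["well_water_pct"]
        assert (w >= 0).all() and (w <= 100).all()


class TestGeneratorEstimatorConsistency:
    def test_community_sir_recovers_mean_risk(self, small_study):
        """Aggregated simulated counts / standardized expecteds track the
        mean of the latent risk surface."""
        s = small_study
        sc = small_scenario(baseline_rates={
            k: v * 20 for k, v in default_stratum_rates("bladder").items()})
        truth = TruthBundle(risk_field=RiskField(
            kind="one_bump", amplitude=2.0, centers=((40_000.0, 40_000.0),),
            scale_m=25_000.0))
        cases = simulate_cases(sc, s["population"], s["geography"], s["grid"],
                               truth, seed=4)
        from riskmap.localem import build_offset
        offset, _ = build_offset(s["population"], s["rates"],
                                 s["geography"].fine, s["grid"], (1980, 2010))
        mu = offset.expected_counts().sum(axis=0) * 20  # rates were scaled
        X, Y = s["grid"].centers()
        lam_true = truth.risk_field.evaluate(X, Y, 1995)
        # global closure: observed / risk-weighted expected ~ 1
        expected_under_truth = float((mu * lam_true).sum())
        rel_err = abs(len(cases) - expected_under_truth) / expected_under_truth
        assert rel_err < 0.1
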