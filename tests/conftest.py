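import pytest
from hypothesis import settings

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=25)
settings.load_profile("ci")

from riskmap.localem import RegionIndex, build_offset
from riskmap.raster import rasterize
from riskmap.standardize import person_years, provincial_rates
from riskmap.synthetic import (
    RiskField,
    Scenario,
    TruthBundle,
    censor_geocodes,
    make_covariates,
    make_geography,
    make_population,
    simulate_cases,
)
from riskmap.types import GridSpec

SMALL_FINE_TARGETS = {1981: 12, 1986: 12, 1991: 90, 1996: 90, 2001: 90,
                      2006: 90, 2011: 90}


def small_scenario(**kw) -> Scenario:
    base = dict(seed=1, n_communities=30, n_coarse=4,
                study_area=(120_000.0, 80_000.0),
                fine_region_targets=dict(SMALL_FINE_TARGETS),
                study_years=(1980, 2010))
    base.update(kw)
    return Scenario(**base)


@pytest.fixture(scope="session")
def small_geography():
    sc = small_scenario()
    return sc, make_geography(sc)


@pytest.fixture(scope="session")
def small_study(small_geography):
    """A complete small synthetic study shared across the suite."""
    sc, geo = small_geography
    pop = make_population(sc, geo)
    grid = GridSpec(0.0, 0.0, 2000.0, 60, 40)
    truth = TruthBundle(risk_field=RiskField(
        kind="one_bump", amplitude=2.0, centers=((40_000.0, 40_000.0),),
        scale_m=15_000.0))
    exact = simulate_cases(sc, pop, geo, grid, truth, seed=5)
    cases = censor_geocodes(exact, sc, geo, seed=6)
    py = person_years(pop, range(1980, 2011))
    rates = provincial_rates(cases, py)
    offset, fine_rasters = build_offset(pop, rates, geo.fine, grid, (1980, 2010))
    index = RegionIndex(fine=fine_rasters,
                        coarse=rasterize(geo.coarse.regions, grid))
    cov, cov_truth = make_covariates(sc, geo.communities, 7)
    return dict(scenario=sc, geography=geo, population=pop, grid=grid,
                truth=truth, exact_cases=exact, cases=cases, py=py,
                rates=rates, offset=offset, index=index,
                covariates=cov, cov_truth=cov_truth)
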