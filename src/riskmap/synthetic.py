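"""Synthetic cancer-registry generator.

Builds a fully synthetic study — nested geographies, census populations,
socioeconomic covariates, and case records drawn from a known relative-risk
surface with realistic geocode censoring — so that every downstream stage
(standardization, BYM, local-EM, bootstrap inference) can be exercised and
validated against known ground truth without any confidential data.

The default :class:`Scenario` emulates the structure of the Nova Scotia
registry setting: 311 community units grouped into 18 coarse divisions,
time-varying fine census regions (~115 units in the 1981/1986 censuses,
1379-1645 later), populations uniform within the inhabited portion of each
fine region, adult (20+) five-year age bands, and a geocode-precision mix of
exact points, postal-code region sets and coarse-division censoring that
differs between the pre-1998 and 1998+ eras.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import shapely
from scipy.cluster.vq import kmeans2
from shapely.geometry import MultiPoint, Point, box
from shapely.ops import unary_union, voronoi_diagram
from shapely.strtree import STRtree

from .raster import rasterize, region_adjacency, require_population_cells
from .types import (
    AGE_GROUPS,
    CENSUS_YEARS,
    CaseRecord,
    GridSpec,
    Region,
    RegionSet,
    SchemaError,
    age_group_midpoint,
    census_year_for,
)

ERA_SPLIT_YEAR = 1998

#: adult (20+) age-band population shares, oldest bands thinnest
_AGE_WEIGHTS = np.array([8.5, 8.5, 8.5, 8.5, 8.0, 7.5, 7.0, 6.5,
                         6.0, 5.5, 4.5, 3.5, 2.5, 2.0])
AGE_SHARES = _AGE_WEIGHTS / _AGE_WEIGHTS.sum()

#: geocode mixes (exact, region_set, coarse) by era: the recent era reflects
#: predominantly civic-address geocoding; the early era is postal-code heavy.
DEFAULT_GEOCODE_MIX = {
    "recent": (0.866, 0.023, 0.111),
    "early": (0.436, 0.529, 0.035),
}

DEFAULT_FINE_TARGETS = {1981: 113, 1986: 118, 1991: 1379, 1996: 1450,
                        2001: 1500, 2006: 1550, 2011: 1645}


@dataclass
class RiskField:
    """Latent relative-risk surface lambda(s, t).

    ``amplitude`` is the peak relative risk of a bump (2.0 means risk doubled
    at the bump centre); ``scale_m`` the Gaussian spatial scale of a bump;
    ``drift_per_year`` multiplies the log-excess linearly in time, centred on
    ``drift_ref_year``.
    """

    kind: str = "constant"
    amplitude: float = 1.0
    centers: tuple[tuple[float, float], ...] = ()
    scale_m: float = 20_000.0
    drift_per_year: float = 0.0
    drift_ref_year: int = 1995

    def __post_init__(self):
        if self.kind not in ("constant", "one_bump", "two_bump", "gradient"):
            raise SchemaError(f"unknown risk field kind {self.kind!r}")
        if self.amplitude < 0:
            raise SchemaError("risk amplitude must be >= 0")

    def evaluate(self, X: np.ndarray, Y: np.ndarray, year: float) -> np.ndarray:
        X = np.asarray(X, float)
        Y = np.asarray(Y, float)
        tfac = 1.0 + self.drift_per_year * (year - self.drift_ref_year)
        tfac = max(tfac, 0.0)
        if self.kind == "constant":
            lam = np.full(X.shape, self.amplitude)
        elif self.kind == "gradient":
            span = np.ptp(X) or 1.0
            lam = 1.0 + (self.amplitude - 1.0) * tfac * (X - X.min()) / span
        else:
            lam = np.ones(X.shape)
            for cx, cy in self.centers:
                bump = np.exp(-((X - cx) ** 2 + (Y - cy) ** 2)
                              / (2 * self.scale_m ** 2))
                lam = lam + (self.amplitude - 1.0) * tfac * bump
        lam = np.maximum(lam, 1e-12)
        if not np.all(np.isfinite(lam)):
            raise SchemaError("risk field evaluated to non-finite values")
        return lam


def default_stratum_rates(site: str = "bladder",
                          total_cases: Optional[float] = None,
                          adult_population: float = 720_000.0,
                          n_years: float = 13.0) -> dict[tuple[str, str], float]:
    """Annual per-person incidence rates by (sex, age band).

    Calibrated so that a province-scale adult population over a 13-year
    window yields roughly 3,200 bladder-like or 2,100 kidney-like cases, with
    male:female crude ratios of about 2.9 and 1.5 respectively, and incidence
    rising steeply with age as urinary-tract cancers do.
    """
    if total_cases is None:
        total_cases = {"bladder": 3232.0, "kidney": 2143.0}[site]
    mf_ratio = {"bladder": 2.9, "kidney": 1.5}[site]
    crude = total_cases / (adult_population * n_years)
    mids = np.array([22.0 + 5 * i for i in range(13)] + [87.5])
    age_mult = np.exp(0.07 * (mids - 70.0))
    sex_mult = {"M": 2 * mf_ratio / (1 + mf_ratio), "F": 2 / (1 + mf_ratio)}
    # population-weighted mean multiplier, equal sexes within each band
    mean_mult = float(np.sum(AGE_SHARES * age_mult)) * 0.5 * (sex_mult["M"] + sex_mult["F"])
    k = crude / mean_mult
    return {(sex, ag): k * age_mult[i] * sex_mult[sex]
            for sex in ("M", "F") for i, ag in enumerate(AGE_GROUPS)}


@dataclass
class Scenario:
    """All knobs of the synthetic study, with defaults set to the
    province-scale conditions the package is designed around."""

    seed: int = 0
    site: str = "bladder"
    n_communities: int = 311
    n_coarse: int = 18
    study_area: tuple[float, float] = (300_000.0, 180_000.0)
    study_years: tuple[int, int] = (1980, 2010)
    census_years: tuple[int, ...] = CENSUS_YEARS
    fine_region_targets: dict[int, int] = field(
        default_factory=lambda: dict(DEFAULT_FINE_TARGETS))
    fine_pop_range: tuple[float, float] = (400.0, 700.0)
    community_pop_cap: float = 30_900.0
    baseline_rates: Optional[dict[tuple[str, str], float]] = None
    risk_field: RiskField = field(default_factory=RiskField)
    geocode_mix: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_GEOCODE_MIX))
    censoring_set_sizes: tuple[int, ...] = (1, 2, 3, 4)
    uninhabited_share: float = 0.2
    covariate_loading: float = 0.8
    covariate_noise_sd: float = 0.6
    in_situ_prob: dict[str, float] = field(
        default_factory=lambda: {"recent": 0.36, "early": 0.08})

    def __post_init__(self):
        for era, mix in self.geocode_mix.items():
            if abs(sum(mix) - 1.0) > 1e-9 or any(p < 0 for p in mix):
                raise SchemaError(f"geocode mix for era {era!r} is not a distribution")
        if self.baseline_rates is not None:
            if any(r <= 0 for r in self.baseline_rates.values()):
                raise SchemaError("baseline rates must be > 0")
        if self.n_communities < 4:
            raise SchemaError("need at least 4 communities")

    def rates(self) -> dict[tuple[str, str], float]:
        if self.baseline_rates is not None:
            return self.baseline_rates
        return default_stratum_rates(self.site)

    def era_of(self, year: int) -> str:
        return "recent" if year >= ERA_SPLIT_YEAR else "early"


@dataclass
class Geography:
    communities: RegionSet
    fine: RegionSet
    coarse: RegionSet
    #: community id containing each fine region (late periods only)
    fine_to_community: dict[tuple[str, tuple[int, int]], Optional[str]]
    #: coarse division of each community
    community_to_coarse: dict[str, str]


@dataclass
class TruthBundle:
    """Ground truth retained by the generator for recovery testing only."""

    risk_field: Optional[RiskField] = None
    latent_material: Optional[pd.Series] = None
    latent_social: Optional[pd.Series] = None
    bym_params: Optional[dict] = None
    S: Optional[np.ndarray] = None
    V: Optional[np.ndarray] = None

    def lambda_on_grid(self, grid: GridSpec, year: float) -> np.ndarray:
        X, Y = grid.centers()
        return self.risk_field.evaluate(X, Y, year)


# --- geography --------------------------------------------------------------

def _voronoi_cells(points: np.ndarray, area) -> list:
    """Clipped Voronoi cells, one per input point, in input order."""
    mp = MultiPoint([Point(p) for p in points])
    raw = voronoi_diagram(mp, envelope=area.buffer(area.bounds[2] * 0.1))
    cells = [g.intersection(area) for g in raw.geoms]
    tree = STRtree(cells)
    ordered = [None] * len(points)
    for i, p in enumerate(points):
        hit = tree.query(Point(p), predicate="intersects")
        if hit.size == 0:
            raise SchemaError("voronoi cell lookup failed")
        ordered[i] = cells[int(hit[0])]
    return ordered


def _sample_in(polygon, n: int, rng: np.random.Generator) -> np.ndarray:
    minx, miny, maxx, maxy = polygon.bounds
    out = []
    while len(out) < n:
        cand = rng.uniform([minx, miny], [maxx, maxy], size=(max(4 * n, 16), 2))
        keep = shapely.contains_xy(polygon, cand[:, 0], cand[:, 1])
        out.extend(cand[keep].tolist())
    return np.array(out[:n])


def make_geography(scenario: Scenario, include_fine: bool = True) -> Geography:
    """Nested Voronoi-style tessellations of a rectangular study area.

    Late census periods subdivide communities so each fine region lies inside
    exactly one community; early periods (whose fine-region counts are below
    the community count, as with real census subdivisions) instead group
    whole communities within each coarse division.
    """
    rng = np.random.default_rng(scenario.seed)
    W, H = scenario.study_area
    area = box(0.0, 0.0, W, H)
    full_period = scenario.study_years

    pts = rng.uniform([0, 0], [W, H], size=(scenario.n_communities, 2))
    for _ in range(2):  # Lloyd relaxation for more regular communities
        cells = _voronoi_cells(pts, area)
        pts = np.array([[c.centroid.x, c.centroid.y] for c in cells])
    cells = _voronoi_cells(pts, area)
    comm_ids = [f"C{i:03d}" for i in range(scenario.n_communities)]
    communities = RegionSet("community", [
        Region(cid, cell, full_period) for cid, cell in zip(comm_ids, cells)])

    n_coarse = min(scenario.n_coarse, scenario.n_communities)
    _, labels = kmeans2(pts, n_coarse, minit="++", seed=int(rng.integers(2**31)))
    coarse_regions = []
    community_to_coarse = {}
    for d in range(n_coarse):
        members = np.flatnonzero(labels == d)
        if members.size == 0:
            continue
        did = f"D{d:02d}"
        poly = unary_union([cells[i] for i in members])
        coarse_regions.append(Region(did, poly, full_period))
        for i in members:
            community_to_coarse[comm_ids[i]] = did
    coarse = RegionSet("coarse_division", coarse_regions)

    fine_regions: list[Region] = []
    fine_to_community: dict[tuple[str, tuple[int, int]], Optional[str]] = {}
    if include_fine:
        # heavy-tailed community weights give the urban/rural size contrast
        weights = rng.lognormal(0.0, 0.9, size=scenario.n_communities)
        weights /= weights.sum()
        for c in scenario.census_years:
            if not (scenario.study_years[0] - 2 <= c <= scenario.study_years[1] + 2):
                continue
            target = scenario.fine_region_targets.get(c, scenario.n_communities * 4)
            period = (c - 2, c + 2)
            if target >= scenario.n_communities:
                alloc = np.maximum(1, np.round(target * weights)).astype(int)
                for i, cid in enumerate(comm_ids):
                    n_i = int(alloc[i])
                    if n_i == 1:
                        subs = [cells[i]]
                    else:
                        seeds = _sample_in(cells[i], n_i, rng)
                        # one Lloyd pass regularizes cell sizes so no
                        # subdivision degenerates into a sliver
                        subs = _voronoi_cells(seeds, cells[i])
                        seeds = np.array([[s.centroid.x, s.centroid.y]
                                          for s in subs])
                        subs = _voronoi_cells(seeds, cells[i])
                    for s, sub in enumerate(subs):
                        fid = f"F{c}-{cid}-{s:03d}"
                        fine_regions.append(Region(fid, sub, period,
                                                   _inhab_frac(rng, scenario)))
                        fine_to_community[(fid, period)] = cid
            else:
                # group whole communities within each coarse division
                for did in sorted({community_to_coarse[cid] for cid in comm_ids}):
                    members = [i for i, cid in enumerate(comm_ids)
                               if community_to_coarse[cid] == did]
                    g = max(1, round(target * len(members) / scenario.n_communities))
                    g = min(g, len(members))
                    if g == 1:
                        lab = np.zeros(len(members), int)
                    else:
                        _, lab = kmeans2(pts[members], g, minit="++",
                                         seed=int(rng.integers(2**31)))
                    for gi in range(g):
                        sel = [members[j] for j in np.flatnonzero(lab == gi)]
                        if not sel:
                            continue
                        fid = f"F{c}-{did}-{gi:03d}"
                        poly = unary_union([cells[i] for i in sel])
                        fine_regions.append(Region(fid, poly, period,
                                                   _inhab_frac(rng, scenario)))
                        fine_to_community[(fid, period)] = None
    fine = RegionSet("fine_census", fine_regions)
    return Geography(communities=communities, fine=fine, coarse=coarse,
                     fine_to_community=fine_to_community,
                     community_to_coarse=community_to_coarse)


def _inhab_frac(rng: np.random.Generator, scenario: Scenario) -> float:
    if rng.random() < scenario.uninhabited_share:
        return float(rng.uniform(0.6, 1.0))
    return 1.0


# --- population -------------------------------------------------------------

def _largest_remainder(totals: np.ndarray, shares: np.ndarray) -> np.ndarray:
    """Integer split of each row total across columns, preserving row sums."""
    raw = totals[:, None] * shares[None, :]
    base = np.floor(raw).astype(int)
    short = np.round(totals - base.sum(axis=1)).astype(int)
    frac = raw - base
    order = np.argsort(-frac, axis=1, kind="stable")
    for r in range(base.shape[0]):
        for c in order[r, :short[r]]:
            base[r, c] += 1
    return base


def make_population(scenario: Scenario, geography: Geography) -> pd.DataFrame:
    """Census population table: (region_id, census_year, sex, age_group, count).

    Fine-region totals for subdivision periods are drawn around 400-700
    persons; grouped-period totals follow from the member communities.
    Community totals are capped near the configured maximum.
    """
    rng = np.random.default_rng(scenario.seed + 1)
    lo, hi = scenario.fine_pop_range

    # base community totals: sum of plausible per-subdivision draws, using the
    # latest census geography to set each community's size
    latest = max(c for c in scenario.census_years
                 if scenario.fine_region_targets.get(c, 0) >= scenario.n_communities) \
        if any(v >= scenario.n_communities for v in scenario.fine_region_targets.values()) \
        else None
    comm_ids = geography.communities.ids()
    n_sub = {cid: 0 for cid in comm_ids}
    if latest is not None:
        for (fid, period), cid in geography.fine_to_community.items():
            if cid is not None and period == (latest - 2, latest + 2):
                n_sub[cid] += 1
    comm_total = {cid: min(scenario.community_pop_cap,
                           max(1, n_sub[cid]) * rng.uniform(lo, hi))
                  for cid in comm_ids}

    rows = []
    strata = [(sex, ag) for sex in ("M", "F") for ag in AGE_GROUPS]
    shares = np.concatenate([0.5 * AGE_SHARES, 0.5 * AGE_SHARES])
    for c in scenario.census_years:
        period = (c - 2, c + 2)
        regions = [r for r in geography.fine.regions if r.period_validity == period]
        if not regions:
            continue
        jitter = rng.lognormal(0.0, 0.03)
        totals = np.empty(len(regions))
        for k, r in enumerate(regions):
            cid = geography.fine_to_community.get((r.region_id, period))
            if cid is not None:
                base = comm_total[cid] / max(1, n_sub[cid])
                totals[k] = base * rng.uniform(0.85, 1.15)
            else:
                # grouped early-period region: sum of covered communities
                covered = [q for q in comm_ids
                           if r.polygon.contains(
                               geography.communities.regions[comm_ids.index(q)]
                               .polygon.representative_point())]
                totals[k] = sum(comm_total[q] for q in covered) * rng.uniform(0.95, 1.05)
        totals = np.round(totals * jitter)
        counts = _largest_remainder(totals, shares)
        for k, r in enumerate(regions):
            for s, (sex, ag) in enumerate(strata):
                rows.append((r.region_id, c, sex, ag, int(counts[k, s])))
    return pd.DataFrame(rows, columns=["region_id", "census_year", "sex",
                                       "age_group", "count"])


# --- cases ------------------------------------------------------------------

def simulate_cases(scenario: Scenario, population: pd.DataFrame,
                   geography: Geography, grid: GridSpec,
                   truth: TruthBundle, seed: int) -> list[CaseRecord]:
    """Draw exact-location case records from the latent risk surface.

    Per period and cell, counts are Poisson with mean
    (stratum rate x population in cell x years in window x lambda(cell, year));
    each case is then placed uniformly within its cell.
    """
    rng = np.random.default_rng(seed)
    rates = scenario.rates()
    field_ = truth.risk_field
    if field_ is None:
        raise SchemaError("truth bundle lacks a risk field")
    X, Y = grid.centers()
    y0, y1 = scenario.study_years
    cases: list[CaseRecord] = []
    seq = 0
    strata = [(sex, ag) for sex in ("M", "F") for ag in AGE_GROUPS]

    for c in scenario.census_years:
        period = (c - 2, c + 2)
        years = [t for t in range(max(y0, c - 2), min(y1, c + 2) + 1)]
        if not years:
            continue
        regions = [r for r in geography.fine.regions if r.period_validity == period]
        pop_c = population[population["census_year"] == c]
        if not regions or pop_c.empty:
            continue
        ras = rasterize(regions, grid)
        populated = set(pop_c.loc[pop_c["count"] > 0, "region_id"])
        require_population_cells(ras, populated & set(ras.ids))
        # per-region expected cases per year under lambda = 1, and stratum mix
        pivot = pop_c.pivot_table(index="region_id", columns=["sex", "age_group"],
                                  values="count", aggfunc="sum", fill_value=0)
        rate_vec = np.array([rates[s] for s in strata])
        pivot = pivot.reindex(columns=pd.MultiIndex.from_tuples(strata), fill_value=0)
        intensity = pivot.to_numpy() * rate_vec[None, :]
        region_rate = dict(zip(pivot.index, intensity.sum(axis=1)))
        region_mix = {rid: row / row.sum() if row.sum() > 0 else None
                      for rid, row in zip(pivot.index, intensity)}

        n_inhab = np.zeros(len(ras.ids))
        flat_idx = ras.index.ravel()
        inhab_flat = ras.inhabited.ravel()
        for k in range(len(ras.ids)):
            n_inhab[k] = np.sum((flat_idx == k) & inhab_flat)
        base = np.zeros(grid.shape[0] * grid.shape[1])
        for k, rid in enumerate(ras.ids):
            if rid in region_rate and n_inhab[k] > 0:
                sel = (flat_idx == k) & inhab_flat
                base[sel] = region_rate[rid] / n_inhab[k]
        base = base.reshape(grid.shape)

        for year in years:
            lam = field_.evaluate(X, Y, year)
            mean = base * lam
            counts = rng.poisson(mean)
            rr, cc = np.nonzero(counts)
            for r_i, c_i in zip(rr, cc):
                k = ras.index[r_i, c_i]
                rid = ras.ids[k]
                mix = region_mix.get(rid)
                for _ in range(counts[r_i, c_i]):
                    s_idx = int(rng.choice(len(strata), p=mix)) if mix is not None \
                        else int(rng.integers(len(strata)))
                    sex, ag = strata[s_idx]
                    x = grid.x0 + (c_i + rng.random()) * grid.delta
                    y = grid.y0 + (r_i + rng.random()) * grid.delta
                    behaviour = "invasive"
                    if scenario.site == "bladder":
                        p_is = scenario.in_situ_prob[scenario.era_of(year)]
                        if rng.random() < p_is:
                            behaviour = "in_situ"
                    cases.append(CaseRecord(
                        case_id=f"{scenario.site[:2]}{seq:06d}", site=scenario.site,
                        behaviour=behaviour, sex=sex, age_group=ag, year=year,
                        precision="exact", point=(x, y), true_point=(x, y)))
                    seq += 1
    return cases


def censor_geocodes(cases: list[CaseRecord], scenario: Scenario,
                    geography: Geography, seed: int) -> list[CaseRecord]:
    """Degrade exact geocodes to the era's precision mix.

    Postal-code-like cases become region-set censored over the containing
    fine census region plus a few adjacent ones; town-name-like cases keep
    only their coarse division.  The true point is retained in a hidden
    truth field for evaluation only.
    """
    rng = np.random.default_rng(seed)
    adjacency_cache: dict[tuple[int, int], dict[str, frozenset[str]]] = {}
    tree_cache: dict[tuple[int, int], tuple[STRtree, list[Region]]] = {}
    coarse_tree = STRtree([r.polygon for r in geography.coarse.regions])
    coarse_ids = [r.region_id for r in geography.coarse.regions]

    out: list[CaseRecord] = []
    for case in cases:
        if case.point is None:
            raise SchemaError(f"case {case.case_id} has no exact point to censor")
        mix = scenario.geocode_mix[scenario.era_of(case.year)]
        u = rng.random()
        precision = "exact" if u < mix[0] else \
            ("region_set" if u < mix[0] + mix[1] else "coarse")
        if precision == "exact":
            out.append(case)
            continue
        x, y = case.point
        if precision == "coarse":
            hit = coarse_tree.query(Point(x, y), predicate="intersects")
            if hit.size == 0:
                out.append(case)
                continue
            out.append(CaseRecord(
                case_id=case.case_id, site=case.site, behaviour=case.behaviour,
                sex=case.sex, age_group=case.age_group, year=case.year,
                precision="coarse", coarse_region=coarse_ids[int(hit[0])],
                true_point=case.true_point))
            continue
        census = census_year_for(case.year, scenario.census_years)
        period = (census - 2, census + 2)
        if period not in tree_cache:
            regions = [r for r in geography.fine.regions
                       if r.period_validity == period]
            tree_cache[period] = (STRtree([r.polygon for r in regions]), regions)
            adjacency_cache[period] = region_adjacency(regions)
        tree, regions = tree_cache[period]
        hit = tree.query(Point(x, y), predicate="intersects")
        if hit.size == 0:
            out.append(case)
            continue
        home = regions[int(hit[0])].region_id
        k = int(rng.choice(scenario.censoring_set_sizes))
        neigh = sorted(adjacency_cache[period][home])
        extra = list(rng.choice(neigh, size=min(k - 1, len(neigh)),
                                replace=False)) if k > 1 and neigh else []
        out.append(CaseRecord(
            case_id=case.case_id, site=case.site, behaviour=case.behaviour,
            sex=case.sex, age_group=case.age_group, year=case.year,
            precision="region_set",
            candidate_regions=frozenset([home] + extra),
            true_point=case.true_point))
    return out


def block_grid_study(nx: int = 40, ny: int = 40, delta_m: float = 2000.0,
                     block: int = 4, total_expected: float = 1000.0,
                     period: tuple[int, int] = (1999, 2003),
                     density_cv: float = 0.3, seed: int = 0):
    """A self-contained gridded study for calibration experiments.

    Builds an offset surface with mildly heterogeneous expected-case density
    on an nx x ny grid, fine census regions as ``block`` x ``block`` cell
    squares and coarse divisions as grid quadrants.  Returns
    (OffsetSurface, RegionIndex).
    """
    from .localem import RegionIndex
    from .raster import RasterizedRegions
    from .types import OffsetSurface

    rng = np.random.default_rng(seed)
    grid = GridSpec(0.0, 0.0, delta_m, nx, ny)
    dens = rng.lognormal(0.0, density_cv, size=grid.shape)
    dens *= total_expected / dens.sum()
    offset = OffsetSurface(grid=grid, periods=[period],
                           values=(dens / grid.cell_area)[None])
    cols = np.arange(nx) // block
    rows = np.arange(ny) // block
    fine_idx = rows[:, None] * (int(np.ceil(nx / block))) + cols[None, :]
    fine_ids = [f"B{k:03d}" for k in range(fine_idx.max() + 1)]
    fine = RasterizedRegions(grid=grid, ids=fine_ids, index=fine_idx,
                             inhabited=np.ones(grid.shape, bool))
    qrow = (np.arange(ny) >= ny // 2).astype(int)
    qcol = (np.arange(nx) >= nx // 2).astype(int)
    coarse_idx = qrow[:, None] * 2 + qcol[None, :]
    coarse = RasterizedRegions(grid=grid, ids=["Q0", "Q1", "Q2", "Q3"],
                               index=coarse_idx,
                               inhabited=np.ones(grid.shape, bool))
    return offset, RegionIndex(fine=[fine], coarse=coarse)


def cases_from_margins(site: str, sex: str, years: tuple[int, int],
                       total: int, in_situ: int,
                       precision_shares: tuple[float, float, float],
                       mean_age: float) -> list[CaseRecord]:
    """Deterministically build a case list matching stated marginal counts.

    Used to validate cohort-summary arithmetic against published-style
    tables: ``total`` cases of one site and sex spread uniformly over
    ``years``, with the stated in-situ count, geocode-precision shares
    (fractions of exact / region-set / coarse) and mean age at diagnosis
    (achieved by mixing the two age bands bracketing the target).
    The geometry attached to each record is a placeholder.
    """
    mids = np.array([age_group_midpoint(a) for a in AGE_GROUPS])
    hi = int(np.searchsorted(mids, mean_age))
    hi = min(max(hi, 1), len(AGE_GROUPS) - 1)
    lo = hi - 1
    f_hi = (mean_age - mids[lo]) / (mids[hi] - mids[lo])
    n_hi = int(round(f_hi * total))
    n_exact = int(round(precision_shares[0] * total))
    n_rs = int(round(precision_shares[1] * total))
    cases = []
    span = years[1] - years[0] + 1
    for j in range(total):
        if j < n_exact:
            prec = dict(precision="exact", point=(0.0, 0.0))
        elif j < n_exact + n_rs:
            prec = dict(precision="region_set",
                        candidate_regions=frozenset({"R0"}))
        else:
            prec = dict(precision="coarse", coarse_region="D0")
        cases.append(CaseRecord(
            case_id=f"{site[:2]}{sex}{j:05d}", site=site,
            behaviour="in_situ" if j % max(1, total // max(in_situ, 1)) == 0
            and sum(c.behaviour == "in_situ" for c in cases) < in_situ
            else "invasive",
            sex=sex,
            age_group=AGE_GROUPS[hi] if j < n_hi else AGE_GROUPS[lo],
            year=years[0] + j % span, **prec))
    # exact in-situ count: the modular rule above can undershoot
    short = in_situ - sum(c.behaviour == "in_situ" for c in cases)
    if short > 0:
        for c in cases:
            if short == 0:
                break
            if c.behaviour == "invasive":
                c.behaviour = "in_situ"
                short -= 1
    return cases


# --- covariates -------------------------------------------------------------

INDICATORS_MATERIAL = ("no_highschool_pct", "avg_income", "employment_rate")
INDICATORS_SOCIAL = ("sep_div_wid_pct", "single_parent_pct", "living_alone_pct")


def make_covariates(scenario: Scenario, communities: RegionSet,
                    seed: int) -> tuple[pd.DataFrame, TruthBundle]:
    """Community covariate table: six socioeconomic indicators driven by two
    latent deprivation factors, plus well-water usage percentage."""
    rng = np.random.default_rng(seed)
    n = len(communities)
    load = scenario.covariate_loading
    nsd = scenario.covariate_noise_sd
    f_mat = rng.normal(size=n)
    f_soc = rng.normal(size=n)

    def ind(factor, sign=1.0):
        return sign * (load * factor + nsd * rng.normal(size=n))

    cents = np.array([[r.polygon.centroid.x, r.polygon.centroid.y]
                      for r in communities.regions])
    W = max(cents[:, 0].max() - cents[:, 0].min(), 1.0)
    well = 55 + 30 * np.tanh(3 * (cents[:, 0] - cents[:, 0].mean()) / W) \
        + 12 * rng.normal(size=n)
    df = pd.DataFrame({
        "community_id": communities.ids(),
        "no_highschool_pct": 30 + 8 * ind(f_mat),
        "avg_income": 35_000 - 6_000 * ind(f_mat),
        "employment_rate": 60 - 7 * ind(f_mat),
        "sep_div_wid_pct": 12 + 3 * ind(f_soc),
        "single_parent_pct": 15 + 4 * ind(f_soc),
        "living_alone_pct": 10 + 3 * ind(f_soc),
        "well_water_pct": np.clip(well, 0.0, 100.0),
    })
    truth = TruthBundle(latent_material=pd.Series(f_mat, index=df["community_id"]),
                        latent_social=pd.Series(f_soc, index=df["community_id"]))
    return df, truth


# --- community-level (BYM) ground-truth simulation --------------------------

def sample_icar(neighbours: dict[str, frozenset[str]], sigma: float,
                rng: np.random.Generator) -> np.ndarray:
    """Draw one intrinsic-CAR field with sum-to-zero per connected component.

    Sampling uses the spectral pseudo-inverse of the graph Laplacian, scaled
    so that sigma plays the role of the conditional standard deviation.
    """
    ids = sorted(neighbours)
    n = len(ids)
    pos = {cid: i for i, cid in enumerate(ids)}
    Q = np.zeros((n, n))
    for cid, nbrs in neighbours.items():
        i = pos[cid]
        Q[i, i] = len(nbrs)
        for m in nbrs:
            Q[i, pos[m]] = -1.0
    w, v = np.linalg.eigh(Q)
    S = np.zeros(n)
    keep = w > 1e-8
    z = rng.normal(size=int(keep.sum()))
    S = v[:, keep] @ (z * sigma / np.sqrt(w[keep]))
    # exact sum-to-zero per component
    comps = _components(neighbours)
    for comp in comps:
        idx = [pos[c] for c in comp]
        S[idx] -= S[idx].mean()
    return S


def _components(neighbours: dict[str, frozenset[str]]) -> list[list[str]]:
    seen: set[str] = set()
    comps = []
    for start in sorted(neighbours):
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for w_ in neighbours[u]:
                if w_ not in seen:
                    seen.add(w_)
                    stack.append(w_)
        comps.append(comp)
    return comps


def simulate_bym_data(neighbours: dict[str, frozenset[str]],
                      E: dict[str, float],
                      X: Optional[pd.DataFrame],
                      params: dict,
                      seed: int):
    """Simulate community counts from the BYM model itself.

    ``params`` holds mu, beta (array or None), sigma_s, sigma_v.  Returns
    (list of CommunityData, TruthBundle).
    """
    from .types import CommunityData

    rng = np.random.default_rng(seed)
    ids = sorted(neighbours)
    S = sample_icar(neighbours, params["sigma_s"], rng)
    V = rng.normal(0.0, params["sigma_v"], size=len(ids))
    beta = np.asarray(params.get("beta")) if params.get("beta") is not None else None
    data = []
    for i, cid in enumerate(ids):
        xb = 0.0
        x_i = np.zeros(0)
        if beta is not None and X is not None:
            x_i = X.loc[cid].to_numpy(dtype=float)
            xb = float(x_i @ beta)
        eta = params["mu"] + xb + S[i] + V[i]
        y = rng.poisson(E[cid] * math.exp(eta))
        data.append(CommunityData(community_id=cid, Y=int(y), E=float(E[cid]),
                                  X=x_i, neighbours=neighbours[cid]))
    truth = TruthBundle(bym_params=dict(params), S=S, V=V)
    return data, truth
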