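"""Indirect standardization and deprivation indices.

Person-year denominators come from quinquennial censuses: every study year is
assigned to the census whose +/-2-year window contains it, so a census count
contributes once per covered study year.  Expected counts E_i are the usual
indirect-standardization sums of person-years times reference stratum rates;
when the rates are computed from the same data, sum(E_i) equals the observed
total exactly (closure).

The material and social deprivation scores are first principal components of
three standardized census indicators each, computed on the correlation matrix
so the scores are invariant to affine rescaling of any indicator, and signed
so that higher always means more deprived.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .types import AGE_GROUPS, CaseRecord, SchemaError, census_year_for

log = logging.getLogger("riskmap")


def person_years(population: pd.DataFrame,
                 study_years: Iterable[int],
                 census_years: Optional[Sequence[int]] = None) -> pd.DataFrame:
    """Person-years per (region_id, sex, age_group) over the study window.

    Each study year contributes the count from its covering census; an
    uncovered year raises, naming the year.
    """
    study_years = sorted(set(int(y) for y in study_years))
    if census_years is None:
        census_years = sorted(population["census_year"].unique())
    years_per_census: dict[int, int] = {}
    for y in study_years:
        c = census_year_for(y, census_years)  # raises for uncovered years
        years_per_census[c] = years_per_census.get(c, 0) + 1

    frames = []
    for c, n_years in years_per_census.items():
        sub = population[population["census_year"] == c].copy()
        if sub.empty:
            raise SchemaError(f"no population rows for census year {c}")
        sub["person_years"] = sub["count"].astype(float) * n_years
        frames.append(sub[["region_id", "sex", "age_group", "person_years"]])
    out = (pd.concat(frames)
           .groupby(["region_id", "sex", "age_group"], as_index=False)["person_years"]
           .sum())
    return out


def provincial_rates(cases: Sequence[CaseRecord],
                     py: pd.DataFrame,
                     sex: Optional[str] = None) -> pd.DataFrame:
    """Whole-study-area stratum rates = case total / person-year total.

    Returns a frame with columns (sex, age_group, rate).  Strata with
    positive cases but zero person-years raise; strata with no cases get
    rate 0.
    """
    counts: dict[tuple[str, str], int] = {}
    for c in cases:
        if sex is not None and c.sex != sex:
            continue
        counts[(c.sex, c.age_group)] = counts.get((c.sex, c.age_group), 0) + 1
    tot_py = py.groupby(["sex", "age_group"])["person_years"].sum()
    rows = []
    sexes = [sex] if sex is not None else ["M", "F"]
    for s in sexes:
        for ag in AGE_GROUPS:
            n = counts.get((s, ag), 0)
            denom = float(tot_py.get((s, ag), 0.0))
            if denom <= 0:
                if n > 0:
                    raise SchemaError(
                        f"stratum ({s}, {ag}): {n} cases but zero person-years")
                rate = 0.0
            else:
                rate = n / denom
            rows.append((s, ag, rate))
    return pd.DataFrame(rows, columns=["sex", "age_group", "rate"])


def expected_counts(py: pd.DataFrame, rates: pd.DataFrame,
                    region_to_community: Mapping[str, str]) -> pd.Series:
    """Indirectly standardized expected counts E_i per community.

    Communities whose population is entirely missing are excluded with a
    warning rather than carried with E_i = 0.
    """
    merged = py.merge(rates, on=["sex", "age_group"], how="left")
    if merged["rate"].isna().any():
        bad = merged.loc[merged["rate"].isna()].iloc[0]
        raise SchemaError(f"no rate for stratum ({bad['sex']}, {bad['age_group']})")
    merged["expected"] = merged["person_years"] * merged["rate"]
    unmapped = set(merged["region_id"]) - set(region_to_community)
    if unmapped:
        raise SchemaError(f"regions not mapped to a community: {sorted(unmapped)[:5]}")
    merged["community_id"] = merged["region_id"].map(region_to_community)
    E = merged.groupby("community_id")["expected"].sum()
    dropped = E.index[E <= 0].tolist()
    if dropped:
        warnings.warn(f"excluding {len(dropped)} communities with zero expected "
                      f"count (no population): {dropped[:5]}")
        E = E[E > 0]
    return E


# --- deprivation indices ----------------------------------------------------

MATERIAL_INDICATORS = {"no_highschool_pct": +1.0, "avg_income": -1.0,
                       "employment_rate": -1.0}
SOCIAL_INDICATORS = {"sep_div_wid_pct": +1.0, "single_parent_pct": +1.0,
                     "living_alone_pct": +1.0}


@dataclass
class DeprivationIndices:
    material: pd.Series
    social: pd.Series
    material_loadings: pd.Series
    social_loadings: pd.Series


def _first_component(df: pd.DataFrame, signs: Mapping[str, float]) -> tuple[pd.Series, pd.Series]:
    cols = [c for c in signs if c in df.columns]
    if len(cols) < len(signs):
        missing = set(signs) - set(cols)
        raise SchemaError(f"indicator table missing columns {sorted(missing)}")
    Z = np.empty((len(df), 0))
    kept = []
    for c in cols:
        x = df[c].to_numpy(dtype=float) * signs[c]
        sd = x.std(ddof=0)
        if sd == 0:
            warnings.warn(f"indicator {c!r} has zero variance; dropped from PCA")
            continue
        Z = np.column_stack([Z, (x - x.mean()) / sd]) if Z.size else \
            ((x - x.mean()) / sd)[:, None]
        kept.append(c)
    n = len(df)
    if not kept:
        return (pd.Series(np.zeros(n), index=df.index),
                pd.Series(dtype=float))
    R = (Z.T @ Z) / n  # correlation matrix of the kept indicators
    w, v = np.linalg.eigh(R)
    pc = v[:, -1]
    if pc.sum() < 0:  # orient: higher score = more deprived
        pc = -pc
    scores = Z @ pc
    scores = scores - scores.mean()
    return (pd.Series(scores, index=df.index),
            pd.Series(pc, index=kept))


def deprivation_indices(indicators: pd.DataFrame) -> DeprivationIndices:
    """Material and social deprivation scores for each community.

    ``indicators`` must be indexed (or carry a column) ``community_id`` and
    include the six census indicators.  Income and employment are
    sign-flipped before standardization so that larger scores mean more
    deprivation on both dimensions.
    """
    df = indicators.set_index("community_id") if "community_id" in indicators.columns \
        else indicators
    if len(df) < 3:
        raise SchemaError("need at least 3 communities for the PCA indices")
    mat, mat_load = _first_component(df, MATERIAL_INDICATORS)
    soc, soc_load = _first_component(df, SOCIAL_INDICATORS)
    return DeprivationIndices(material=mat, social=soc,
                              material_loadings=mat_load,
                              social_loadings=soc_load)


def community_table(cases: Sequence[CaseRecord],
                    py: pd.DataFrame,
                    rates: pd.DataFrame,
                    region_to_community: Mapping[str, str],
                    covariates: pd.DataFrame,
                    case_to_community: Mapping[str, str]) -> pd.DataFrame:
    """Assemble the per-community (Y_i, E_i, X_i) analysis table."""
    E = expected_counts(py, rates, region_to_community)
    Y = pd.Series(0, index=E.index, dtype=int)
    for c in cases:
        cid = case_to_community.get(c.case_id)
        if cid in Y.index:
            Y[cid] += 1
    idx = deprivation_indices(covariates)
    out = pd.DataFrame({"community_id": E.index, "Y": Y.values, "E": E.values})
    cov = covariates.set_index("community_id")
    out["well_water_pct"] = out["community_id"].map(cov["well_water_pct"]).fillna(0.0)
    out["material"] = out["community_id"].map(idx.material).fillna(0.0)
    out["social"] = out["community_id"].map(idx.social).fillna(0.0)
    return out
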