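"""Readers and writers for the standard file formats.

Regions travel as GeoJSON (one feature per region, properties carrying
``region_id``, ``period_validity`` and ``inhabited_fraction``); cases,
populations and covariates as headed CSV; gridded surfaces as GeoTIFF with
one band (page) per period/year and the standard geotransform tags, so any
GIS can place them.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping, shape

from .types import (
    CaseRecord,
    ExceedanceSurface,
    GeometryError,
    GridSpec,
    Region,
    RegionSet,
    RiskSurface,
    SchemaError,
)

log = logging.getLogger("riskmap")

_REQUIRED_PROPS = ("region_id", "period_validity", "inhabited_fraction")


def write_regions(regions: RegionSet, path: Union[str, Path]) -> None:
    features = []
    for r in regions.regions:
        features.append({
            "type": "Feature",
            "geometry": mapping(r.polygon),
            "properties": {
                "region_id": r.region_id,
                "period_validity": list(r.period_validity),
                "inhabited_fraction": r.inhabited_fraction,
            },
        })
    doc = {
        "type": "FeatureCollection",
        "features": features,
        "riskmap": {"level": regions.level, "crs_label": regions.crs_label},
    }
    Path(path).write_text(json.dumps(doc))


def read_regions(path: Union[str, Path], level: str) -> RegionSet:
    doc = json.loads(Path(path).read_text())
    regions = []
    for k, feat in enumerate(doc.get("features", [])):
        props = feat.get("properties", {})
        for p in _REQUIRED_PROPS:
            if p not in props:
                raise SchemaError(f"feature #{k}: missing property {p!r}")
        geom = shape(feat["geometry"])
        if not geom.is_valid:
            raise GeometryError(f"region {props['region_id']!r}: invalid geometry")
        regions.append(Region(
            region_id=str(props["region_id"]),
            polygon=geom,
            period_validity=tuple(int(y) for y in props["period_validity"]),
            inhabited_fraction=float(props["inhabited_fraction"]),
        ))
    crs = doc.get("riskmap", {}).get("crs_label", "synthetic-planar-metres")
    return RegionSet(level=level, regions=regions, crs_label=crs)


CASE_COLUMNS = ["case_id", "site", "behaviour", "sex", "age_group", "year",
                "precision", "x", "y", "candidate_regions", "coarse_region",
                "true_x", "true_y"]


def write_cases(cases: list[CaseRecord], path: Union[str, Path]) -> None:
    rows = []
    for c in cases:
        rows.append({
            "case_id": c.case_id, "site": c.site, "behaviour": c.behaviour,
            "sex": c.sex, "age_group": c.age_group, "year": c.year,
            "precision": c.precision,
            "x": c.point[0] if c.point else "",
            "y": c.point[1] if c.point else "",
            "candidate_regions": ";".join(sorted(c.candidate_regions))
            if c.candidate_regions else "",
            "coarse_region": c.coarse_region or "",
            "true_x": c.true_point[0] if c.true_point else "",
            "true_y": c.true_point[1] if c.true_point else "",
        })
    pd.DataFrame(rows, columns=CASE_COLUMNS).to_csv(path, index=False)


def read_cases(path: Union[str, Path]) -> list[CaseRecord]:
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in CASE_COLUMNS[:11] if c not in df.columns]
    if missing:
        raise SchemaError(f"case file missing columns {missing}")
    cases = []
    for idx, row in df.iterrows():
        try:
            precision = row["precision"]
            point = cand = coarse = None
            if precision == "exact":
                point = (float(row["x"]), float(row["y"]))
            elif precision == "region_set":
                ids = [s for s in row["candidate_regions"].split(";") if s]
                cand = frozenset(ids)
            elif precision == "coarse":
                coarse = row["coarse_region"] or None
            truth = None
            if row.get("true_x", "") != "" and row.get("true_y", "") != "":
                truth = (float(row["true_x"]), float(row["true_y"]))
            cases.append(CaseRecord(
                case_id=row["case_id"], site=row["site"],
                behaviour=row["behaviour"], sex=row["sex"],
                age_group=row["age_group"], year=int(row["year"]),
                precision=precision, point=point, candidate_regions=cand,
                coarse_region=coarse, true_point=truth,
            ))
        except (ValueError, SchemaError) as exc:
            raise SchemaError(f"case file row {idx} ({row.get('case_id', '?')}): {exc}") from exc
    n = len(cases)
    if n:
        shares = {p: 100.0 * sum(c.precision == p for c in cases) / n
                  for p in ("exact", "region_set", "coarse")}
        log.info("read %d cases: %.1f%% exact / %.1f%% region_set / %.1f%% coarse",
                 n, shares["exact"], shares["region_set"], shares["coarse"])
    return cases


# --- gridded surfaces -------------------------------------------------------

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737


def write_surface(surface: Union[RiskSurface, ExceedanceSurface],
                  path: Union[str, Path],
                  crs_label: str = "synthetic-planar-metres") -> None:
    """Write a surface as a multi-page float64 GeoTIFF (one page per
    period/year, rows stored north-up)."""
    grid = surface.grid
    vals = surface.values
    d = float(grid.delta)
    y_top = grid.y0 + grid.ny * d
    extratags = [
        (_TAG_PIXEL_SCALE, "d", 3, (d, d, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, grid.x0, y_top, 0.0)),
        (_TAG_GEO_ASCII, "s", None, crs_label + "|"),
    ]
    with tifffile.TiffWriter(str(path)) as tif:
        for band in vals:
            tif.write(band[::-1, :].astype(np.float64), extratags=extratags,
                      photometric="minisblack")


def read_surface(path: Union[str, Path]) -> tuple[GridSpec, np.ndarray, str]:
    """Read back a surface GeoTIFF -> (grid, values (n, ny, nx), crs_label)."""
    with tifffile.TiffFile(str(path)) as tif:
        pages = tif.pages
        bands = np.stack([p.asarray()[::-1, :] for p in pages])
        tags = pages[0].tags
        scale = tags[_TAG_PIXEL_SCALE].value
        tie = tags[_TAG_TIEPOINT].value
        crs = tags[_TAG_GEO_ASCII].value.rstrip("|") if _TAG_GEO_ASCII in tags \
            else "unknown"
    ny, nx = bands.shape[-2:]
    d = float(scale[0])
    x0 = float(tie[3])
    y0 = float(tie[4]) - ny * d
    return GridSpec(x0=x0, y0=y0, delta=d, nx=nx, ny=ny), bands, crs


def read_population(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = {"region_id", "census_year", "sex", "age_group", "count"}
    missing = required - set(df.columns)
    if missing:
        raise SchemaError(f"population file missing columns {sorted(missing)}")
    if (df["count"] < 0).any():
        bad = df.loc[df["count"] < 0].iloc[0]
        raise SchemaError(f"negative population count for region {bad['region_id']!r}")
    if df.duplicated(["region_id", "census_year", "sex", "age_group"]).any():
        raise SchemaError("duplicate (region, census_year, sex, age_group) rows")
    return df


def read_covariates(path: Union[str, Path]) -> pd.DataFrame:
    df = pd.read_csv(path)
    if "community_id" not in df.columns:
        raise SchemaError("covariate file missing community_id column")
    return df
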