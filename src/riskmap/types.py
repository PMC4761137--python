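"""Shared domain types for the two-track disease-mapping analysis.

All geometry lives in a single planar metric CRS (coordinates in metres);
kernel bandwidths are given in kilometres at the user surface and converted
to metres internally.  Periods are inclusive calendar-year ranges; a case
belongs to the census period whose window (census year +/- 2) contains its
diagnosis year.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from shapely.geometry.base import BaseGeometry

SITES = ("bladder", "kidney")
BEHAVIOURS = ("in_situ", "invasive")
SEXES = ("M", "F")
PRECISIONS = ("exact", "region_set", "coarse")
LEVELS = ("community", "fine_census", "coarse_division")

#: 5-year age bands from 20-24 up to 85+ (adults only).
AGE_GROUPS = tuple(f"{a}-{a + 4}" for a in range(20, 85, 5)) + ("85+",)


class SchemaError(ValueError):
    """An input record or file violates a type invariant."""


class GeometryError(ValueError):
    """A region geometry is invalid or inconsistent."""


def age_group_midpoint(age_group: str) -> float:
    """Midpoint of a 5-year band; 87.5 for the open-ended 85+ band."""
    if age_group == "85+":
        return 87.5
    lo, hi = age_group.split("-")
    return (int(lo) + int(hi) + 1) / 2.0


@dataclass(frozen=True)
class Region:
    region_id: str
    polygon: BaseGeometry
    period_validity: tuple[int, int]
    inhabited_fraction: float = 1.0

    def __post_init__(self):
        if not (0.0 < self.inhabited_fraction <= 1.0):
            raise SchemaError(
                f"region {self.region_id!r}: inhabited_fraction "
                f"{self.inhabited_fraction} outside (0, 1]"
            )
        if self.polygon.is_empty or not self.polygon.is_valid:
            raise GeometryError(f"region {self.region_id!r}: invalid geometry")
        y0, y1 = self.period_validity
        if y1 < y0:
            raise SchemaError(f"region {self.region_id!r}: empty period {y0}-{y1}")


@dataclass
class RegionSet:
    """A set of polygons at one level of the nested geography."""

    level: str
    regions: list[Region]
    crs_label: str = "synthetic-planar-metres"

    def __post_init__(self):
        if self.level not in LEVELS:
            raise SchemaError(f"unknown region level {self.level!r}")
        seen: set[tuple[str, tuple[int, int]]] = set()
        for r in self.regions:
            key = (r.region_id, r.period_validity)
            if key in seen:
                raise SchemaError(
                    f"duplicate region_id {r.region_id!r} for period {r.period_validity}"
                )
            seen.add(key)

    def for_period(self, year: int) -> list[Region]:
        return [r for r in self.regions if r.period_validity[0] <= year <= r.period_validity[1]]

    def ids(self) -> list[str]:
        return [r.region_id for r in self.regions]

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class CaseRecord:
    """One diagnosis with a geocode at one of three precision levels."""

    case_id: str
    site: str
    behaviour: str
    sex: str
    age_group: str
    year: int
    precision: str
    point: Optional[tuple[float, float]] = None
    candidate_regions: Optional[frozenset[str]] = None
    coarse_region: Optional[str] = None
    #: generator-only ground truth, never consumed by estimators
    true_point: Optional[tuple[float, float]] = None

    def __post_init__(self):
        if self.site not in SITES:
            raise SchemaError(f"case {self.case_id}: unknown site {self.site!r}")
        if self.behaviour not in BEHAVIOURS:
            raise SchemaError(f"case {self.case_id}: unknown behaviour {self.behaviour!r}")
        if self.sex not in SEXES:
            raise SchemaError(f"case {self.case_id}: unknown sex {self.sex!r}")
        if self.age_group not in AGE_GROUPS:
            raise SchemaError(f"case {self.case_id}: age_group {self.age_group!r} "
                              "not a 20+ five-year band")
        if self.precision not in PRECISIONS:
            raise SchemaError(f"case {self.case_id}: unknown precision {self.precision!r}")
        filled = [self.point is not None,
                  self.candidate_regions is not None,
                  self.coarse_region is not None]
        expected = [self.precision == "exact",
                    self.precision == "region_set",
                    self.precision == "coarse"]
        if filled != expected:
            raise SchemaError(
                f"case {self.case_id}: geocode fields {filled} inconsistent with "
                f"precision {self.precision!r}"
            )
        if self.candidate_regions is not None and len(self.candidate_regions) == 0:
            raise SchemaError(f"case {self.case_id}: empty candidate_regions")


@dataclass
class CommunityData:
    """Per-community observed/expected counts, covariates and neighbours."""

    community_id: str
    Y: int
    E: float
    X: np.ndarray
    neighbours: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self):
        if self.Y < 0 or int(self.Y) != self.Y:
            raise SchemaError(f"community {self.community_id}: Y must be a count")
        if not self.E > 0:
            raise SchemaError(f"community {self.community_id}: E must be > 0")
        if self.community_id in self.neighbours:
            raise SchemaError(f"community {self.community_id}: self-neighbour")


@dataclass(frozen=True)
class GridSpec:
    """Row-major regular grid; values arrays are shaped (ny, nx) as [row, col]."""

    x0: float
    y0: float
    delta: float
    nx: int
    ny: int

    def __post_init__(self):
        if self.delta <= 0:
            raise SchemaError("grid cell size must be > 0")
        if self.nx < 2 or self.ny < 2:
            raise SchemaError("grid must be at least 2x2")

    @property
    def cell_area(self) -> float:
        return self.delta * self.delta

    @property
    def shape(self) -> tuple[int, int]:
        return (self.ny, self.nx)

    def centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(X, Y) arrays of cell-centre coordinates, each shaped (ny, nx)."""
        xs = self.x0 + (np.arange(self.nx) + 0.5) * self.delta
        ys = self.y0 + (np.arange(self.ny) + 0.5) * self.delta
        return np.meshgrid(xs, ys)

    def cell_of(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """(row, col) of the cells containing points; boundary points go to the
        cell with the smaller linear index (left/lower)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.ceil((x - self.x0) / self.delta).astype(int) - 1
        row = np.ceil((y - self.y0) / self.delta).astype(int) - 1
        col = np.clip(col, 0, self.nx - 1)
        row = np.clip(row, 0, self.ny - 1)
        return row, col

    def contains(self, x, y) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        return ((x >= self.x0) & (x <= self.x0 + self.nx * self.delta)
                & (y >= self.y0) & (y <= self.y0 + self.ny * self.delta))


def _check_grid_values(grid: GridSpec, values: np.ndarray, n_leading: int) -> np.ndarray:
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:
        values = values[None, ...]
    if values.ndim != 2 + (n_leading > 0) or values.shape[-2:] != grid.shape:
        if values.shape[-2:] != grid.shape:
            raise SchemaError(
                f"values shape {values.shape} does not match grid {grid.shape}"
            )
    if not np.all(np.isfinite(values)):
        raise SchemaError("surface values must be finite")
    return values


@dataclass
class OffsetSurface:
    """Expected-case density rho(s, t) per unit area under reference rates.

    ``values`` is shaped (n_periods, ny, nx) and holds densities in expected
    cases per m^2 over the whole period.
    """

    grid: GridSpec
    periods: list[tuple[int, int]]
    values: np.ndarray

    def __post_init__(self):
        self.values = _check_grid_values(self.grid, self.values, 1)
        if self.values.shape[0] != len(self.periods):
            raise SchemaError("one value plane per period required")
        if np.any(self.values < 0):
            raise SchemaError("offset densities must be >= 0")

    def expected_counts(self) -> np.ndarray:
        """Per-period expected counts per cell, shaped like ``values``."""
        return self.values * self.grid.cell_area

    def period_of(self, year: int) -> int:
        for k, (y0, y1) in enumerate(self.periods):
            if y0 <= year <= y1:
                return k
        raise SchemaError(f"year {year} not covered by any offset period")


@dataclass
class RiskSurface:
    """Estimated relative-risk surface lambda-hat(s) or lambda-hat(s, t)."""

    grid: GridSpec
    values: np.ndarray
    h_km: float
    tau_years: Optional[float] = None
    times: Optional[list[int]] = None
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None, ...]
        if self.values.shape[-2:] != self.grid.shape:
            raise SchemaError("risk values do not match grid shape")
        if self.times is not None and len(self.times) != self.values.shape[0]:
            raise SchemaError("one value plane per time point required")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise SchemaError("risk values must be finite and >= 0")


@dataclass
class ExceedanceSurface:
    """P(s; 10%) or P(s, t; 10%): bootstrap probability that risk exceeds
    ``threshold`` (default 1.1 = 10% above the typical level)."""

    grid: GridSpec
    values: np.ndarray
    threshold: float = 1.1
    n_replicates: int = 0
    times: Optional[list[int]] = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 2:
            self.values = self.values[None, ...]
        if self.values.shape[-2:] != self.grid.shape:
            raise SchemaError("exceedance values do not match grid shape")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise SchemaError("exceedance probabilities must lie in [0, 1]")
        if self.threshold <= 0:
            raise SchemaError("threshold must be > 0")


CENSUS_YEARS = (1981, 1986, 1991, 1996, 2001, 2006, 2011)


def census_year_for(year: int, census_years: Sequence[int] = CENSUS_YEARS) -> int:
    """The census whose +/-2-year window covers ``year``.

    Raises if no window covers the year (the windows of 5-yearly censuses tile
    the timeline exactly, so only years beyond either end are uncovered).
    """
    for c in census_years:
        if c - 2 <= year <= c + 2:
            return c
    raise SchemaError(f"study year {year} not within 2 years of any census")
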