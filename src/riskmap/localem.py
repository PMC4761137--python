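"""Local-EM kernel intensity smoothing for spatially censored case records.

The estimator targets a relative-risk surface lambda(s) (or lambda(s, t))
for a point process whose expected-case density under reference rates is the
offset rho(s, t).  Case locations may be known exactly, only up to a set of
candidate fine census regions (postal-code censoring), or only up to a
coarse division.  The fixed-point iteration alternates

  E-step:  w_jg  proportional to  lambda(g) rho(g) area(g)   over the
           candidate cells of case j (exact cases put unit mass on their
           cell; the case's own census period supplies rho);
  M-step:  lambda_new = smooth(sum_j w_j) / smooth(rho area), rescaled so
           that sum_g lambda rho area equals the case total exactly.

Smoothing uses a truncated-Gaussian kernel made doubly stochastic on the
study-region mask by Sinkhorn symmetrization: rows summing to one make a
flat field an exact fixed point (edge-correction exactness) and columns
summing to one preserve mass, the two properties the estimator relies on.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.ndimage import convolve1d

from .raster import RasterizedRegions
from .types import (
    CaseRecord,
    GridSpec,
    OffsetSurface,
    RiskSurface,
    SchemaError,
)

log = logging.getLogger("riskmap")


@dataclass(frozen=True)
class KernelSpec:
    """Gaussian smoothing kernel; bandwidths are standard deviations."""

    h_km: float
    tau_years: Optional[float] = None
    truncation_sd: float = 4.0

    def __post_init__(self):
        if self.h_km <= 0:
            raise SchemaError("spatial bandwidth must be > 0")
        if self.tau_years is not None and self.tau_years <= 0:
            raise SchemaError("temporal bandwidth must be > 0")


@dataclass
class EMControl:
    tol: float = 1e-4
    max_iter: int = 200


def _gauss_weights(sigma_cells: float, truncation_sd: float,
                   max_radius: Optional[int] = None) -> np.ndarray:
    r = int(np.ceil(truncation_sd * sigma_cells))
    if max_radius is not None:
        r = min(r, max_radius)
    r = max(r, 1)
    d = np.arange(-r, r + 1, dtype=float)
    w = np.exp(-0.5 * (d / sigma_cells) ** 2)
    return w / w.sum()


_OPERATOR_CACHE: dict = {}
_OPERATOR_CACHE_MAX = 32


def cached_operator(grid: GridSpec, h_km: float, mask: Optional[np.ndarray],
                    truncation_sd: float = 4.0) -> "SmoothingOperator":
    """Memoized smoothing operators: bootstrap and cross-validation refit the
    same (grid, bandwidth, mask) hundreds of times and the Sinkhorn scaling
    is the expensive part."""
    key = (grid, float(h_km), float(truncation_sd),
           None if mask is None else mask.tobytes())
    op = _OPERATOR_CACHE.get(key)
    if op is None:
        if len(_OPERATOR_CACHE) >= _OPERATOR_CACHE_MAX:
            _OPERATOR_CACHE.pop(next(iter(_OPERATOR_CACHE)))
        op = SmoothingOperator(grid, h_km, mask=mask,
                               truncation_sd=truncation_sd)
        _OPERATOR_CACHE[key] = op
    return op


class SmoothingOperator:
    """Doubly stochastic truncated-Gaussian smoother on a masked grid.

    The raw separable kernel K is symmetrized to S = diag(d) K diag(d) with
    d chosen (Sinkhorn iteration) so every row/column restricted to the mask
    sums to one.
    """

    def __init__(self, grid: GridSpec, h_km: float, mask: Optional[np.ndarray] = None,
                 truncation_sd: float = 4.0):
        self.grid = grid
        sigma_cells = h_km * 1000.0 / grid.delta
        if sigma_cells < 0.5:
            warnings.warn(
                f"bandwidth {h_km} km is under half a grid cell "
                f"({grid.delta / 1000:.2f} km); expect undersmoothing artifacts")
        self.weights = _gauss_weights(sigma_cells, truncation_sd)
        self.mask = np.ones(grid.shape, bool) if mask is None else mask.astype(bool)
        self._d = self._sinkhorn()

    def _apply_raw(self, f: np.ndarray) -> np.ndarray:
        f = np.where(self.mask, f, 0.0)
        out = convolve1d(f, self.weights, axis=0, mode="constant", cval=0.0)
        out = convolve1d(out, self.weights, axis=1, mode="constant", cval=0.0)
        return np.where(self.mask, out, 0.0)

    def _sinkhorn(self, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
        d = np.where(self.mask, 1.0, 0.0)
        for _ in range(max_iter):
            kd = self._apply_raw(d)
            # self-weight is positive, so kd > 0 on every masked cell
            new = np.where(self.mask, np.sqrt(d / np.where(kd > 0, kd, 1.0)), 0.0)
            err = np.max(np.abs(np.where(self.mask, d * kd, 1.0) - 1.0))
            d = new
            if err < tol:
                break
        return d

    def __call__(self, f: np.ndarray) -> np.ndarray:
        return self._d * self._apply_raw(self._d * f)

    def dense_matrix(self) -> np.ndarray:
        """Explicit operator matrix over flattened masked cells (small grids
        only; used by cross-checks)."""
        n = self.grid.ny * self.grid.nx
        cols = []
        for j in range(n):
            e = np.zeros(n)
            e[j] = 1.0
            cols.append(self(e.reshape(self.grid.shape)).ravel())
        return np.array(cols).T


class TemporalOperator:
    """Doubly stochastic 1-D Gaussian smoother over the study years."""

    def __init__(self, years: Sequence[int], tau_years: float,
                 truncation_sd: float = 4.0):
        self.years = list(years)
        T = len(self.years)
        self.weights = _gauss_weights(float(tau_years), truncation_sd,
                                      max_radius=max(T - 1, 1))
        self._d = self._sinkhorn(T)

    def _apply_raw(self, f: np.ndarray) -> np.ndarray:
        return convolve1d(f, self.weights, axis=0, mode="constant", cval=0.0)

    def _sinkhorn(self, T: int, tol: float = 1e-12, max_iter: int = 1000) -> np.ndarray:
        d = np.ones(T)
        for _ in range(max_iter):
            kd = self._apply_raw(d)
            err = np.max(np.abs(d * kd - 1.0))
            d = np.sqrt(d / kd)
            if err < tol:
                break
        return d

    def __call__(self, f: np.ndarray) -> np.ndarray:
        # f shaped (T, ...); broadcast the scaling over trailing axes
        shape = (len(self._d),) + (1,) * (f.ndim - 1)
        d = self._d.reshape(shape)
        return d * self._apply_raw(d * f)


# --- offset construction ----------------------------------------------------

@dataclass
class RegionIndex:
    """Rasterized candidate-region lookup, one fine raster per offset period."""

    fine: list[RasterizedRegions]
    coarse: Optional[RasterizedRegions] = None


def build_offset(population, rates, regions, grid: GridSpec,
                 study_years: tuple[int, int],
                 census_years: Optional[Sequence[int]] = None,
                 sex: Optional[str] = None) -> tuple[OffsetSurface, list[RasterizedRegions]]:
    """Gridded expected-case density per census period.

    rho(g, t) spreads each fine region's expected count (person-years x
    stratum rate for the years of the period inside the study window)
    uniformly over the region's inhabited cells.  Raises if a populated
    region has no cells on the grid.
    """
    from .raster import rasterize, require_population_cells

    if census_years is None:
        census_years = sorted(population["census_year"].unique())
    y0, y1 = study_years
    rate_map = rates.set_index(["sex", "age_group"])["rate"] if hasattr(rates, "set_index") \
        else rates
    periods = []
    planes = []
    rasters = []
    for c in census_years:
        years = [t for t in range(max(y0, c - 2), min(y1, c + 2) + 1)]
        if not years:
            continue
        period = (c - 2, c + 2)
        regs = [r for r in regions.regions if r.period_validity == period]
        pop_c = population[population["census_year"] == c]
        if sex is not None:
            pop_c = pop_c[pop_c["sex"] == sex]
        if not regs or pop_c.empty:
            continue
        merged = pop_c.copy()
        merged["rate"] = [rate_map.get((s, a), 0.0)
                          for s, a in zip(merged["sex"], merged["age_group"])]
        merged["expected"] = merged["count"] * merged["rate"] * len(years)
        per_region = merged.groupby("region_id")["expected"].sum()
        ras = rasterize(regs, grid)
        require_population_cells(ras, set(per_region.index[per_region > 0]) )
        plane = np.zeros(grid.shape)
        flat_idx = ras.index.ravel()
        inhab = ras.inhabited.ravel()
        plane_flat = plane.ravel()
        for k, rid in enumerate(ras.ids):
            exp_r = float(per_region.get(rid, 0.0))
            if exp_r <= 0:
                continue
            sel = np.flatnonzero((flat_idx == k) & inhab)
            plane_flat[sel] = exp_r / (sel.size * grid.cell_area)
        planes.append(plane_flat.reshape(grid.shape))
        periods.append(period)
        rasters.append(ras)
    if not planes:
        raise SchemaError("no offset periods overlap the study window")
    return OffsetSurface(grid=grid, periods=periods,
                         values=np.stack(planes)), rasters


# --- the fixed-point iteration ---------------------------------------------

def _case_cells(case: CaseRecord, grid: GridSpec, period_idx: int,
                index: Optional[RegionIndex]) -> np.ndarray:
    """Flat candidate-cell indices for one case."""
    if case.precision == "exact":
        r, c = grid.cell_of(*case.point)
        return np.array([int(r) * grid.nx + int(c)])
    if index is None:
        raise SchemaError(f"case {case.case_id} is censored but no region "
                          "index was supplied")
    if case.precision == "region_set":
        ras = index.fine[period_idx]
        cells = [ras.cells_of(rid) for rid in sorted(case.candidate_regions)
                 if rid in ras.ids]
        if not cells:
            raise SchemaError(f"case {case.case_id}: no candidate region is on "
                              "the grid for its period")
        return np.unique(np.concatenate(cells))
    if index.coarse is None:
        raise SchemaError(f"case {case.case_id} is coarse-censored but no "
                          "coarse raster was supplied")
    return index.coarse.cells_of(case.coarse_region)


@dataclass
class _Prepared:
    cells: list[np.ndarray]
    periods: np.ndarray
    years: np.ndarray


def _prepare(cases: Sequence[CaseRecord], offset: OffsetSurface,
             index: Optional[RegionIndex]) -> _Prepared:
    grid = offset.grid
    cells, periods, years = [], [], []
    mu = offset.expected_counts()
    for case in cases:
        p = offset.period_of(case.year)
        cc = _case_cells(case, grid, p, index)
        if mu[p].ravel()[cc].sum() <= 0:
            raise SchemaError(f"case {case.case_id}: candidate cells have zero "
                              "offset in its period")
        cells.append(cc)
        periods.append(p)
        years.append(case.year)
    return _Prepared(cells=cells, periods=np.array(periods, int),
                     years=np.array(years, int))


def localem_fit(cases: Sequence[CaseRecord], offset: OffsetSurface,
                kernel: KernelSpec, control: Optional[EMControl] = None,
                region_index: Optional[RegionIndex] = None,
                mask: Optional[np.ndarray] = None) -> RiskSurface:
    """Pooled spatial local-EM fit: lambda-hat(s) on the offset grid."""
    control = control or EMControl()
    grid = offset.grid
    prep = _prepare(cases, offset, region_index)
    mu_periods = offset.expected_counts()          # (P, ny, nx)
    mu_pool = mu_periods.sum(axis=0)
    if mask is None:
        mask = mu_pool > 0
    smooth = cached_operator(grid, kernel.h_km, mask,
                             truncation_sd=kernel.truncation_sd)
    s_mu = smooth(mu_pool)
    lam = np.where(mask, 1.0, 0.0)
    n = len(cases)
    if n == 0:
        return RiskSurface(grid=grid, values=np.zeros(grid.shape),
                           h_km=kernel.h_km, converged=True, n_iter=0)

    mu_flat = [mu_periods[p].ravel() for p in range(mu_periods.shape[0])]
    history: list[float] = []
    converged = False
    for it in range(1, control.max_iter + 1):
        lam_flat = lam.ravel()
        m = np.zeros(grid.ny * grid.nx)
        for cc, p in zip(prep.cells, prep.periods):
            w = lam_flat[cc] * mu_flat[p][cc]
            tot = w.sum()
            if tot <= 0:  # current estimate vanished on the candidate set
                w = mu_flat[p][cc]
                tot = w.sum()
            m[cc] += w / tot
        s_m = smooth(m.reshape(grid.shape))
        with np.errstate(divide="ignore", invalid="ignore"):
            new = np.where(s_mu > 0, s_m / np.where(s_mu > 0, s_mu, 1.0), 0.0)
        total = float(np.sum(new * mu_pool))
        if total > 0:
            new = new * (n / total)
        change = float(np.max(np.abs(new - lam)) / max(float(np.max(lam)), 1e-300))
        history.append(change)
        lam = new
        if change < control.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"local-EM did not converge in {control.max_iter} "
                      f"iterations (last change {history[-1]:.2e})")
    if len(history) >= 10 and np.any(np.diff(history[-10:]) > 1e-12):
        log.info("local-EM sup-norm change was not monotone over the last "
                 "10 iterations")
    return RiskSurface(grid=grid, values=lam, h_km=kernel.h_km,
                       converged=converged, n_iter=len(history))


def localem_fit_st(cases: Sequence[CaseRecord], offset: OffsetSurface,
                   kernel: KernelSpec, control: Optional[EMControl] = None,
                   region_index: Optional[RegionIndex] = None,
                   index_years: Optional[Sequence[int]] = None,
                   study_years: Optional[tuple[int, int]] = None,
                   mask: Optional[np.ndarray] = None) -> RiskSurface:
    """Spatio-temporal local-EM with a separable Gaussian kernel k_h k_tau.

    lambda-hat(s, t) is estimated on the full (year x grid) lattice; censored
    cases are spread only within their own period's candidate cells and
    their own diagnosis year.  Returns the surface at ``index_years`` (all
    years when omitted).
    """
    if kernel.tau_years is None:
        raise SchemaError("spatio-temporal fit needs a temporal bandwidth")
    control = control or EMControl()
    grid = offset.grid
    prep = _prepare(cases, offset, region_index)
    if study_years is None:
        y_lo = min(p[0] for p in offset.periods)
        y_hi = max(p[1] for p in offset.periods)
        if prep.years.size:
            y_lo = min(y_lo, prep.years.min())
            y_hi = max(y_hi, prep.years.max())
    else:
        y_lo, y_hi = study_years
    years = list(range(y_lo, y_hi + 1))
    t_of_year = {y: i for i, y in enumerate(years)}
    T = len(years)

    # per-year expected counts: each period's mass split evenly over its years
    mu = np.zeros((T,) + grid.shape)
    for p, (py0, py1) in enumerate(offset.periods):
        yrs = [y for y in range(py0, py1 + 1) if y in t_of_year]
        if not yrs:
            continue
        for y in yrs:
            mu[t_of_year[y]] = offset.expected_counts()[p] / len(yrs)
    if mask is None:
        mask = mu.sum(axis=0) > 0
    smooth_s = cached_operator(grid, kernel.h_km, mask,
                               truncation_sd=kernel.truncation_sd)
    smooth_t = TemporalOperator(years, kernel.tau_years, kernel.truncation_sd)

    def S(f: np.ndarray) -> np.ndarray:
        out = np.stack([smooth_s(f[t]) for t in range(T)])
        return smooth_t(out)

    s_mu = S(mu)
    lam = np.where(mask[None, ...], 1.0, 0.0) * np.ones((T, 1, 1))
    n = len(cases)
    if n == 0:
        sel = _select_years(years, index_years)
        return RiskSurface(grid=grid, values=np.zeros((len(sel[0]),) + grid.shape),
                           h_km=kernel.h_km, tau_years=kernel.tau_years,
                           times=sel[0], converged=True, n_iter=0)

    ncell = grid.ny * grid.nx
    history: list[float] = []
    converged = False
    for it in range(1, control.max_iter + 1):
        m = np.zeros((T, ncell))
        for cc, p, y in zip(prep.cells, prep.periods, prep.years):
            t = t_of_year[y]
            w = lam[t].ravel()[cc] * mu[t].ravel()[cc]
            tot = w.sum()
            if tot <= 0:
                w = mu[t].ravel()[cc]
                tot = w.sum()
            m[t, cc] += w / tot
        s_m = S(m.reshape((T,) + grid.shape))
        with np.errstate(divide="ignore", invalid="ignore"):
            new = np.where(s_mu > 0, s_m / np.where(s_mu > 0, s_mu, 1.0), 0.0)
        total = float(np.sum(new * mu))
        if total > 0:
            new = new * (n / total)
        change = float(np.max(np.abs(new - lam)) / max(float(np.max(lam)), 1e-300))
        history.append(change)
        lam = new
        if change < control.tol:
            converged = True
            break
    if not converged:
        warnings.warn(f"spatio-temporal local-EM did not converge in "
                      f"{control.max_iter} iterations")
    sel_years, sel_idx = _select_years(years, index_years)
    return RiskSurface(grid=grid, values=lam[sel_idx], h_km=kernel.h_km,
                       tau_years=kernel.tau_years, times=sel_years,
                       converged=converged, n_iter=len(history))


def _select_years(years: list[int], index_years: Optional[Sequence[int]]):
    if index_years is None:
        return years, np.arange(len(years))
    sel = []
    for y in index_years:
        if y not in years:
            raise SchemaError(f"index year {y} outside the fitted range")
        sel.append(years.index(y))
    return list(index_years), np.array(sel, int)
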