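"""Local-EM core: smoothing operator, offset construction, fixed point."""

import numpy as np
import pytest

from oracle_em import brute_force_em, dense_kernel
from riskmap.localem import (
    EMControl,
    KernelSpec,
    RegionIndex,
    SmoothingOperator,
    TemporalOperator,
    build_offset,
    localem_fit,
    localem_fit_st,
)
from riskmap.raster import RasterizedRegions
from riskmap.types import CaseRecord, GridSpec, OffsetSurface, SchemaError


class TestSmoothing:
    def test_delta_matches_closed_form_gaussian(self):
        g = GridSpec(0, 0, 1000.0, 80, 80)
        S = SmoothingOperator(g, h_km=2.0)
        f = np.zeros(g.shape)
        f[40, 40] = 1.0
        out = S(f)
        sig, r = 2.0, 8
        d = np.arange(-r, r + 1)
        w = np.exp(-0.5 * (d / sig) ** 2)
        w /= w.sum()
        np.testing.assert_allclose(out[40 - r:40 + r + 1, 40 - r:40 + r + 1],
                                   np.outer(w, w), atol=1e-6)

    def test_constant_field_unchanged(self):
        g = GridSpec(0, 0, 1000.0, 25, 18)
        mask = np.ones(g.shape, bool)
        mask[:5, :7] = False  # irregular study region
        S = SmoothingOperator(g, h_km=4.0, mask=mask)
        out = S(np.where(mask, 3.7, 0.0))
        assert np.max(np.abs(out[mask] - 3.7)) < 1e-9
        assert np.all(out[~mask] == 0.0)

    def test_mass_preserved(self):
        rng = np.random.default_rng(0)
        g = GridSpec(0, 0, 1000.0, 30, 30)
        S = SmoothingOperator(g, h_km=5.0)
        f = rng.random(g.shape)
        assert abs(S(f).sum() - f.sum()) / f.sum() < 1e-6

    def test_matches_brute_force_double_loop(self):
        rng = np.random.default_rng(1)
        g = GridSpec(0, 0, 1000.0, 12, 10)
        S = SmoothingOperator(g, h_km=1.5)
        M = dense_kernel(nx=12, ny=10, sigma_cells=1.5)
        f = rng.random(g.shape)
        np.testing.assert_allclose(S(f).ravel(), M @ f.ravel(), atol=1e-10)

    def test_undersmoothing_warns(self):
        g = GridSpec(0, 0, 1000.0, 10, 10)
        with pytest.warns(UserWarning, match="half a grid cell"):
            SmoothingOperator(g, h_km=0.3)

    def test_temporal_flat_limit_is_uniform_average(self):
        T = TemporalOperator(range(1980, 1990), tau_years=1e6)
        x = np.arange(10.0)
        np.testing.assert_allclose(T(x), np.full(10, x.mean()), atol=1e-9)


def toy_offset(mu_cells, nx, ny, period=(1994, 1998)):
    g = GridSpec(0, 0, 1000.0, nx, ny)
    vals = np.asarray(mu_cells, float).reshape(ny, nx) / g.cell_area
    return OffsetSurface(grid=g, periods=[period], values=vals[None])


def exact_case(i, x, y, year=1996):
    return CaseRecord(case_id=f"e{i}", site="bladder", behaviour="invasive",
                      sex="M", age_group="60-64", year=year, precision="exact",
                      point=(x, y))


def censored_case(i, regions, year=1996):
    return CaseRecord(case_id=f"s{i}", site="bladder", behaviour="invasive",
                      sex="M", age_group="60-64", year=year,
                      precision="region_set",
                      candidate_regions=frozenset(regions))


def two_region_index(grid):
    """Left/right split of the grid into fine regions A and B."""
    index = np.zeros(grid.shape, int)
    index[:, grid.nx // 2:] = 1
    ras = RasterizedRegions(grid=grid, ids=["A", "B"], index=index,
                            inhabited=np.ones(grid.shape, bool))
    return RegionIndex(fine=[ras], coarse=None)


class TestFixedPoint:
    def test_exact_cases_converge_in_one_iteration(self):
        rng = np.random.default_rng(2)
        offset = toy_offset(rng.uniform(0.5, 2.0, 48), 8, 6)
        g = offset.grid
        cases = [exact_case(i, *rng.uniform([0, 0], [8000, 6000])) for i in range(9)]
        with pytest.warns(UserWarning):  # max_iter=1 cannot see convergence
            fit1 = localem_fit(cases, offset, KernelSpec(h_km=2.0),
                               EMControl(tol=1e-12, max_iter=1))
        fit = localem_fit(cases, offset, KernelSpec(h_km=2.0),
                          EMControl(tol=1e-12))
        assert fit.converged and fit.n_iter <= 2
        np.testing.assert_allclose(fit.values, fit1.values, atol=1e-12)

    def test_exact_reduction_equals_single_smooth_ratio(self):
        """With no censoring the fixed point is the ratio-of-smooths
        estimator computed directly."""
        rng = np.random.default_rng(3)
        offset = toy_offset(rng.uniform(0.5, 2.0, 60), 10, 6)
        g = offset.grid
        cases = [exact_case(i, *rng.uniform([0, 0], [10000, 6000]))
                 for i in range(12)]
        fit = localem_fit(cases, offset, KernelSpec(h_km=2.0))
        S = SmoothingOperator(g, 2.0, mask=offset.values[0] > 0)
        counts = np.zeros(g.shape)
        for c in cases:
            r, col = g.cell_of(*c.point)
            counts[r, col] += 1
        mu = offset.expected_counts()[0]
        direct = S(counts) / S(mu)
        direct *= len(cases) / (direct * mu).sum()
        np.testing.assert_allclose(fit.values[0], direct, atol=1e-12)

    def test_fully_censored_single_region_is_flat_sir(self):
        g = GridSpec(0, 0, 1000.0, 6, 4)
        rng = np.random.default_rng(4)
        mu = rng.uniform(0.5, 2.0, 24)
        offset = toy_offset(mu, 6, 4)
        index = np.zeros(g.shape, int)
        ras = RasterizedRegions(grid=g, ids=["ALL"], index=index,
                                inhabited=np.ones(g.shape, bool))
        ri = RegionIndex(fine=[ras], coarse=None)
        cases = [censored_case(i, ["ALL"]) for i in range(7)]
        fit = localem_fit(cases, offset, KernelSpec(h_km=2.0), region_index=ri)
        sir = 7 / mu.sum()
        assert np.max(np.abs(fit.values[0] - sir)) < 1e-6 * sir

    @pytest.mark.parametrize("n_cases,h_km", [(1, 1.0), (3, 1.0), (5, 2.0)])
    def test_matches_brute_force_oracle(self, n_cases, h_km):
        """Oracle equivalence on small two-region instances with mixed
        censoring."""
        rng = np.random.default_rng(n_cases * 7 + 1)
        nx, ny = 5, 2
        mu_cells = rng.uniform(0.2, 1.5, nx * ny)
        offset = toy_offset(mu_cells, nx, ny)
        g = offset.grid
        ri = two_region_index(g)
        cases = []
        for i in range(n_cases):
            kind = i % 3
            if kind == 0:
                cases.append(exact_case(i, rng.uniform(0, nx * 1000),
                                        rng.uniform(0, ny * 1000)))
            elif kind == 1:
                cases.append(censored_case(i, ["A"]))
            else:
                cases.append(censored_case(i, ["A", "B"]))
        fit = localem_fit(cases, offset, KernelSpec(h_km=h_km),
                          EMControl(tol=1e-10, max_iter=500), region_index=ri)
        # independent dense reference
        sigma = h_km * 1000.0 / g.delta
        Sd = dense_kernel(nx=nx, ny=ny, sigma_cells=sigma)
        cells = []
        for c in cases:
            if c.precision == "exact":
                r, col = g.cell_of(*c.point)
                cells.append(np.array([r * nx + col]))
            else:
                sel = np.concatenate([ri.fine[0].cells_of(rid)
                                      for rid in sorted(c.candidate_regions)])
                cells.append(np.unique(sel))
        ref = brute_force_em(cells, mu_cells, Sd, tol=1e-10, max_iter=500)
        np.testing.assert_allclose(fit.values[0].ravel(), ref, atol=1e-8)

    def test_mass_conservation(self, small_study):
        s = small_study
        fit = localem_fit(s["cases"], s["offset"], KernelSpec(h_km=8.0),
                          region_index=s["index"])
        mu = s["offset"].expected_counts().sum(axis=0)
        total = float((fit.values[0] * mu).sum())
        assert abs(total - len(s["cases"])) / len(s["cases"]) < 1e-4

    def test_case_order_and_duplicate_split_invariance(self):
        rng = np.random.default_rng(5)
        offset = toy_offset(rng.uniform(0.5, 2.0, 40), 8, 5)
        ri = two_region_index(offset.grid)
        cases = [censored_case(0, ["A", "B"]), censored_case(1, ["A"]),
                 exact_case(2, 500, 500)]
        f1 = localem_fit(cases, offset, KernelSpec(h_km=2.0), region_index=ri)
        f2 = localem_fit(cases[::-1], offset, KernelSpec(h_km=2.0),
                         region_index=ri)
        np.testing.assert_allclose(f1.values, f2.values, atol=1e-12)

    def test_zero_offset_candidate_raises_naming_case(self):
        mu = np.ones(24)
        mu[12:] = 0.0  # region B has no population
        offset = toy_offset(mu, 6, 4)
        ri = RegionIndex(fine=[RasterizedRegions(
            grid=offset.grid, ids=["A", "B"],
            index=(np.arange(24).reshape(4, 6) >= 12).astype(int),
            inhabited=np.ones((4, 6), bool))], coarse=None)
        with pytest.raises(SchemaError, match="s0"):
            localem_fit([censored_case(0, ["B"])], offset,
                        KernelSpec(h_km=2.0), region_index=ri)

    def test_nonnegative_and_finite(self, small_study):
        s = small_study
        fit = localem_fit(s["cases"], s["offset"], KernelSpec(h_km=5.0),
                          region_index=s["index"])
        assert np.all(np.isfinite(fit.values))
        assert np.all(fit.values >= 0)


class TestSpatioTemporal:
    def test_infinite_tau_reduces_to_pooled_spatial(self, small_study):
        s = small_study
        pooled = localem_fit(s["cases"], s["offset"], KernelSpec(h_km=8.0),
                             region_index=s["index"])
        st = localem_fit_st(s["cases"], s["offset"],
                            KernelSpec(h_km=8.0, tau_years=1e6),
                            region_index=s["index"], study_years=(1980, 2010))
        assert np.max(np.abs(st.values - pooled.values[0][None])) < 1e-6

    def test_time_constant_truth_gives_stable_slices(self, small_study):
        s = small_study
        st = localem_fit_st(s["cases"], s["offset"],
                            KernelSpec(h_km=10.0, tau_years=13.0),
                            region_index=s["index"], study_years=(1980, 2010),
                            index_years=[1980, 2010])
        a, b = st.values[0], st.values[1]
        denom = max(a.max(), b.max())
        assert np.max(np.abs(a - b)) / denom < 0.35

    def test_paper_scale_bandwidths_accepted(self):
        k = KernelSpec(h_km=11.0, tau_years=13.0)
        assert k.h_km == 11.0 and k.tau_years == 13.0


class TestOffset:
    def test_single_region_mass_in_its_cells(self, small_study):
        s = small_study
        offset = s["offset"]
        mu = offset.expected_counts()
        # conservation: per-period integral equals period expected totals
        # (self-standardized totals sum to the case count)
        assert mu.sum() == pytest.approx(len(s["cases"]), rel=1e-9)

    def test_inhabited_fraction_concentrates_density(self):
        from riskmap.raster import rasterize
        from riskmap.types import Region
        from shapely.geometry import box
        import pandas as pd
        g = GridSpec(0, 0, 1000.0, 10, 10)
        region = Region("r1", box(0, 0, 10_000, 10_000), (1994, 1998),
                        inhabited_fraction=0.5)
        from riskmap.types import RegionSet
        rs = RegionSet("fine_census", [region])
        pop = pd.DataFrame([("r1", 1996, "M", "60-64", 1000)],
                           columns=["region_id", "census_year", "sex",
                                    "age_group", "count"])
        rates = pd.DataFrame([("M", "60-64", 1e-3)],
                             columns=["sex", "age_group", "rate"])
        offset, _ = build_offset(pop, rates, rs, g, (1996, 1996))
        vals = offset.values[0]
        inhabited = vals > 0
        assert inhabited.sum() == 50
        # density on the inhabited half is double the uniform value
        uniform = 1000 * 1e-3 / (10_000.0 * 10_000.0)
        np.testing.assert_allclose(vals[inhabited], 2 * uniform, rtol=1e-9)
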