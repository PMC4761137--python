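"""Region-to-grid rasterization by cell-centre containment.

A cell belongs to the region containing its centre; this is deterministic and
converges to area-weighting as the cell size shrinks.  Partially uninhabited
regions (inhabited_fraction < 1) spread their population over the inhabited
subset of their cells, chosen deterministically as the cells nearest the
region's representative point.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import shapely
from shapely.strtree import STRtree

from .types import GridSpec, Region, SchemaError


@dataclass
class RasterizedRegions:
    """Integer label image for one period's tessellation."""

    grid: GridSpec
    ids: list[str]
    #: (ny, nx) int array; index into ``ids``, -1 where no region
    index: np.ndarray
    #: (ny, nx) bool array of inhabited cells
    inhabited: np.ndarray

    def cells_of(self, region_id: str) -> np.ndarray:
        """Flat indices (row-major) of the cells of one region."""
        k = self.ids.index(region_id)
        return np.flatnonzero(self.index.ravel() == k)

    def region_of_point(self, x: float, y: float) -> str | None:
        r, c = self.grid.cell_of(x, y)
        k = self.index[int(r), int(c)]
        return self.ids[k] if k >= 0 else None


def rasterize(regions: list[Region], grid: GridSpec) -> RasterizedRegions:
    """Label every grid cell with the region containing its centre."""
    X, Y = grid.centers()
    pts = shapely.points(X.ravel(), Y.ravel())
    index = np.full(pts.shape, -1, dtype=int)
    tree = STRtree(pts)
    for k, region in enumerate(regions):
        hit = tree.query(region.polygon, predicate="intersects")
        if hit.size:
            # first-writer wins only where unassigned: tessellations overlap
            # at shared boundaries only, and boundary centres are measure-zero
            unset = index[hit] == -1
            index[hit[unset]] = k
    index = index.reshape(grid.shape)

    inhabited = np.zeros(grid.shape, dtype=bool)
    flat = index.ravel()
    xs = X.ravel()
    ys = Y.ravel()
    for k, region in enumerate(regions):
        cells = np.flatnonzero(flat == k)
        if cells.size == 0:
            continue
        f = region.inhabited_fraction
        n_keep = max(1, int(np.ceil(f * cells.size)))
        if n_keep >= cells.size:
            keep = cells
        else:
            rp = region.polygon.representative_point()
            d2 = (xs[cells] - rp.x) ** 2 + (ys[cells] - rp.y) ** 2
            keep = cells[np.argsort(d2, kind="stable")[:n_keep]]
        inhabited.ravel()[keep] = True
    return RasterizedRegions(grid=grid, ids=[r.region_id for r in regions],
                             index=index, inhabited=inhabited)


def region_adjacency(regions: list[Region]) -> dict[str, frozenset[str]]:
    """Queen contiguity between polygons: any shared boundary point."""
    tree = STRtree([r.polygon for r in regions])
    out: dict[str, set[str]] = {r.region_id: set() for r in regions}
    a, b = tree.query([r.polygon for r in regions], predicate="intersects")
    for i, j in zip(a, b):
        if i == j:
            continue
        out[regions[i].region_id].add(regions[j].region_id)
        out[regions[j].region_id].add(regions[i].region_id)
    return {k: frozenset(v) for k, v in out.items()}


def coverage_check(regions: list[Region], grid: GridSpec) -> float:
    """Fraction of grid cells whose centre falls inside some region."""
    ras = rasterize(regions, grid)
    return float(np.mean(ras.index >= 0))


def require_population_cells(ras: RasterizedRegions, populated_ids: set[str]) -> None:
    present = {ras.ids[k] for k in np.unique(ras.index) if k >= 0}
    missing = populated_ids - present
    if missing:
        raise SchemaError(
            f"grid too coarse: populated regions with no grid cells: "
            f"{sorted(missing)[:5]}{'...' if len(missing) > 5 else ''}"
        )
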