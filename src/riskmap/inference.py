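"""Bandwidth cross-validation, score tests and bootstrap exceedance surfaces.

Bandwidths are chosen by repeated half-splits of the cases: the model is fit
to one half against a halved offset and scored by the censoring-aware
Poisson log-likelihood of the held-out half, averaged over both fold
orientations and several splits.  Departure from constant risk is tested
with an offset-weighted variance statistic whose null distribution comes
from a parametric bootstrap at constant risk, re-censored with the data's
own precision mix.  Exceedance surfaces P(s; 10%) are one minus the
pointwise bootstrap p-value for lambda(s) < 1.1, following the protocol of
100 constant-risk replicates.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .localem import (
    EMControl,
    KernelSpec,
    RegionIndex,
    localem_fit,
    localem_fit_st,
)
from .raster import RasterizedRegions
from .types import (
    CaseRecord,
    ExceedanceSurface,
    OffsetSurface,
    RiskSurface,
    SchemaError,
)

log = logging.getLogger("riskmap")


@dataclass
class CVTable:
    table: pd.DataFrame      # h_km, tau_years, score_mean, score_sd
    n_splits: int
    seed: int


@dataclass
class BootstrapConfig:
    B: int = 100
    lambda0: float = 1.1
    seed: int = 0

    def __post_init__(self):
        if self.B < 1:
            raise SchemaError("need at least one bootstrap replicate")
        if self.lambda0 <= 0:
            raise SchemaError("null relative risk must be > 0")


def _halved(offset: OffsetSurface) -> OffsetSurface:
    return OffsetSurface(grid=offset.grid, periods=list(offset.periods),
                         values=offset.values * 0.5)


def _case_candidate_mass(case: CaseRecord, lam: RiskSurface,
                         offset: OffsetSurface,
                         region_index: Optional[RegionIndex]) -> float:
    from .localem import _case_cells

    p = offset.period_of(case.year)
    cells = _case_cells(case, offset.grid, p, region_index)
    mu = offset.expected_counts()[p].ravel()
    if lam.values.shape[0] == 1:
        lam_flat = lam.values[0].ravel()
    else:
        t = lam.times.index(case.year)
        lam_flat = lam.values[t].ravel()
    return float(np.sum(lam_flat[cells] * mu[cells]))


def heldout_loglik(lam: RiskSurface, cases: Sequence[CaseRecord],
                   offset: OffsetSurface,
                   region_index: Optional[RegionIndex]) -> float:
    """Poisson log-likelihood of held-out cases under predicted means.

    For exact cases this is the usual cell-count likelihood (up to a
    constant); censored cases contribute the log predicted mass over their
    candidate cells.
    """
    mu = offset.expected_counts()
    if lam.values.shape[0] == 1:
        total = float(np.sum(lam.values[0] * mu.sum(axis=0)))
    else:
        total = 0.0
        for p, (y0, y1) in enumerate(offset.periods):
            yrs = [y for y in lam.times if y0 <= y <= y1]
            for y in yrs:
                total += float(np.sum(lam.values[lam.times.index(y)] * mu[p])) / len(yrs)
    ll = -total
    for case in cases:
        mass = _case_candidate_mass(case, lam, offset, region_index)
        ll += np.log(max(mass, 1e-300))
    return ll


def cv_score(cases: Sequence[CaseRecord], offset: OffsetSurface,
             bandwidths: Sequence[tuple[float, Optional[float]]],
             n_splits: int = 10, seed: int = 0,
             region_index: Optional[RegionIndex] = None,
             control: Optional[EMControl] = None,
             study_years: Optional[tuple[int, int]] = None) -> CVTable:
    """Half-split cross-validation scores for candidate bandwidths.

    ``bandwidths`` is a list of (h_km, tau_years-or-None); higher scores are
    better.
    """
    if len(bandwidths) < 2:
        raise SchemaError("need at least 2 candidate bandwidths")
    if len(cases) < 20:
        raise SchemaError("need at least 20 cases for half-split CV")
    rng = np.random.default_rng(seed)
    half = _halved(offset)
    scores: dict[int, list[float]] = {k: [] for k in range(len(bandwidths))}
    for split in range(n_splits):
        for attempt in range(10):
            perm = rng.permutation(len(cases))
            a_idx = perm[: len(cases) // 2]
            b_idx = perm[len(cases) // 2:]
            if a_idx.size and b_idx.size:
                break
            log.info("empty CV fold; resplitting (attempt %d)", attempt + 1)
        half_a = [cases[i] for i in sorted(a_idx)]
        half_b = [cases[i] for i in sorted(b_idx)]
        for k, (h, tau) in enumerate(bandwidths):
            s = 0.0
            for fit_half, score_half in ((half_a, half_b), (half_b, half_a)):
                lam = _fit(fit_half, half, h, tau, control, region_index,
                           study_years)
                s += heldout_loglik(lam, score_half, half, region_index)
            scores[k].append(s / 2.0)
    rows = [(h, tau, float(np.mean(scores[k])),
             float(np.std(scores[k], ddof=1)) if len(scores[k]) > 1 else 0.0)
            for k, (h, tau) in enumerate(bandwidths)]
    table = pd.DataFrame(rows, columns=["h_km", "tau_years", "score_mean",
                                        "score_sd"])
    if not np.all(np.isfinite(table["score_mean"])):
        raise SchemaError("non-finite CV scores")
    return CVTable(table=table, n_splits=n_splits, seed=seed)


def _fit(cases, offset, h, tau, control, region_index, study_years) -> RiskSurface:
    if tau is None:
        return localem_fit(cases, offset, KernelSpec(h_km=h), control,
                           region_index)
    return localem_fit_st(cases, offset, KernelSpec(h_km=h, tau_years=tau),
                          control, region_index, study_years=study_years)


def select_bandwidth(cv: CVTable) -> tuple[float, Optional[float]]:
    """Argmax of the mean CV score; ties broken toward more smoothing."""
    t = cv.table
    if t.empty:
        raise SchemaError("empty CV table")
    best = t["score_mean"].max()
    ties = t[np.isclose(t["score_mean"], best, rtol=0.0, atol=1e-12)]
    ties = ties.sort_values(["h_km", "tau_years"], na_position="first")
    row = ties.iloc[-1]
    tau = None if pd.isna(row["tau_years"]) else float(row["tau_years"])
    return float(row["h_km"]), tau


# --- parametric bootstrap ---------------------------------------------------

@dataclass
class CensoringModel:
    """Everything needed to re-censor simulated cases like the data.

    ``classes`` holds one (precision, candidate-set size) per real case and
    is resampled for simulated cases, preserving the data's precision mix;
    candidate sets are rebuilt from the rasterized fine regions around the
    simulated location.
    """

    classes: list[tuple[str, int]]
    fine_adjacency: list[dict[str, list[str]]]   # per offset period
    coarse: Optional[RasterizedRegions] = None

    @staticmethod
    def from_data(cases: Sequence[CaseRecord],
                  region_index: Optional[RegionIndex]) -> "CensoringModel":
        classes = [(c.precision,
                    len(c.candidate_regions) if c.candidate_regions else 0)
                   for c in cases]
        adj = []
        if region_index is not None:
            adj = [raster_adjacency(ras) for ras in region_index.fine]
        return CensoringModel(classes=classes, fine_adjacency=adj,
                              coarse=region_index.coarse if region_index else None)


def raster_adjacency(ras: RasterizedRegions) -> dict[str, list[str]]:
    """Rook adjacency between rasterized regions (shared cell edge)."""
    idx = ras.index
    pairs = set()
    for a, b in ((idx[:, :-1], idx[:, 1:]), (idx[:-1, :], idx[1:, :])):
        diff = (a != b) & (a >= 0) & (b >= 0)
        for i, j in zip(a[diff].ravel(), b[diff].ravel()):
            pairs.add((min(i, j), max(i, j)))
    out: dict[str, list[str]] = {rid: [] for rid in ras.ids}
    for i, j in pairs:
        out[ras.ids[i]].append(ras.ids[j])
        out[ras.ids[j]].append(ras.ids[i])
    return {k: sorted(v) for k, v in out.items()}


def simulate_constant_risk(offset: OffsetSurface, lambda0: float,
                           censoring: CensoringModel,
                           region_index: Optional[RegionIndex],
                           rng: np.random.Generator,
                           study_years: Optional[tuple[int, int]] = None
                           ) -> list[CaseRecord]:
    """Simulate one dataset at constant relative risk ``lambda0`` and
    re-censor it with the data's precision mix."""
    grid = offset.grid
    mu = offset.expected_counts()
    cases: list[CaseRecord] = []
    seq = 0
    for p, (y0, y1) in enumerate(offset.periods):
        if study_years is not None:
            y0 = max(y0, study_years[0])
            y1 = min(y1, study_years[1])
        years = list(range(y0, y1 + 1))
        counts = rng.poisson(lambda0 * mu[p])
        rr, cc = np.nonzero(counts)
        for r_i, c_i in zip(rr, cc):
            for _ in range(counts[r_i, c_i]):
                year = int(rng.choice(years))
                x = grid.x0 + (c_i + 0.5) * grid.delta
                y = grid.y0 + (r_i + 0.5) * grid.delta
                prec, size = censoring.classes[int(rng.integers(len(censoring.classes)))]
                kw = dict(case_id=f"b{seq:06d}", site="bladder",
                          behaviour="invasive", sex="M", age_group="20-24",
                          year=year)
                if prec == "region_set" and region_index is not None:
                    ras = region_index.fine[p]
                    home = ras.ids[ras.index[r_i, c_i]] \
                        if ras.index[r_i, c_i] >= 0 else None
                    if home is None:
                        prec = "exact"
                    else:
                        neigh = censoring.fine_adjacency[p].get(home, [])
                        k = max(size, 1)
                        extra = list(rng.choice(neigh,
                                                size=min(k - 1, len(neigh)),
                                                replace=False)) if k > 1 and neigh else []
                        cases.append(CaseRecord(
                            precision="region_set",
                            candidate_regions=frozenset([home] + extra), **kw))
                        seq += 1
                        continue
                if prec == "coarse" and censoring.coarse is not None:
                    k = censoring.coarse.index[r_i, c_i]
                    if k >= 0:
                        cases.append(CaseRecord(
                            precision="coarse",
                            coarse_region=censoring.coarse.ids[k], **kw))
                        seq += 1
                        continue
                cases.append(CaseRecord(precision="exact", point=(x, y), **kw))
                seq += 1
    return cases


def _weighted_variance(lam: RiskSurface, offset: OffsetSurface,
                       temporal: bool = False) -> float:
    """Offset-weighted variance of the risk surface over inhabited cells.

    Spatio-temporal variant subtracts each location's (weighted) time mean
    first, isolating variation over time.
    """
    mu_pool = offset.expected_counts().sum(axis=0)
    if lam.values.shape[0] == 1:
        v = lam.values[0]
        w = mu_pool
        m = np.sum(w * v) / np.sum(w)
        return float(np.sum(w * (v - m) ** 2) / np.sum(w))
    # per-year weights: each period's mass spread over its years
    T = lam.values.shape[0]
    w = np.broadcast_to(mu_pool / T, lam.values.shape)
    v = lam.values
    if temporal:
        tm = v.mean(axis=0, keepdims=True)
        v = v - tm
        m = 0.0
    else:
        m = np.sum(w * v) / np.sum(w)
    return float(np.sum(w * (v - m) ** 2) / np.sum(w))


@dataclass
class ScoreTestResult:
    statistic: float
    p_value: float
    null_statistics: np.ndarray
    h_km: float
    tau_years: Optional[float]


def score_test(cases: Sequence[CaseRecord], offset: OffsetSurface,
               h_km: float, tau_years: Optional[float] = None,
               B: int = 100, seed: int = 0,
               region_index: Optional[RegionIndex] = None,
               control: Optional[EMControl] = None,
               study_years: Optional[tuple[int, int]] = None) -> ScoreTestResult:
    """Bootstrap-calibrated test for spatial (tau None) or spatio-temporal
    variation in risk.

    The statistic is the offset-weighted variance of the fitted surface
    (after removing each location's time mean for the temporal variant); the
    null distribution comes from B constant-risk (lambda = 1) simulations
    re-censored like the data, and p = (1 + #{T* >= T}) / (B + 1).
    """
    if B < 19:
        raise SchemaError("B < 19 gives too coarse a p-value resolution")
    rng = np.random.default_rng(seed)
    temporal = tau_years is not None
    lam = _fit(list(cases), offset, h_km, tau_years, control, region_index,
               study_years)
    T_obs = _weighted_variance(lam, offset, temporal=temporal)
    censoring = CensoringModel.from_data(cases, region_index)
    null_stats = np.empty(B)
    for b in range(B):
        sim = simulate_constant_risk(offset, 1.0, censoring, region_index,
                                     rng, study_years)
        lam_b = _fit(sim, offset, h_km, tau_years, control, region_index,
                     study_years)
        null_stats[b] = _weighted_variance(lam_b, offset, temporal=temporal)
    p = (1.0 + float(np.sum(null_stats >= T_obs))) / (B + 1.0)
    return ScoreTestResult(statistic=T_obs, p_value=p,
                           null_statistics=null_stats, h_km=h_km,
                           tau_years=tau_years)


def bootstrap_exceedance(cases: Sequence[CaseRecord], offset: OffsetSurface,
                         h_km: float, tau_years: Optional[float] = None,
                         cfg: Optional[BootstrapConfig] = None,
                         region_index: Optional[RegionIndex] = None,
                         control: Optional[EMControl] = None,
                         index_years: Optional[Sequence[int]] = None,
                         study_years: Optional[tuple[int, int]] = None
                         ) -> tuple[ExceedanceSurface, RiskSurface]:
    """Exceedance surface P(s; 10%) (or P(s, t; 10%)) by parametric bootstrap.

    B datasets are simulated at constant relative risk lambda0 (default 1.1),
    re-censored like the data and refit with the same bandwidths; the
    p-value at s is the proportion of replicates whose estimate exceeds the
    data's, and P(s) = 1 - p(s).  Returns (exceedance, data fit).
    """
    cfg = cfg or BootstrapConfig()
    rng = np.random.default_rng(cfg.seed)
    if tau_years is None:
        lam_data = localem_fit(list(cases), offset, KernelSpec(h_km=h_km),
                               control, region_index)
    else:
        lam_data = localem_fit_st(list(cases), offset,
                                  KernelSpec(h_km=h_km, tau_years=tau_years),
                                  control, region_index,
                                  index_years=index_years,
                                  study_years=study_years)
    censoring = CensoringModel.from_data(cases, region_index)
    exceed_count = np.zeros_like(lam_data.values)
    used = 0
    dropped = 0
    for b in range(cfg.B):
        sim = simulate_constant_risk(offset, cfg.lambda0, censoring,
                                     region_index, rng, study_years)
        if tau_years is None:
            lam_b = localem_fit(sim, offset, KernelSpec(h_km=h_km), control,
                                region_index)
        else:
            lam_b = localem_fit_st(sim, offset,
                                   KernelSpec(h_km=h_km, tau_years=tau_years),
                                   control, region_index,
                                   index_years=index_years,
                                   study_years=study_years)
        if not lam_b.converged:
            dropped += 1
            log.info("bootstrap replicate %d dropped (non-convergent)", b)
            continue
        exceed_count += (lam_b.values > lam_data.values)
        used += 1
    if used == 0 or dropped > 0.1 * cfg.B:
        raise SchemaError(f"too many non-convergent bootstrap replicates "
                          f"({dropped}/{cfg.B})")
    p = exceed_count / used
    surf = ExceedanceSurface(grid=offset.grid, values=1.0 - p,
                             threshold=cfg.lambda0, n_replicates=used,
                             times=lam_data.times)
    return surf, lam_data
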