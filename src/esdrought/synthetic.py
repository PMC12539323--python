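"""Seeded synthetic landscape generator.

Produces a :class:`~esdrought.grid.LandscapeDataset` whose rasters carry
the statistical structure the analysis pipeline assumes, so every
downstream stage can be exercised and checked against planted truth
without any external data:

* designated drought years with grid-mean SPEI well below -1;
* hump-shaped upper boundaries of each service against SPEI, per
  land-use type: a cell-year's service is ``b(SPEI) * U * L`` where
  ``b`` is a planted parabola (apex = the planted threshold), ``U`` is a
  Beta(a, 1) draw that keeps the upper envelope densely populated, and
  ``L`` is a per-cell capacity level in (0, 1];
* four bundle archetypes: each cell draws a bundle that sets its
  capacity profile across services and its drought frequency;
* per-cell drought-degree strata (none..extreme) realized through the
  depth of the cell's worst drought year, with correlated capacity
  levels inside a stratum so that planted trade-offs (e.g. a negative
  WR-FS correlation among extreme-drought cells) are recoverable;
* linear trends and additive Gaussian noise per input variable
  (truncated at hard physical bounds);
* a hot-and-dry climate signature for drought cell-years, so the binned
  mean-SPEI surface has its minimum in a known temperature x
  precipitation window.

Input rasters (water yield, RUSLE erosivity, NPP, NDVI, zone grain
totals) are then back-solved from the planted service values, so the ES
equations reproduce the planted structure when the pipeline runs.

Ground-truth bundle and stratum labels are recorded on the dataset.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, DimensionError
from .grid import (
    ES_NAMES,
    LAND_USE_CODES,
    VARIABLES,
    GridField,
    LandscapeDataset,
)

STRATUM_NAMES: tuple[str, ...] = ("none", "slight", "medium", "serious", "extreme")

# SPEI interval in which a stratum's *worst* drought year is drawn;
# kept strictly inside the class cutoffs so classification recovers the
# stratum exactly (when no global forced-drought years override it).
_WORST_YEAR_SPEI = {
    1: (-0.95, -0.55),
    2: (-1.45, -1.05),
    3: (-1.95, -1.55),
    4: (-2.45, -2.05),
}


@dataclass
class BoundaryHump:
    """Planted parabolic upper boundary ``b(x) = height - curvature (x - apex)^2``."""

    apex: float
    height: float
    curvature: float

    def __call__(self, x: np.ndarray) -> np.ndarray:
        return np.maximum(self.height - self.curvature * (np.asarray(x) - self.apex) ** 2, 0.0)


@dataclass
class BundleCentroid:
    """One bundle archetype: capacity multipliers per service + drought frequency."""

    multipliers: dict[str, float]  # service -> level in (0, 1]
    spei_f: float  # target fraction of drought years
    fraction: float  # mixing fraction of cells


def _default_boundary_spec() -> dict[tuple[str, str], BoundaryHump]:
    heights = {"WR": 900.0, "SC": 450.0, "CS": 1150.0, "FS": 130.0}
    apices = {
        "WR": {"cropland": 0.20, "forest": 0.81, "shrub": 0.40, "grassland": 0.30, "other": 0.10},
        "SC": {"cropland": 0.25, "forest": 0.96, "shrub": 0.50, "grassland": 0.35, "other": 0.15},
        "CS": {"cropland": 0.10, "forest": -0.30, "shrub": 0.20, "grassland": 0.15, "other": 0.00},
        "FS": {"cropland": 0.30, "forest": 0.20, "shrub": 0.20, "grassland": 0.20, "other": 0.20},
    }
    spec = {}
    for es, by_lu in apices.items():
        h = heights[es]
        for lu, apex in by_lu.items():
            spec[(es, lu)] = BoundaryHump(apex=apex, height=h, curvature=0.05 * h)
    return spec


def _default_cluster_spec() -> list[BundleCentroid]:
    # B1 regulation-strong, B2 fragile/low-drought, B3 food-dominant, B4 carbon/droughty
    return [
        BundleCentroid({"WR": 1.0, "SC": 1.0, "CS": 0.8, "FS": 0.2}, spei_f=0.30, fraction=0.30),
        BundleCentroid({"WR": 0.35, "SC": 0.30, "CS": 0.40, "FS": 0.30}, spei_f=0.15, fraction=0.20),
        BundleCentroid({"WR": 0.40, "SC": 0.45, "CS": 0.60, "FS": 1.0}, spei_f=0.25, fraction=0.30),
        BundleCentroid({"WR": 0.60, "SC": 0.60, "CS": 1.0, "FS": 0.25}, spei_f=0.45, fraction=0.20),
    ]


@dataclass
class SyntheticConfig:
    """Everything the generator needs; identical config + seed => identical dataset."""

    n_rows: int = 50
    n_cols: int = 50
    n_years: int = 23
    cell_km: float = 1.0
    seed: int = 0
    first_year: int = 2000
    drought_years: tuple[int, ...] = (11, 22)
    invalid_fraction: float = 0.02
    n_zones: int = 9
    land_use_fracs: dict[str, float] = field(
        default_factory=lambda: {
            "cropland": 0.30, "forest": 0.30, "shrub": 0.10, "grassland": 0.25, "other": 0.05,
        }
    )
    boundary_spec: dict[tuple[str, str], BoundaryHump] = field(
        default_factory=_default_boundary_spec
    )
    envelope_beta_a: float = 5.0
    trend_spec: dict[str, float] = field(default_factory=lambda: {"NPP": 3.2})
    noise_spec: dict[str, float] = field(default_factory=dict)
    cluster_spec: list[BundleCentroid] = field(default_factory=_default_cluster_spec)
    stratum_probs: dict[str, float] = field(
        default_factory=lambda: {
            "none": 0.20, "slight": 0.35, "medium": 0.25, "serious": 0.12, "extreme": 0.08,
        }
    )
    stratum_correlations: dict[str, dict[tuple[str, str], float]] = field(
        default_factory=lambda: {
            "extreme": {("WR", "FS"): -0.25, ("SC", "FS"): -0.32},
            "slight": {("WR", "CS"): 0.11},
        }
    )
    level_cv: float = 0.15
    drought_suppression: dict[str, float] = field(
        default_factory=lambda: {"WR": 0.30, "SC": 0.25, "CS": 0.05, "FS": 0.10}
    )
    spei_normal_mean: float = 0.35
    spei_normal_sd: float = 0.30
    forced_drought_mean: float = -1.3
    forced_drought_sd: float = 0.25

    def validate(self) -> None:
        for name in ("n_rows", "n_cols", "n_zones"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if self.n_years < 3:
            raise ConfigurationError("n_years must be >= 3")
        if not 0 <= self.invalid_fraction < 1:
            raise ConfigurationError("invalid_fraction must be in [0, 1)")
        for y in self.drought_years:
            if not 0 <= y < self.n_years:
                raise ConfigurationError(f"drought_years index {y} outside 0..{self.n_years - 1}")
        for name, d in (("land_use_fracs", self.land_use_fracs),
                        ("stratum_probs", self.stratum_probs)):
            if abs(sum(d.values()) - 1.0) > 1e-9:
                raise ConfigurationError(f"{name} must sum to 1")
        if abs(sum(c.fraction for c in self.cluster_spec) - 1.0) > 1e-9:
            raise ConfigurationError("cluster_spec mixing fractions must sum to 1")
        for c in self.cluster_spec:
            if not 0 <= c.spei_f <= 1:
                raise ConfigurationError("cluster_spec spei_f must be in [0, 1]")
        for es in ES_NAMES:
            for lu in LAND_USE_CODES:
                if (es, lu) not in self.boundary_spec:
                    raise ConfigurationError(f"boundary_spec missing ({es!r}, {lu!r})")
        for var, sd in self.noise_spec.items():
            if sd < 0:
                raise ConfigurationError(f"noise_spec[{var!r}] must be >= 0")
        if self.level_cv < 0:
            raise ConfigurationError("level_cv must be >= 0")
        for es, f in self.drought_suppression.items():
            if not 0 <= f < 1:
                raise ConfigurationError(f"drought_suppression[{es!r}] must be in [0, 1)")


def _stratum_correlation_matrix(
    spec: dict[tuple[str, str], float] | None
) -> np.ndarray:
    corr = np.eye(len(ES_NAMES))
    if spec:
        idx = {n: i for i, n in enumerate(ES_NAMES)}
        for (a, b), rho in spec.items():
            corr[idx[a], idx[b]] = corr[idx[b], idx[a]] = rho
    # ridge until positive definite (user-specified pairs may conflict)
    for jitter in (0.0, 1e-8, 1e-4, 1e-2):
        try:
            np.linalg.cholesky(corr + jitter * np.eye(len(ES_NAMES)))
            return corr + jitter * np.eye(len(ES_NAMES))
        except np.linalg.LinAlgError:
            continue
    raise ConfigurationError("stratum_correlations matrix is not positive definite")


def _zone_map(n_rows: int, n_cols: int, n_zones: int) -> np.ndarray:
    zr = max(int(np.floor(np.sqrt(n_zones))), 1)
    while n_zones % zr:
        zr -= 1
    zc = n_zones // zr
    row_edges = np.linspace(0, n_rows, zr + 1).astype(int)
    col_edges = np.linspace(0, n_cols, zc + 1).astype(int)
    zones = np.zeros((n_rows, n_cols), dtype=np.int32)
    zid = 1
    for i in range(zr):
        for j in range(zc):
            zones[row_edges[i]:row_edges[i + 1], col_edges[j]:col_edges[j + 1]] = zid
            zid += 1
    return zones


def generate_boundary_scatter(
    hump: BoundaryHump,
    n: int = 10_000,
    x_range: tuple[float, float] = (-2.5, 1.5),
    beta_a: float = 5.0,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Scatter under a planted hump boundary: x uniform, y = b(x) * Beta(a, 1).

    Optional additive Gaussian noise (SD in y units) perturbs the points;
    the envelope remains dense near the boundary because Beta(a, 1) mass
    concentrates at 1.
    """
    rng = np.random.default_rng(seed)
    x = rng.uniform(*x_range, size=n)
    y = hump(x) * rng.beta(beta_a, 1.0, size=n)
    if noise_sd > 0:
        y = y + rng.normal(0.0, noise_sd, size=n)
    return x, np.maximum(y, 0.0)


def generate_cluster_features(
    centroids: np.ndarray,
    n: int = 10_000,
    sd: float = 1.0,
    fractions: np.ndarray | None = None,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Isotropic Gaussian mixture rows + true labels, for clustering checks."""
    centroids = np.atleast_2d(np.asarray(centroids, dtype=float))
    k = len(centroids)
    fractions = np.full(k, 1.0 / k) if fractions is None else np.asarray(fractions)
    rng = np.random.default_rng(seed)
    labels = rng.choice(k, size=n, p=fractions / fractions.sum())
    data = centroids[labels] + rng.normal(0.0, sd, size=(n, centroids.shape[1]))
    return data, labels + 1


def derive_wue(gpp: GridField, et: GridField) -> GridField:
    """Water-use efficiency: GPP / ET; cells with ET = 0 become invalid."""
    if gpp.shape != et.shape:
        raise DimensionError(f"GPP shape {gpp.shape} != ET shape {et.shape}")
    mask = gpp.mask & et.mask & (et.values > 0)
    out = np.full(gpp.values.shape, np.nan)
    np.divide(gpp.values, et.values, out=out, where=et.values > 0)
    return GridField(out, mask, gpp.cell_km)


def generate_landscape(config: SyntheticConfig) -> LandscapeDataset:
    """Generate a full landscape dataset with planted, recorded structure."""
    config.validate()
    R, C, T = config.n_rows, config.n_cols, config.n_years
    ss = np.random.SeedSequence(config.seed)
    (r_mask, r_lu, r_bundle, r_stratum, r_spei, r_u, r_level,
     r_inputs, r_climate, r_noise) = [np.random.default_rng(s) for s in ss.spawn(10)]

    mask = r_mask.random((R, C)) >= config.invalid_fraction
    if not mask.any():
        mask[R // 2, C // 2] = True
    M = int(mask.sum())

    lu_names = list(config.land_use_fracs)
    lu_probs = np.array([config.land_use_fracs[n] for n in lu_names])
    land_use = np.zeros((R, C), dtype=np.int32)
    land_use[mask] = r_lu.choice(
        [LAND_USE_CODES[n] for n in lu_names], size=M, p=lu_probs
    )
    zones = _zone_map(R, C, config.n_zones)
    zones[~mask] = 0

    fracs = np.array([c.fraction for c in config.cluster_spec])
    bundle = np.zeros((R, C), dtype=np.int32)
    bundle[mask] = r_bundle.choice(len(fracs), size=M, p=fracs) + 1

    s_probs = np.array([config.stratum_probs[n] for n in STRATUM_NAMES])
    stratum = np.full((R, C), -1, dtype=np.int32)
    stratum[mask] = r_stratum.choice(len(STRATUM_NAMES), size=M, p=s_probs)

    # ---- SPEI series -------------------------------------------------
    b_flat = bundle[mask]
    s_flat = stratum[mask]
    spei = r_spei.normal(config.spei_normal_mean, config.spei_normal_sd, size=(T, M))
    forced = np.zeros(T, dtype=bool)
    for y in config.drought_years:
        forced[y] = True
    if forced.any():
        spei[forced] = r_spei.normal(
            config.forced_drought_mean, config.forced_drought_sd, size=(int(forced.sum()), M)
        )
    f_b = np.array([0.0] + [c.spei_f for c in config.cluster_spec])
    n_extra = np.round(f_b[b_flat] * T).astype(int) - int(forced.sum())
    n_extra = np.clip(n_extra, 0, T - int(forced.sum()))
    n_extra[s_flat == 0] = 0
    # rank unforced years per cell; the n_extra lowest ranks become drought years
    rr = r_spei.random((T, M))
    rr[forced] = np.inf
    order = np.argsort(rr, axis=0)
    rank_of_year = np.empty_like(order)
    np.put_along_axis(rank_of_year, order, np.arange(T)[:, None] * np.ones((1, M), int), axis=0)
    extra = rank_of_year < n_extra[None, :]
    slight_lo, slight_hi = _WORST_YEAR_SPEI[1]
    spei[extra] = r_spei.uniform(slight_lo, slight_hi, size=int(extra.sum()))
    # deepest year carries the stratum's severity
    has_extra = n_extra > 0
    worst_year = order[0]
    for code, (lo, hi) in _WORST_YEAR_SPEI.items():
        sel = has_extra & (s_flat == code)
        cols = np.nonzero(sel)[0]
        if cols.size:
            spei[worst_year[cols], cols] = r_spei.uniform(lo, hi, size=cols.size)

    # ---- planted service values --------------------------------------
    corr_chol = {
        name: np.linalg.cholesky(
            _stratum_correlation_matrix(config.stratum_correlations.get(name))
        )
        for name in STRATUM_NAMES
    }
    z = np.empty((M, len(ES_NAMES)))
    for code, name in enumerate(STRATUM_NAMES):
        sel = s_flat == code
        if sel.any():
            raw = r_level.normal(size=(int(sel.sum()), len(ES_NAMES)))
            z[sel] = raw @ corr_chol[name].T
    mult = np.array(
        [[0.0] * len(ES_NAMES)]
        + [[c.multipliers[e] for e in ES_NAMES] for c in config.cluster_spec]
    )
    levels = np.clip(mult[b_flat] * (1.0 + config.level_cv * z), 0.01, 1.0)

    lu_flat = land_use[mask]
    drought_cell_year = spei <= -0.5
    es_target: dict[str, np.ndarray] = {}
    for e_idx, es in enumerate(ES_NAMES):
        apex = np.empty(M)
        height = np.empty(M)
        curv = np.empty(M)
        for lu_name, code in LAND_USE_CODES.items():
            hump = config.boundary_spec[(es, lu_name)]
            pick = lu_flat == code
            apex[pick], height[pick], curv[pick] = hump.apex, hump.height, hump.curvature
        b_of_x = np.maximum(height[None, :] - curv[None, :] * (spei - apex[None, :]) ** 2, 0.0)
        u = r_u.beta(config.envelope_beta_a, 1.0, size=(T, M))
        vals = b_of_x * u * levels[None, :, e_idx]
        supp = config.drought_suppression.get(es, 0.0)
        if supp > 0:
            vals = np.where(drought_cell_year, vals * (1.0 - supp), vals)
        if es == "FS":
            vals = np.where((lu_flat == LAND_USE_CODES["cropland"])[None, :], vals, 0.0)
        es_target[es] = vals

    # ---- back-solve input rasters ------------------------------------
    variables: dict[str, np.ndarray] = {}

    def full(flat_tm: np.ndarray) -> np.ndarray:
        out = np.full((T, R, C), np.nan, dtype=np.float32)
        out[:, mask] = flat_tm.astype(np.float32)
        return out

    def static(flat_m: np.ndarray) -> np.ndarray:
        return full(np.broadcast_to(flat_m, (T, M)))

    velocity = r_inputs.uniform(200.0, 350.0, size=M)
    ti = r_inputs.uniform(2.0, 5.0, size=M)
    ks = r_inputs.uniform(200.0, 450.0, size=M)
    atten = (
        np.clip(249.0 / velocity, 0, 1)
        * np.clip(0.9 * ti / 3.0, 0, 1)
        * np.clip(ks / 300.0, 0, 1)
    )
    variables["Velocity"] = static(velocity)
    variables["TI"] = static(ti)
    variables["Ks"] = static(ks)
    variables["Yield"] = full(es_target["WR"] / atten[None, :])

    k_f = r_inputs.uniform(0.15, 0.45, size=M)
    l_f = r_inputs.uniform(1.0, 3.0, size=M)
    s_f = r_inputs.uniform(1.0, 5.0, size=M)
    p_f = r_inputs.uniform(0.2, 0.8, size=M)
    c_f = r_inputs.uniform(0.1, 0.9, size=M)
    denom = k_f * l_f * s_f * (1.0 - p_f * c_f)
    variables["K"] = static(k_f)
    variables["L"] = static(l_f)
    variables["S"] = static(s_f)
    variables["P"] = static(p_f)
    variables["C"] = static(c_f)
    variables["R"] = full(es_target["SC"] / denom[None, :])

    npp = es_target["CS"] / 1.63
    variables["NPP"] = full(npp)
    variables["GPP"] = full(np.maximum(2.1 * npp + r_inputs.normal(0, 10.0, size=(T, M)), 0.0))
    et_base = r_inputs.uniform(450.0, 750.0, size=M)
    variables["ET"] = full(
        np.maximum(et_base[None, :] + r_inputs.normal(0, 20.0, size=(T, M)), 1.0)
    )

    # NDVI proportional to the FS target on cropland so the allocation
    # rule reproduces the planted FS exactly; vegetated background elsewhere
    crop = lu_flat == LAND_USE_CODES["cropland"]
    ndvi = np.empty((T, M))
    base_by_lu = {"cropland": 0.45, "forest": 0.75, "shrub": 0.60, "grassland": 0.55, "other": 0.20}
    # static per-cell NDVI base off cropland, so interannual NDVI variation
    # comes only from trend_spec / noise_spec (cropland NDVI instead carries
    # the per-year food-supply allocation pattern, below)
    for lu_name, code in LAND_USE_CODES.items():
        pick = lu_flat == code
        base = np.clip(
            base_by_lu[lu_name] + r_inputs.normal(0, 0.05, size=int(pick.sum())),
            -1.0, 1.0,
        )
        ndvi[:, pick] = base[None, :]
    zones_flat = zones[mask]
    area = float(config.cell_km) ** 2
    yield_rows = []
    years = np.arange(config.first_year, config.first_year + T)
    for zid in range(1, config.n_zones + 1):
        in_zone = zones_flat == zid
        zcrop = in_zone & crop
        for t in range(T):
            if zcrop.any():
                tgt = es_target["FS"][t, zcrop]
                p_sum = float(tgt.sum() * area)
                peak = tgt.max()
                if peak > 0:
                    ndvi[t, zcrop] = 0.85 * tgt / peak
                else:
                    ndvi[t, zcrop] = 0.0
            else:
                p_sum = 0.0
            yield_rows.append({"zone_id": zid, "year": int(years[t]), "p_sum_t": p_sum})
    variables["NDVI"] = full(ndvi)
    zone_grain_yield = pd.DataFrame(yield_rows)

    # climate signature: drought cell-years are hot and dry
    dr = spei <= -1.0
    tem = r_climate.normal(15.5, 1.2, size=(T, M))
    pre = np.maximum(r_climate.normal(1100.0, 130.0, size=(T, M)), 0.0)
    tem[dr] = np.clip(r_climate.normal(24.0, 0.45, size=int(dr.sum())), 23.05, 24.95)
    pre[dr] = np.clip(r_climate.normal(500.0, 45.0, size=int(dr.sum())), 405.0, 595.0)
    variables["TEM"] = full(tem)
    variables["PRE"] = full(pre)
    variables["SPEI"] = full(spei)

    variables["EL"] = static(r_inputs.uniform(0.0, 3000.0, size=M))
    variables["SL"] = static(r_inputs.uniform(0.0, 40.0, size=M))
    variables["SOC"] = static(r_inputs.uniform(5.0, 40.0, size=M))
    variables["RSMC"] = static(r_inputs.uniform(0.2, 0.9, size=M))
    variables["POP"] = static(100.0 * r_inputs.lognormal(0.0, 1.0, size=M))
    variables["GDP"] = static(500.0 * r_inputs.lognormal(0.0, 1.0, size=M))

    # trends, then noise, then physical truncation
    t_axis = np.arange(T, dtype=np.float32)[:, None, None]
    for var, slope in config.trend_spec.items():
        if var not in variables:
            raise ConfigurationError(f"trend_spec names unknown variable {var!r}")
        variables[var] = variables[var] + np.float32(slope) * t_axis
    for var, sd in config.noise_spec.items():
        if var not in variables:
            raise ConfigurationError(f"noise_spec names unknown variable {var!r}")
        if sd > 0:
            variables[var] = (
                variables[var]
                + r_noise.normal(0.0, sd, size=(T, R, C)).astype(np.float32)
            )
    variables["NDVI"] = np.clip(variables["NDVI"], -1.0, 1.0)
    for var in ("NPP", "GPP", "ET", "PRE", "Yield", "POP", "GDP", "R", "K", "L", "S", "Ks"):
        variables[var] = np.maximum(variables[var], 0.0)
    for var in ("C", "P"):
        variables[var] = np.clip(variables[var], 0.0, 1.0)
    for var in VARIABLES:
        variables[var] = np.ascontiguousarray(variables[var], dtype=np.float32)
        variables[var][:, ~mask] = np.nan

    true_bundle = bundle.copy()  # 0 on invalid cells
    true_stratum = stratum.copy()  # -1 on invalid cells; 0 = 'none'
    ds = LandscapeDataset(
        variables=variables,
        land_use=land_use,
        zones=zones,
        zone_grain_yield=zone_grain_yield,
        mask=mask,
        cell_km=config.cell_km,
        years=years,
        true_bundle=true_bundle,
        true_stratum=true_stratum,
    )
    ds.validate()
    return ds


def noise_free(config: SyntheticConfig) -> SyntheticConfig:
    """Copy of a config with all stochastic dispersion switched off where possible."""
    return replace(config, noise_spec={}, level_cv=0.0)
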