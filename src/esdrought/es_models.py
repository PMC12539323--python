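"""Per-cell ecosystem-service models.

Four annual services are computed on the common grid:

* water retention (WR, mm) — InVEST-style attenuation of water yield,
  ``WR = min(1, 249/Velocity) * min(1, 0.9*TI/3) * min(1, Ks/300) * Yield``;
* soil conservation (SC, t·hm⁻²·a⁻¹) — RUSLE-style factor product
  ``SC = R*K*L*S*(1 - P*C)``;
* carbon sequestration (CS) — proportional to net primary productivity,
  ``CS = 1.63 * NPP`` per unit area (t·km⁻² with NPP in g·m⁻²·a⁻¹), and
  ``G_V = 1.63 * NPP * A`` per cell of area A km²;
* food supply (FS, t·km⁻²) — municipal grain totals disaggregated onto
  cropland cells proportionally to NDVI: ``P_i = NDVI_i / NDVI_sum * P_sum``.

The SC cover/practice term is implemented as the product form
``(1 - P*C)``; the textbook alternative ``(1 - C)(1 - P)`` is available
through ``rusle_variant="textbook"``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import AllocationError, DomainError
from .grid import ES_NAMES, LAND_USE_CODES, GridField, LandscapeDataset, check_coregistered


@dataclass
class WaterRetentionInputs:
    """Co-registered inputs to the water-retention model."""

    velocity: GridField
    ti: GridField
    ks: GridField
    yield_: GridField

    def __post_init__(self) -> None:
        check_coregistered(self.velocity, self.ti, self.ks, self.yield_)


@dataclass
class RusleFactors:
    """Co-registered RUSLE factor rasters (all non-negative; C, P in [0, 1])."""

    r: GridField
    k: GridField
    l: GridField
    s: GridField
    c: GridField
    p: GridField

    def __post_init__(self) -> None:
        check_coregistered(self.r, self.k, self.l, self.s, self.c, self.p)


@dataclass
class EsStack:
    """Annual stacks of the four services on the common grid.

    Each array has shape ``(n_years, n_rows, n_cols)``.
    """

    wr: np.ndarray
    sc: np.ndarray
    cs: np.ndarray
    fs: np.ndarray
    mask: np.ndarray
    cell_km: float = 1.0

    def get(self, name: str) -> np.ndarray:
        return {"WR": self.wr, "SC": self.sc, "CS": self.cs, "FS": self.fs}[name]

    @property
    def n_years(self) -> int:
        return self.wr.shape[0]

    def period_mean(self, name: str) -> np.ndarray:
        """Mean over years, NaN outside the mask."""
        out = np.full(self.mask.shape, np.nan)
        out[self.mask] = self.get(name)[:, self.mask].mean(axis=0)
        return out


def compute_water_retention(inputs: WaterRetentionInputs) -> GridField:
    """Water retention (mm): water yield damped by three clamped terms.

    Each attenuation term is clipped to [0, 1], so retention never
    exceeds yield.
    """
    m = inputs.velocity.mask
    vel = inputs.velocity.values
    if np.any(vel[m] <= 0):
        raise DomainError("flow-velocity coefficient must be > 0 on valid cells")
    if np.any(inputs.yield_.values[m] < 0):
        raise DomainError("water yield must be >= 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        t_vel = np.clip(249.0 / vel, 0.0, 1.0)
        t_ti = np.clip(0.9 * inputs.ti.values / 3.0, 0.0, 1.0)
        t_ks = np.clip(inputs.ks.values / 300.0, 0.0, 1.0)
        retention = t_vel * t_ti * t_ks * inputs.yield_.values
    return GridField(retention, m, inputs.velocity.cell_km)


def compute_soil_conservation(
    factors: RusleFactors, rusle_variant: str = "printed"
) -> GridField:
    """Soil conservation (t·hm⁻²·a⁻¹) from the RUSLE factor product.

    ``rusle_variant="printed"`` uses ``(1 - P*C)``;
    ``"textbook"`` uses ``(1 - C) * (1 - P)``.
    """
    m = factors.r.mask
    c, p = factors.c.values, factors.p.values
    for name, arr in (("C", c), ("P", p)):
        vals = arr[m]
        if np.any((vals < 0) | (vals > 1)):
            raise DomainError(f"RUSLE factor {name} outside [0, 1] on valid cells")
    for name, f in (("R", factors.r), ("K", factors.k), ("L", factors.l), ("S", factors.s)):
        if np.any(f.values[m] < 0):
            raise DomainError(f"RUSLE factor {name} negative on valid cells")
    base = factors.r.values * factors.k.values * factors.l.values * factors.s.values
    if rusle_variant == "printed":
        qsc = base * (1.0 - p * c)
    elif rusle_variant == "textbook":
        qsc = base * (1.0 - c) * (1.0 - p)
    else:
        raise ValueError(f"unknown rusle_variant {rusle_variant!r}")
    return GridField(qsc, m, factors.r.cell_km)


def compute_carbon_sequestration(npp: GridField, per_cell: bool = False) -> GridField:
    """Carbon sequestration from NPP.

    With NPP in g·m⁻²·a⁻¹ (numerically equal to t·km⁻²·a⁻¹) the per-area
    service is ``1.63 * NPP`` in t·km⁻²; with ``per_cell=True`` the value
    is multiplied by the cell area in km² to give the per-cell total G_V.
    """
    if np.any(npp.values[npp.mask] < 0):
        raise DomainError("NPP must be >= 0 on valid cells")
    cs = 1.63 * npp.values
    if per_cell:
        cs = cs * npp.cell_area_km2
    return GridField(cs, npp.mask, npp.cell_km)


def allocate_food_supply(
    ndvi: GridField,
    land_use: np.ndarray,
    zones: np.ndarray,
    zone_totals: pd.DataFrame,
    year: int,
    as_density: bool = True,
) -> GridField:
    """Disaggregate one year's municipal grain totals onto cropland cells.

    Within each zone, cropland cell *i* receives
    ``P_i = NDVI_i / NDVI_sum * P_sum`` tonnes; non-cropland cells get 0.
    Cropland cells with negative NDVI are excluded from ``NDVI_sum`` (and
    receive 0) with a warning, so allocations stay non-negative while the
    zone total is conserved exactly.

    With ``as_density=True`` the result is t·km⁻² (tonnes divided by cell
    area); otherwise t per cell.
    """
    mask = ndvi.mask
    out = np.zeros(ndvi.values.shape, dtype=float)
    out[~mask] = np.nan
    crop = (land_use == LAND_USE_CODES["cropland"]) & mask
    totals = zone_totals[zone_totals["year"] == year]
    lookup = dict(zip(totals["zone_id"].to_numpy(), totals["p_sum_t"].to_numpy()))
    for zid in np.unique(zones[mask]):
        p_sum = float(lookup.get(int(zid), 0.0))
        if p_sum == 0.0:
            continue
        sel = crop & (zones == zid)
        nd = ndvi.values[sel]
        neg = nd < 0
        if neg.any():
            warnings.warn(
                f"zone {int(zid)}: {int(neg.sum())} cropland cells with negative "
                "NDVI excluded from allocation",
                stacklevel=2,
            )
        nd = np.where(neg, 0.0, nd)
        ndvi_sum = nd.sum()
        if ndvi_sum <= 0:
            raise AllocationError(
                f"zone {int(zid)} has grain yield {p_sum} t but no positive "
                "cropland NDVI to allocate it to"
            )
        out[sel] = nd / ndvi_sum * p_sum
    if as_density:
        out = out / ndvi.cell_area_km2
    return GridField(out, mask, ndvi.cell_km)


def compute_es_stack(
    dataset: LandscapeDataset, rusle_variant: str = "printed"
) -> EsStack:
    """Compute all four services for every year of a landscape."""
    T = dataset.n_years
    shp = dataset.shape
    wr = np.empty((T, *shp))
    sc = np.empty((T, *shp))
    cs = np.empty((T, *shp))
    fs = np.empty((T, *shp))
    for t in range(T):
        g = dataset.grid_field
        wr[t] = compute_water_retention(
            WaterRetentionInputs(g("Velocity", t), g("TI", t), g("Ks", t), g("Yield", t))
        ).values
        sc[t] = compute_soil_conservation(
            RusleFactors(g("R", t), g("K", t), g("L", t), g("S", t), g("C", t), g("P", t)),
            rusle_variant=rusle_variant,
        ).values
        cs[t] = compute_carbon_sequestration(g("NPP", t)).values
        year = int(dataset.years[t]) if dataset.years.size else t
        fs[t] = allocate_food_supply(
            g("NDVI", t), dataset.land_use, dataset.zones,
            dataset.zone_grain_yield, year=year,
        ).values
    return EsStack(wr, sc, cs, fs, dataset.mask.copy(), dataset.cell_km)


def zone_es_summary(es: EsStack, zones: np.ndarray, years: np.ndarray) -> pd.DataFrame:
    """Per-zone, per-year mean of each service (columns zone_id, year, *_mean)."""
    rows = []
    m = es.mask
    for t in range(es.n_years):
        year = int(years[t]) if len(years) else t
        for zid in np.unique(zones[m]):
            sel = m & (zones == zid)
            rows.append(
                {
                    "zone_id": int(zid),
                    "year": year,
                    **{
                        f"{name.lower()}_mean": float(np.mean(es.get(name)[t][sel]))
                        for name in ES_NAMES
                    },
                }
            )
    return pd.DataFrame(rows)
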