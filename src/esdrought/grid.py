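"""Gridded containers shared by every pipeline stage.

All analysis happens on a single co-registered grid: every raster shares
one shape, one cell size and one validity mask (a cell invalid in the
land-use map is invalid everywhere).  ``GridField`` wraps one 2-D layer;
``LandscapeDataset`` holds the full multi-year stack of input variables
plus the static land-use map, municipal zones and the zonal grain-yield
table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import DataError, DimensionError

#: land-use class codes used throughout the package
LAND_USE_CODES: dict[str, int] = {
    "cropland": 1,
    "forest": 2,
    "shrub": 3,
    "grassland": 4,
    "other": 5,
}
LAND_USE_NAMES: dict[int, str] = {v: k for k, v in LAND_USE_CODES.items()}

#: dynamic input variables carried by a LandscapeDataset (one layer per year)
VARIABLES: tuple[str, ...] = (
    "SPEI", "PRE", "TEM", "ET", "GPP", "NPP", "NDVI", "SOC", "RSMC",
    "Ks", "TI", "Velocity", "Yield", "R", "K", "L", "S", "C", "P",
    "EL", "SL", "POP", "GDP",
)

ES_NAMES: tuple[str, ...] = ("WR", "SC", "CS", "FS")


@dataclass
class GridField:
    """One variable on the common grid for one point in time.

    Parameters
    ----------
    values
        2-D array; entries on invalid cells are ignored (conventionally NaN).
    mask
        Boolean validity mask, True on valid cells.
    cell_km
        Cell edge length in kilometres.
    """

    values: np.ndarray
    mask: np.ndarray
    cell_km: float = 1.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.ndim != 2:
            raise DimensionError("GridField values must be 2-D")
        if self.mask.shape != self.values.shape:
            raise DimensionError(
                f"mask shape {self.mask.shape} != values shape {self.values.shape}"
            )

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area_km2(self) -> float:
        return float(self.cell_km) ** 2

    def valid_values(self) -> np.ndarray:
        """1-D array of values on valid cells."""
        return self.values[self.mask]


def check_coregistered(*fields: GridField) -> None:
    """Raise :class:`DimensionError` unless all fields share grid and mask."""
    ref = fields[0]
    for f in fields[1:]:
        if f.shape != ref.shape:
            raise DimensionError(f"shape mismatch: {f.shape} vs {ref.shape}")
        if f.cell_km != ref.cell_km:
            raise DimensionError(
                f"cell size mismatch: {f.cell_km} vs {ref.cell_km} km"
            )
        if not np.array_equal(f.mask, ref.mask):
            raise DimensionError("validity masks differ between co-registered fields")


@dataclass
class LandscapeDataset:
    """The pipeline's single input object: a multi-year multi-variable stack.

    ``variables`` maps a variable name to a ``(n_years, n_rows, n_cols)``
    float32 array; static variables (elevation, slope, ...) are stored with
    the year axis repeated so every variable is addressed uniformly.
    ``zone_grain_yield`` has columns ``zone_id, year, p_sum_t``.

    ``true_bundle`` / ``true_stratum`` are generator-recorded ground-truth
    labels (0 on invalid cells); they exist only so that planted structure
    can be checked, and are absent (None) for datasets read from real data.
    """

    variables: dict[str, np.ndarray]
    land_use: np.ndarray
    zones: np.ndarray
    zone_grain_yield: pd.DataFrame
    mask: np.ndarray
    cell_km: float = 1.0
    years: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    true_bundle: np.ndarray | None = None
    true_stratum: np.ndarray | None = None

    @property
    def n_years(self) -> int:
        return next(iter(self.variables.values())).shape[0]

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def cell_area_km2(self) -> float:
        return float(self.cell_km) ** 2

    def grid_field(self, name: str, year_index: int) -> GridField:
        """One variable-year as a :class:`GridField`."""
        return GridField(self.variables[name][year_index], self.mask, self.cell_km)

    def static_field(self, name: str) -> GridField:
        """Period mean of a variable as a :class:`GridField`."""
        vals = np.nanmean(self.variables[name], axis=0)
        return GridField(vals, self.mask, self.cell_km)

    def validate(self) -> None:
        """Check the container invariants; raise on violation."""
        shp = self.mask.shape
        T = self.n_years
        for name, arr in self.variables.items():
            if arr.shape != (T, *shp):
                raise DimensionError(f"variable {name} has shape {arr.shape}")
            if np.isnan(arr[:, self.mask]).any():
                raise DataError(f"variable {name} has NaN on valid cells")
        for name, arr in (("land_use", self.land_use), ("zones", self.zones)):
            if arr.shape != shp:
                raise DimensionError(f"{name} has shape {arr.shape}")
        ndvi = self.variables["NDVI"][:, self.mask]
        if ndvi.min() < -1 or ndvi.max() > 1:
            raise DataError("NDVI outside [-1, 1] on valid cells")
        for name in ("NPP", "GPP", "ET", "PRE", "Yield", "POP", "GDP"):
            if self.variables[name][:, self.mask].min() < 0:
                raise DataError(f"{name} negative on valid cells")
        if (self.zone_grain_yield["p_sum_t"] < 0).any():
            raise DataError("negative zonal grain yield")

    def equals(self, other: "LandscapeDataset") -> bool:
        """Bit-exact equality of all data content (ignores provenance)."""
        if set(self.variables) != set(other.variables):
            return False
        if self.shape != other.shape or self.cell_km != other.cell_km:
            return False
        for name, arr in self.variables.items():
            o = other.variables[name]
            if arr.shape != o.shape:
                return False
            if not np.array_equal(arr, o, equal_nan=True):
                return False
        if not np.array_equal(self.mask, other.mask):
            return False
        if not np.array_equal(self.land_use, other.land_use):
            return False
        if not np.array_equal(self.zones, other.zones):
            return False
        if not np.array_equal(self.years, other.years):
            return False
        a = self.zone_grain_yield.sort_values(["zone_id", "year"]).reset_index(drop=True)
        b = other.zone_grain_yield.sort_values(["zone_id", "year"]).reset_index(drop=True)
        if not a[["zone_id", "year"]].equals(b[["zone_id", "year"]]):
            return False
        if not np.allclose(a["p_sum_t"], b["p_sum_t"], rtol=0, atol=0):
            return False
        for mine, theirs in ((self.true_bundle, other.true_bundle),
                             (self.true_stratum, other.true_stratum)):
            if (mine is None) != (theirs is None):
                return False
            if mine is not None and not np.array_equal(mine, theirs):
                return False
        return True
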